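"""Generator correctness: planted parameters must be recoverable."""

import numpy as np
import pytest

from imcprofiler import synthetic as syn
from imcprofiler.panel import make_default_panel
from imcprofiler.synthetic import (
    CLASSES,
    CellSpec,
    DensityInfeasibleError,
    TreatmentProfile,
    default_profiles,
    generate_experiment,
    render_roi,
    sample_cell_layout,
)


class TestProfiles:
    def test_mixture_must_sum_to_one(self):
        p = default_profiles()["nontreated"]
        bad = dict(p.class_mixture)
        bad["negative"] += 0.1
        with pytest.raises(ValueError, match="sums"):
            TreatmentProfile(
                name="x", cell_density=600, class_mixture=bad,
                area_mean=180, area_sd=40, nucleus_fraction=0.35,
                expression=p.expression,
            )

    @pytest.mark.parametrize("field,value", [
        ("cell_density", 0.0), ("nucleus_fraction", 1.0), ("nucleus_fraction", 0.0),
    ])
    def test_invalid_scalar_fields_rejected(self, field, value):
        p = default_profiles()["nontreated"]
        kwargs = dict(
            name="x", cell_density=p.cell_density,
            class_mixture=p.class_mixture, area_mean=180, area_sd=40,
            nucleus_fraction=p.nucleus_fraction, expression=p.expression,
        )
        kwargs[field] = value
        with pytest.raises(ValueError):
            TreatmentProfile(**kwargs)

    def test_planted_effects_in_default_profiles(self):
        """The drug profiles carry the documented fold-changes."""
        p = default_profiles()
        assert p["nontreated"].class_mixture["pHistone3+"] == pytest.approx(0.04)
        assert p["nocodazole"].class_mixture["pHistone3+"] == pytest.approx(0.12)
        # nocodazole doubles pHistone3 in mitotic cells only
        assert (p["nocodazole"].expression["pHistone3+"]["pHistone3-S28"]
                == 2 * p["nontreated"].expression["pHistone3+"]["pHistone3-S28"])
        assert (p["etoposide"].expression["negative"]["pH2A.X-S139"]
                == 5 * p["nontreated"].expression["negative"]["pH2A.X-S139"])
        assert p["etoposide"].class_mixture["Ki-67+"] == pytest.approx(0.30)
        assert p["EGF"].area_mean == pytest.approx(1.8 * 180.0)
        assert (p["EGF"].expression["negative"]["CD29"]
                == pytest.approx(1.5 * p["nontreated"].expression["negative"]["CD29"]))
        assert p["DMSO"].class_mixture == p["nontreated"].class_mixture
        assert p["DMSO"].expression == p["nontreated"].expression


class TestCellSpec:
    def test_nucleus_must_fit_inside_cell(self):
        with pytest.raises(ValueError, match="inside"):
            CellSpec((10, 10), (5, 4), 0.0, (5, 4), "negative", {})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            CellSpec((10, 10), (5, 4), 0.0, (3, 2), "weird", {})


class TestLayout:
    def test_same_seed_identical(self):
        p = default_profiles()["nontreated"]
        a = sample_cell_layout(p, (200, 200), 5)
        b = sample_cell_layout(p, (200, 200), 5)
        assert a == b and len(a) > 0

    def test_tiny_roi_min_density_gives_empty_layout(self):
        p = default_profiles()["nontreated"]
        tiny = TreatmentProfile(
            name="x", cell_density=1e-6, class_mixture=p.class_mixture,
            area_mean=180, area_sd=40, nucleus_fraction=0.35,
            expression=p.expression,
        )
        assert sample_cell_layout(tiny, (50, 50), 0) == []

    def test_infeasible_density_names_achieved_and_requested(self):
        p = default_profiles()["nontreated"]
        dense = TreatmentProfile(
            name="x", cell_density=20000, class_mixture=p.class_mixture,
            area_mean=180, area_sd=40, nucleus_fraction=0.35,
            expression=p.expression,
        )
        with pytest.raises(DensityInfeasibleError, match="20000"):
            sample_cell_layout(dense, (200, 200), 0, max_attempt_factor=20)

    def test_class_frequencies_match_mixture_within_3se(self):
        p = default_profiles()["nontreated"]
        cells = sample_cell_layout(p, (500, 500), 1)
        n = len(cells)
        for cls in CLASSES:
            freq = sum(c.nuclear_class == cls for c in cells) / n
            target = p.class_mixture[cls]
            se = np.sqrt(target * (1 - target) / n)
            assert abs(freq - target) <= 3 * se, cls

    def test_cells_do_not_overlap(self):
        cells = sample_cell_layout(default_profiles()["nontreated"], (300, 300), 2)
        roi = render_roi(cells, rng_seed=0, roi_size=(300, 300))
        # non-overlap means every spec raster survives in the truth mask
        areas = np.bincount(roi.truth_cells.labels.ravel())[1:]
        assert len(areas) == len(cells) and (areas > 0).all()


class TestRender:
    def test_empty_roi_is_pure_background(self):
        roi = render_roi([], rng_seed=3, roi_size=(100, 100), background_lambda=0.2)
        x = roi.stack.pixels.astype(float)
        se = np.sqrt(0.2 / x.size)
        assert abs(x.mean() - 0.2) <= 3 * se
        assert len(roi.truth_table) == 0

    def test_single_nucleus_recovers_planted_rate(self):
        lam = {m: 0.0 for m in make_default_panel().markers}
        lam["Ir191-DNA"] = 50.0
        cell = CellSpec((50, 50), (10, 8), 0.3, (6, 5), "negative", lam)
        roi = render_roi([cell], rng_seed=1, roi_size=(100, 100),
                         background_lambda=0.5)
        nuc = roi.truth_nuclei.labels == 1
        vals = roi.stack.channel("Ir191-DNA")[nuc].astype(float)
        expected = 50.0 + 0.5
        se = np.sqrt(expected / nuc.sum())
        assert abs(vals.mean() - expected) <= 3 * se

    def test_counts_are_integer_and_nonnegative(self):
        cells = sample_cell_layout(default_profiles()["EGF"], (150, 150), 4)
        roi = render_roi(cells, rng_seed=4, roi_size=(150, 150))
        assert np.issubdtype(roi.stack.pixels.dtype, np.integer)
        assert roi.stack.pixels.min() >= 0

    def test_membrane_signal_confined_to_cell_rim(self):
        lam = {m: 0.0 for m in make_default_panel().markers}
        lam["CD29"] = 80.0
        cell = CellSpec((40, 40), (12, 10), 0.0, (7, 6), "negative", lam)
        roi = render_roi([cell], rng_seed=2, roi_size=(80, 80),
                         background_lambda=0.0)
        img = roi.stack.channel("CD29")
        inside = roi.truth_cells.labels == 1
        nucleus = roi.truth_nuclei.labels == 1
        assert img[~inside].sum() == 0
        assert img[nucleus].sum() == 0  # rim never reaches the nucleus
        assert img[inside].sum() > 0

    def test_truth_masks_consistent_with_truth_table(self):
        cells = sample_cell_layout(default_profiles()["nontreated"], (200, 200), 6)
        roi = render_roi(cells, rng_seed=6, roi_size=(200, 200))
        nuc_ids = set(roi.truth_nuclei.label_ids.tolist())
        cell_ids = set(roi.truth_cells.label_ids.tolist())
        assert nuc_ids == cell_ids == set(roi.truth_table["cell_id"].tolist())
        areas = np.bincount(roi.truth_cells.labels.ravel(),
                            minlength=len(cells) + 1)[1:]
        np.testing.assert_array_equal(
            roi.truth_table.sort_values("cell_id")["area_um2"].to_numpy(), areas
        )


class TestExperiment:
    def test_default_layout_has_8_rois(self, default_experiment):
        assert len(default_experiment) == 8
        conditions = [r.stack.condition for r in default_experiment]
        assert conditions.count("nontreated") == 1
        assert conditions.count("DMSO") == 1
        for drug in ("EGF", "etoposide", "nocodazole"):
            assert conditions.count(drug) == 2

    def test_fixed_master_seed_reproduces_stacks_bytewise(self):
        reps = {"nontreated": 1, "nocodazole": 1}
        a = generate_experiment(replicates=reps, roi_size=(150, 150), master_seed=9)
        b = generate_experiment(replicates=reps, roi_size=(150, 150), master_seed=9)
        for ra, rb in zip(a, b):
            assert ra.stack.pixels.tobytes() == rb.stack.pixels.tobytes()
            np.testing.assert_array_equal(ra.truth_cells.labels, rb.truth_cells.labels)

    def test_unknown_condition_in_replicates_rejected(self):
        with pytest.raises(KeyError, match="mystery"):
            generate_experiment(replicates={"mystery": 1})

    def test_nocodazole_mitotic_fraction_triples_control(self, truth_table):
        def frac(cond):
            sub = truth_table[truth_table["condition"] == cond]
            return (sub["true_class"] == "pHistone3+").mean(), len(sub)

        f_noco, n_noco = frac("nocodazole")
        controls = truth_table[truth_table["condition"].isin(["nontreated", "DMSO"])]
        f_ctrl = (controls["true_class"] == "pHistone3+").mean()
        # planted 0.12 vs 0.04: check each side within 3 binomial SE
        se_noco = np.sqrt(0.12 * 0.88 / n_noco)
        se_ctrl = np.sqrt(0.04 * 0.96 / len(controls))
        assert abs(f_noco - 0.12) <= 3 * se_noco
        assert abs(f_ctrl - 0.04) <= 3 * se_ctrl

    def test_planted_lambda_recovered_from_truth_pixels(self, default_experiment):
        """Channel mean over truth-nucleus pixels converges to the profile rate."""
        roi = next(r for r in default_experiment if r.stack.condition == "nontreated")
        profile = default_profiles()["nontreated"]
        neg = roi.truth_table[roi.truth_table["true_class"] == "negative"]
        lam = profile.expression["negative"]["Ir191-DNA"]
        inside = np.isin(roi.truth_nuclei.labels, neg["cell_id"].to_numpy())
        vals = roi.stack.channel("Ir191-DNA")[inside].astype(float)
        # cell-to-cell log-normal jitter (CV 0.3) plus Poisson noise
        n_cells = len(neg)
        se = lam * 0.3 / np.sqrt(n_cells) + np.sqrt(lam / inside.sum())
        assert abs(vals.mean() - (lam + profile.background_lambda)) <= 3 * se
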