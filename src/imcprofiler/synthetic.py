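"""Ground-truthed synthetic IMC regions of interest.

This module emulates drug-treated MCF-7 monolayers imaged by imaging mass
cytometry at 1 um/pixel: elliptical cells scattered without overlap, each
assigned one of six nuclear phenotype classes (pHistone3+, pH2A.X+, p53+,
cyclinD3+, Ki-67+, negative), with per-channel Poisson ion counts deposited
in the compartment each antibody stains (nucleus, cytoplasm, a 2-px membrane
rim, or the whole cell).  The generator returns the rendered stack together
with ground-truth nucleus/cell label masks and a truth table, so every
downstream stage — segmentation, quantification, classification, similarity —
can be scored against a known answer.

Planted treatment effects (defaults)
------------------------------------
* nontreated / DMSO: identical baseline; mitotic (pHistone3+) mixture weight
  0.04.
* nocodazole: mitotic arrest — pHistone3+ weight 0.12 (3x the controls) and
  pHistone3 signal doubled within mitotic cells; cyclin D3+ fraction raised.
* etoposide: DNA damage — pH2A.X rate x5 in every cell, pH2A.X+ weight 0.20,
  Ki-67+ weight 0.30 (sustained proliferation during repair).
* EGF: growth stimulation — mean cell area x1.8 and membrane-marker rates
  x1.5.

Within-class marker correlations are planted through shared log-normal
latent factors (CV 0.3): one coupling pHistone3/Ki-67/p4E-BP1 inside mitotic
cells, one coupling the surface CD markers in every cell, and one coupling
the two Ir DNA-intercalator isotopes (per-cell DNA content).

Noise is pure per-pixel Poisson; there is no channel spillover, no ablation
artefacts and no tissue context — see the methods note for what this does
and does not exercise.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .features import extract_features
from .io import LabelMask, ROIStack
from .panel import ChannelPanel, make_default_panel

#: the six nuclear phenotype classes, in canonical order
CLASSES = ("pHistone3+", "pH2A.X+", "p53+", "cyclinD3+", "Ki-67+", "negative")

#: marker whose high expression defines each positive class
CLASS_MARKER = {
    "pHistone3+": "pHistone3-S28",
    "pH2A.X+": "pH2A.X-S139",
    "p53+": "p53",
    "cyclinD3+": "cyclin D3",
    "Ki-67+": "Ki-67",
}

_POSITIVE_LAMBDA = 30.0  # mean counts/px of a class-defining marker
_JITTER_CV = 0.3  # log-normal cell-to-cell expression variability

# baseline mean ion counts per pixel within the marker's compartment
_BASE_EXPRESSION = {
    "Ir191-DNA": 40.0,
    "Ir193-DNA": 30.0,
    "Rh103-viability": 0.3,
    "IdU": 0.5,
    "pHistone3-S28": 0.8,
    "pH2A.X-S139": 1.0,
    "Ki-67": 1.5,
    "p53": 1.0,
    "cyclin B1": 2.0,
    "cyclin D3": 1.2,
    "p4E-BP1-T37/T46": 2.0,
    "cPARP": 0.5,
    "ERa": 3.0,
    "pan-keratin": 15.0,
    "CK19": 8.0,
    "MUC-1": 4.0,
    "EpCAM": 6.0,
    "CD29": 6.0,
    "CD81": 5.0,
    "CD98": 5.0,
    "CD47": 4.0,
    "CD49e": 4.0,
    "E-cadherin": 6.0,
    "EGFR": 3.0,
    "HER2": 4.0,
    "CD107b": 3.0,
    "vimentin": 1.0,
    "CK5": 1.0,
    "carrier-blank": 0.0,
}

MEMBRANE_CD_MARKERS = ("CD98", "CD29", "EpCAM", "CD81", "CD47", "CD49e")
MITOTIC_TRIO = ("pHistone3-S28", "Ki-67", "p4E-BP1-T37/T46")

#: replicate layout of the emulated experiment: one ROI for each control,
#: two replicate ROIs per compound
DEFAULT_REPLICATES = {
    "nontreated": 1,
    "DMSO": 1,
    "EGF": 2,
    "etoposide": 2,
    "nocodazole": 2,
}

DEFAULT_ROI_SIZE = (500.0, 500.0)  # um


class DensityInfeasibleError(RuntimeError):
    """Raised when dart throwing cannot reach the requested cell density."""


@dataclass(frozen=True)
class CorrelationGroup:
    """Channels forced to co-vary through one shared latent factor.

    ``classes`` restricts the coupling to cells of those classes; ``None``
    applies it to every cell.
    """

    markers: tuple[str, ...]
    classes: tuple[str, ...] | None = None


@dataclass
class TreatmentProfile:
    """Generative parameters of one treatment condition."""

    name: str
    cell_density: float  # cells per mm^2
    class_mixture: dict[str, float]
    area_mean: float  # um^2
    area_sd: float
    nucleus_fraction: float  # nuclear / cell area ratio
    expression: dict[str, dict[str, float]]  # class -> marker -> lambda
    background_lambda: float = 0.2
    correlation_spec: tuple[CorrelationGroup, ...] = ()

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mixture sums to {total}, not 1")
        if self.cell_density <= 0:
            raise ValueError("cell_density must be positive")
        if not 0.0 < self.nucleus_fraction < 1.0:
            raise ValueError("nucleus_fraction must lie in (0, 1)")
        for cls, table in self.expression.items():
            for marker, lam in table.items():
                if lam < 0:
                    raise ValueError(f"negative rate for ({cls}, {marker})")
        if self.background_lambda < 0:
            raise ValueError("background_lambda must be nonnegative")


@dataclass
class CellSpec:
    """Geometry and expression of one synthetic cell.

    Axes are semi-axis lengths in micrometres; the nucleus ellipse shares the
    cell's centre and orientation and is strictly contained in it.
    """

    center: tuple[float, float]  # (x, y) um
    cell_axes: tuple[float, float]  # (major, minor) semi-axes, um
    orientation: float  # radians
    nucleus_axes: tuple[float, float]
    nuclear_class: str
    per_channel_lambda: dict[str, float]

    def __post_init__(self) -> None:
        if min(self.cell_axes) <= 0 or min(self.nucleus_axes) <= 0:
            raise ValueError("axes must be positive")
        if (self.nucleus_axes[0] >= self.cell_axes[0]
                or self.nucleus_axes[1] >= self.cell_axes[1]):
            raise ValueError("nucleus ellipse must be strictly inside the cell")
        if self.nuclear_class not in CLASSES:
            raise ValueError(f"unknown nuclear class {self.nuclear_class!r}")


@dataclass
class SyntheticROI:
    """A rendered ROI with its ground truth."""

    stack: ROIStack
    truth_nuclei: LabelMask
    truth_cells: LabelMask
    truth_table: "object"  # pandas DataFrame with a true_class column
    seed: int


# ---------------------------------------------------------------------------
# default profiles


def _expression(overrides_all=None, overrides_by_class=None) -> dict:
    """Expand base expression into a full class -> marker -> rate map."""
    table = {}
    for cls in CLASSES:
        row = dict(_BASE_EXPRESSION)
        marker = CLASS_MARKER.get(cls)
        if marker is not None:
            row[marker] = _POSITIVE_LAMBDA
        if overrides_all:
            for m, factor in overrides_all.items():
                row[m] = row[m] * factor
        if overrides_by_class and cls in overrides_by_class:
            for m, factor in overrides_by_class[cls].items():
                row[m] = row[m] * factor
        table[cls] = row
    return table


_DEFAULT_CORRELATIONS = (
    CorrelationGroup(MITOTIC_TRIO, classes=("pHistone3+",)),
    CorrelationGroup(MEMBRANE_CD_MARKERS, classes=None),
    CorrelationGroup(("Ir191-DNA", "Ir193-DNA"), classes=None),
)

_CONTROL_MIXTURE = {
    "pHistone3+": 0.04, "pH2A.X+": 0.08, "p53+": 0.08,
    "cyclinD3+": 0.10, "Ki-67+": 0.15, "negative": 0.55,
}
_ETOPOSIDE_MIXTURE = {
    "pHistone3+": 0.04, "pH2A.X+": 0.20, "p53+": 0.08,
    "cyclinD3+": 0.08, "Ki-67+": 0.30, "negative": 0.30,
}
_NOCODAZOLE_MIXTURE = {
    "pHistone3+": 0.12, "pH2A.X+": 0.08, "p53+": 0.08,
    "cyclinD3+": 0.14, "Ki-67+": 0.11, "negative": 0.47,
}


def default_profiles(cell_density: float = 600.0) -> dict[str, TreatmentProfile]:
    """The five default condition profiles with the planted drug effects."""

    def base(name, mixture, area_mean=180.0, area_sd=40.0, expression=None):
        return TreatmentProfile(
            name=name,
            cell_density=cell_density,
            class_mixture=dict(mixture),
            area_mean=area_mean,
            area_sd=area_sd,
            nucleus_fraction=0.35,
            expression=expression if expression is not None else _expression(),
            background_lambda=0.2,
            correlation_spec=_DEFAULT_CORRELATIONS,
        )

    membrane = make_default_panel().markers_by_compartment("membrane")
    return {
        "nontreated": base("nontreated", _CONTROL_MIXTURE),
        "DMSO": base("DMSO", _CONTROL_MIXTURE),
        "EGF": base(
            "EGF", _CONTROL_MIXTURE,
            area_mean=180.0 * 1.8, area_sd=40.0 * 1.8,
            expression=_expression(overrides_all={m: 1.5 for m in membrane}),
        ),
        "etoposide": base(
            "etoposide", _ETOPOSIDE_MIXTURE,
            expression=_expression(overrides_all={"pH2A.X-S139": 5.0}),
        ),
        "nocodazole": base(
            "nocodazole", _NOCODAZOLE_MIXTURE,
            expression=_expression(
                overrides_by_class={"pHistone3+": {"pHistone3-S28": 2.0}}
            ),
        ),
    }


# ---------------------------------------------------------------------------
# layout sampling


def _lognormal_factor(rng: np.random.Generator, cv: float = _JITTER_CV) -> float:
    """Unit-mean log-normal multiplier with the given coefficient of variation."""
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def sample_cell_layout(
    profile: TreatmentProfile,
    roi_size: tuple[float, float] = DEFAULT_ROI_SIZE,
    rng_seed: int = 0,
    max_attempt_factor: int = 200,
) -> list[CellSpec]:
    """Dart-throw non-overlapping elliptical cells to the profile's density.

    Placement rejects candidates whose bounding circles (major semi-axes)
    intersect an accepted cell, so rendered cells never overlap.  Each
    accepted cell draws a nuclear class from the profile mixture and
    per-channel rates from the class expression row, multiplied by unit-mean
    log-normal jitter (CV 0.3); channels in a correlation group applicable to
    the cell's class share one latent factor.

    Deterministic for a fixed seed.  Raises :class:`DensityInfeasibleError`
    if the target count cannot be placed, naming the achieved and requested
    densities.
    """
    w, h = float(roi_size[0]), float(roi_size[1])
    if w <= 0 or h <= 0:
        raise ValueError("roi_size must be positive")
    rng = np.random.default_rng(rng_seed)
    area_mm2 = w * h / 1e6
    n_target = int(round(profile.cell_density * area_mm2))
    if n_target == 0:
        return []

    classes = list(CLASSES)
    weights = np.array([profile.class_mixture.get(c, 0.0) for c in classes])
    weights = weights / weights.sum()

    placed: list[CellSpec] = []
    centers = np.empty((0, 2))
    radii = np.empty((0,))
    max_attempts = max_attempt_factor * n_target
    attempts = 0
    while len(placed) < n_target and attempts < max_attempts:
        attempts += 1
        area = rng.normal(profile.area_mean, profile.area_sd)
        area = max(area, 40.0)  # floor: no sub-resolution cells
        ratio = rng.uniform(0.6, 0.95)  # minor/major
        semi_major = math.sqrt(area / (math.pi * ratio))
        semi_minor = ratio * semi_major
        orientation = rng.uniform(0.0, math.pi)
        margin = semi_major + 1.0
        if 2 * margin >= min(w, h):
            continue
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if centers.shape[0]:
            d = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
            if np.any(d <= radii + semi_major + 0.5):
                continue

        cls = classes[int(rng.choice(len(classes), p=weights))]
        lam = dict(profile.expression[cls])
        grouped: set[str] = set()
        for group in profile.correlation_spec:
            if group.classes is not None and cls not in group.classes:
                continue
            factor = _lognormal_factor(rng)
            for m in group.markers:
                if m in lam:
                    lam[m] *= factor
                    grouped.add(m)
        for m in lam:
            if m not in grouped:
                lam[m] *= _lognormal_factor(rng)

        nf = math.sqrt(profile.nucleus_fraction)
        spec = CellSpec(
            center=(cx, cy),
            cell_axes=(semi_major, semi_minor),
            orientation=orientation,
            nucleus_axes=(semi_major * nf, semi_minor * nf),
            nuclear_class=cls,
            per_channel_lambda=lam,
        )
        placed.append(spec)
        centers = np.vstack([centers, [cx, cy]])
        radii = np.append(radii, semi_major)

    if len(placed) < n_target:
        achieved = len(placed) / area_mm2
        raise DensityInfeasibleError(
            f"placed {len(placed)} cells ({achieved:.0f}/mm^2) after "
            f"{max_attempts} attempts; requested {profile.cell_density:.0f}/mm^2 "
            f"in a {w:.0f}x{h:.0f} um ROI"
        )
    return placed


# ---------------------------------------------------------------------------
# rendering


def _ellipse_mask(shape, center, axes, orientation, origin) -> np.ndarray:
    """Boolean raster of a rotated ellipse on a pixel grid (1 um/px)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    # pixel centers in um, relative to the ellipse center
    x = (xx + origin[0] + 0.5) - center[0]
    y = (yy + origin[1] + 0.5) - center[1]
    c, s = math.cos(orientation), math.sin(orientation)
    u = x * c + y * s
    v = -x * s + y * c
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def render_roi(
    cells: list[CellSpec],
    panel: ChannelPanel | None = None,
    roi_size: tuple[float, float] = DEFAULT_ROI_SIZE,
    rng_seed: int = 0,
    background_lambda: float = 0.2,
    roi_id: str = "synthetic",
    condition: str = "",
) -> SyntheticROI:
    """Rasterize cells and draw per-pixel Poisson ion counts.

    Compartment rules: nuclear channels deposit only inside the nucleus
    ellipse, membrane channels in a 2-px rim inside the cell boundary,
    cytoplasmic channels in cell-minus-nucleus, and ``any`` channels across
    the whole cell.  Truth masks rasterize the ellipses; later cells never
    overwrite earlier labels.
    """
    panel = make_default_panel() if panel is None else panel
    w_um, h_um = float(roi_size[0]), float(roi_size[1])
    H, W = int(round(h_um)), int(round(w_um))
    C = len(panel)
    compartments = [ch.compartment for ch in panel]
    for ch in panel:
        if ch.compartment not in ("nucleus", "cytoplasm", "membrane", "any"):
            raise ValueError(f"unknown compartment {ch.compartment!r}")

    rate = np.full((H, W, C), float(background_lambda), dtype=np.float64)
    nuc_truth = np.zeros((H, W), dtype=np.int32)
    cell_truth = np.zeros((H, W), dtype=np.int32)

    for label, cell in enumerate(cells, start=1):
        cx, cy = cell.center
        r = cell.cell_axes[0] + 1.0
        x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r))
        y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r))
        if x0 < 0 or y0 < 0 or x1 > W or y1 > H:
            raise ValueError(
                f"cell {label} at ({cx:.1f}, {cy:.1f}) does not fit in the ROI"
            )
        shape = (y1 - y0, x1 - x0)
        cell_m = _ellipse_mask(shape, cell.center, cell.cell_axes,
                               cell.orientation, (x0, y0))
        nuc_m = _ellipse_mask(shape, cell.center, cell.nucleus_axes,
                              cell.orientation, (x0, y0))
        nuc_m &= cell_m
        rim = cell_m & ~ndi.binary_erosion(cell_m, iterations=2)
        cyto = cell_m & ~nuc_m

        region_by_compartment = {
            "nucleus": nuc_m, "cytoplasm": cyto, "membrane": rim, "any": cell_m,
        }
        sub_rate = rate[y0:y1, x0:x1]
        for c in range(C):
            lam = cell.per_channel_lambda.get(panel[c].marker, 0.0)
            if lam <= 0:
                continue
            region = region_by_compartment[compartments[c]]
            sub_rate[..., c][region] += lam

        sub_cell = cell_truth[y0:y1, x0:x1]
        sub_nuc = nuc_truth[y0:y1, x0:x1]
        sub_cell[cell_m & (sub_cell == 0)] = label
        sub_nuc[nuc_m & (sub_nuc == 0)] = label

    rng = np.random.default_rng(rng_seed)
    counts = rng.poisson(rate)
    dtype = np.uint16 if counts.max(initial=0) <= 65535 else np.uint32
    stack = ROIStack(counts.astype(dtype), panel, pixel_size=1.0,
                     roi_id=roi_id, condition=condition)
    truth_nuclei = LabelMask(nuc_truth, kind="nuclei")
    truth_cells = LabelMask(cell_truth, kind="cells")

    table = extract_features(stack, truth_cells, truth_nuclei, condition=condition)
    true_class = [cells[int(cid) - 1].nuclear_class
                  for cid in table["cell_id"]]
    table = table.assign(true_class=true_class)
    return SyntheticROI(stack, truth_nuclei, truth_cells, table, int(rng_seed))


# ---------------------------------------------------------------------------
# experiments


def _roi_seed(master_seed: int, condition: str, replicate: int) -> tuple[int, int]:
    """Stable (layout, render) child seeds for one ROI."""
    ss = np.random.SeedSequence(
        [int(master_seed) % (2**31), zlib.crc32(condition.encode()), replicate]
    )
    layout, render = ss.generate_state(2)
    return int(layout) % (2**31), int(render) % (2**31)


def generate_experiment(
    profiles: dict[str, TreatmentProfile] | None = None,
    replicates: dict[str, int] | None = None,
    roi_size: tuple[float, float] = DEFAULT_ROI_SIZE,
    master_seed: int = 0,
) -> list[SyntheticROI]:
    """Generate the full multi-condition experiment.

    The default layout mirrors the emulated acquisition: two replicate ROIs
    per compound (EGF, etoposide, nocodazole) and a single ROI each for the
    nontreated and DMSO controls — 8 ROIs in total.  Per-ROI seeds are
    derived from ``master_seed``, so the whole experiment is reproducible
    bit-for-bit.
    """
    profiles = default_profiles() if profiles is None else profiles
    replicates = dict(DEFAULT_REPLICATES) if replicates is None else replicates
    for cond, n in replicates.items():
        if cond not in profiles:
            raise KeyError(f"condition {cond!r} has no profile")
        if n < 1:
            raise ValueError(f"replicate count for {cond!r} must be >= 1")

    rois: list[SyntheticROI] = []
    for cond, n in replicates.items():
        profile = profiles[cond]
        for rep in range(n):
            layout_seed, render_seed = _roi_seed(master_seed, cond, rep)
            cells = sample_cell_layout(profile, roi_size, layout_seed)
            roi = render_roi(
                cells, make_default_panel(), roi_size, render_seed,
                background_lambda=profile.background_lambda,
                roi_id=f"{cond}-{rep + 1}", condition=cond,
            )
            rois.append(roi)
    return rois


def experiment_table(rois: list[SyntheticROI]):
    """Concatenate the truth tables of an experiment into one table."""
    import pandas as pd

    return pd.concat([r.truth_table for r in rois], ignore_index=True)
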