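"""Config-driven end-to-end orchestration.

Runs simulate -> segment -> quantify -> stats -> embed -> classify ->
similarity from one YAML config and one master seed, writing every artifact
plus a run manifest (config hash, seeds, per-stage object counts, artifact
checksums).  Re-running with the same config and seed reproduces all numeric
artifacts bit-for-bit.  Child seeds are derived per stage from the master
seed (stage name hashed into the seed stream), so stages are independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import io as imcio
from . import segmentation as seg
from . import similarity as simi
from . import stats as st
from . import synthetic as syn
from .embedding import tsne_embed
from .features import extract_features
from .panel import make_default_panel

log = logging.getLogger("imcprofiler")

#: markers entering z-scoring and statistics by default: the drug-sensitive
#: nuclear markers and the surface CD markers highlighted by the analysis
DEFAULT_STAT_MARKERS = [
    "pHistone3-S28", "pH2A.X-S139", "Ki-67", "p4E-BP1-T37/T46", "p53",
    "cyclin D3", "CD98", "CD81", "CD29", "CD49e", "CD47",
]

_SCHEMA = {
    "version": None,
    "seed": None,
    "output_dir": None,
    "simulate": {"roi_size", "cell_density", "replicates"},
    "segmentation": {"nuclear_channel", "cyto_channel", "smooth_sigma",
                     "min_diameter", "max_diameter", "declump"},
    "zscore": {"channels", "clip_percentile"},
    "classifier": {"n_rounds", "folds"},
    "embedding": {"enabled", "perplexity"},
    "similarity": {"population", "parameters", "cutoff"},
}


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original context."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see the YAML schema in docs)."""

    seed: int = 42
    output_dir: str = "imcprofiler_out"
    simulate: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    zscore: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    embedding: dict = field(default_factory=dict)
    similarity: dict = field(default_factory=dict)
    version: int = 1

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, allowed in _SCHEMA.items():
            if allowed is None or key not in raw:
                continue
            extra = set(raw[key]) - allowed
            if extra:
                raise ValueError(f"unknown key(s) under {key!r}: {sorted(extra)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "simulate": self.simulate,
            "segmentation": self.segmentation,
            "zscore": self.zscore,
            "classifier": self.classifier,
            "embedding": self.embedding,
            "similarity": self.similarity,
        }

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master_seed) % (2**31),
                                 zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0]) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest dictionary.

    Any stage error aborts with the stage name; partial outputs are kept and
    a ``FAILED`` marker file names the failing stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }
    stage = "init"
    try:
        # ---- simulate ------------------------------------------------
        stage = "simulate"
        log.info("stage %s", stage)
        sim_cfg = config.simulate
        roi_size = tuple(sim_cfg.get("roi_size", syn.DEFAULT_ROI_SIZE))
        density = sim_cfg.get("cell_density", 600.0)
        replicates = sim_cfg.get("replicates", dict(syn.DEFAULT_REPLICATES))
        profiles = syn.default_profiles(cell_density=density)
        for cond in replicates:
            if cond not in profiles:
                raise KeyError(f"condition {cond!r} has no profile")
        rois = syn.generate_experiment(
            profiles, replicates, roi_size,
            master_seed=_stage_seed(config.seed, "simulate"),
        )
        roi_dir = out / "rois"
        roi_dir.mkdir(exist_ok=True)
        for roi in rois:
            d = roi_dir / roi.stack.roi_id
            d.mkdir(exist_ok=True)
            imcio.write_stack(roi.stack, d / "stack.tiff", bit_depth=16)
            imcio.write_mask(roi.truth_nuclei, d / "truth_nuclei.tiff")
            imcio.write_mask(roi.truth_cells, d / "truth_cells.tiff")
            imcio.write_cell_table(roi.truth_table, d / "truth_table.csv")
        manifest["stages"]["simulate"] = {
            "n_rois": len(rois),
            "roi_ids": [r.stack.roi_id for r in rois],
            "n_cells_truth": int(sum(len(r.truth_table) for r in rois)),
        }

        # ---- segment + quantify -------------------------------------
        stage = "segment"
        log.info("stage %s", stage)
        params = seg.SegmentationParams(**config.segmentation)
        panel = make_default_panel()
        for ch in (params.nuclear_channel, params.cyto_channel):
            if ch not in panel:
                raise KeyError(f"channel {ch!r} not in panel")
        tables = []
        counts = {}
        for roi in rois:
            nuclei = seg.segment_nuclei(roi.stack, params)
            cells = seg.segment_cells(roi.stack, nuclei, params)
            d = roi_dir / roi.stack.roi_id
            imcio.write_mask(nuclei, d / "nuclei.tiff")
            imcio.write_mask(cells, d / "cells.tiff")
            stage = "quantify"
            table = extract_features(roi.stack, cells, nuclei)
            imcio.write_cell_table(table, d / "cells.csv")
            if len(table) != cells.n_objects:
                raise RuntimeError(
                    f"object-count mismatch in {roi.stack.roi_id}: "
                    f"{len(table)} rows vs {cells.n_objects} labels"
                )
            counts[roi.stack.roi_id] = cells.n_objects
            tables.append(table)
            stage = "segment"
        cell_table = pd.concat(tables, ignore_index=True)
        manifest["stages"]["segment"] = {"n_cells_by_roi": counts}
        manifest["stages"]["quantify"] = {"n_cells": int(len(cell_table))}

        # ---- stats ---------------------------------------------------
        stage = "stats"
        log.info("stage %s", stage)
        zcfg = config.zscore
        channels = zcfg.get("channels", DEFAULT_STAT_MARKERS) + st.SIZE_COLUMNS
        clip = zcfg.get("clip_percentile", 99.0)
        cell_table = st.zscore(cell_table, channels, clip_percentile=clip)
        stats_df = st.compare_conditions(
            cell_table, zcfg.get("channels", DEFAULT_STAT_MARKERS),
            reference_conditions=[c for c in ("nontreated", "DMSO")
                                  if c in set(cell_table["condition"])],
        )
        stats_df.to_csv(out / "condition_stats.csv", index=False)
        imcio.write_cell_table(cell_table, out / "cells_all.csv")

        # ---- embed ---------------------------------------------------
        stage = "embed"
        ecfg = config.embedding
        if ecfg.get("enabled", True):
            log.info("stage %s", stage)
            emb = tsne_embed(
                cell_table,
                seed=_stage_seed(config.seed, "embed"),
                perplexity=ecfg.get("perplexity", 30.0),
            )
            emb.to_frame(cell_table).to_csv(out / "tsne.csv", index=False)
            manifest["stages"]["embed"] = {
                "n_points": int(len(cell_table)), "perplexity": emb.perplexity,
            }

        # ---- classify ------------------------------------------------
        stage = "classify"
        log.info("stage %s", stage)
        ccfg = config.classifier
        truth = syn.experiment_table(rois)
        feats = clf.default_feature_names(truth)
        model = clf.train_fast_gentle_boosting(
            truth, truth["true_class"], feats,
            n_rounds=ccfg.get("n_rounds", 50),
        )
        model.to_json(out / "model.json")
        cm = clf.cross_validate(
            truth, truth["true_class"], feats,
            folds=ccfg.get("folds", 5), n_rounds=ccfg.get("n_rounds", 50),
            seed=_stage_seed(config.seed, "classify"),
        )
        cm.to_frame().to_csv(out / "confusion_matrix.csv")
        scored = clf.score_cells(model, cell_table)
        mi = clf.mitotic_index(scored)
        mi.to_csv(out / "mitotic_index.csv", index=False)
        imcio.write_cell_table(scored, out / "cells_scored.csv")
        manifest["stages"]["classify"] = {
            "cv_accuracy": cm.accuracy,
            "cv_diagonal": {c: float(cm.matrix[i, i])
                            for i, c in enumerate(cm.classes)},
            "mitotic_index": dict(zip(mi["condition"], mi["mitotic_index"])),
        }

        # ---- similarity ---------------------------------------------
        stage = "similarity"
        log.info("stage %s", stage)
        scfg = config.similarity
        population = scfg.get("population", "pHistone3+")
        parameters = scfg.get("parameters", list(syn.MEMBRANE_CD_MARKERS))
        cutoff = scfg.get("cutoff", 0.3)
        sim = simi.pearson_matrix(scored, parameters, population)
        sim.to_frame().to_csv(out / "similarity.csv")
        order, Z = simi.hierarchical_order(sim)
        (out / "similarity_dendrogram.nwk").write_text(
            simi.linkage_to_newick(Z, sim.parameters)
        )
        by_cond = {c: g for c, g in scored.groupby("condition", sort=False)}
        xsim = simi.cross_condition_similarity(by_cond, parameters, population)
        xsim.to_frame().to_csv(out / "similarity_cross_condition.csv")
        graph = simi.edge_bundle_graph(xsim, cutoff=cutoff)
        simi.write_graph(graph, json_path=out / "edge_graph.json",
                         graphml_path=out / "edge_graph.graphml")
        manifest["stages"]["similarity"] = {
            "population": population,
            "n_population_cells": sim.n_cells,
            "leaf_order": order,
            "n_edges": graph.number_of_edges(),
        }
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineStageError(stage, exc) from exc

    for f in sorted(out.rglob("*.csv")) + sorted(out.glob("*.json")):
        manifest["artifacts"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
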