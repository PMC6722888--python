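"""Normalization, condition comparison and spatial heat maps.

Marker intensities are standardized as Z-scores pooled over all cells that
enter a comparison, after clipping each channel at its 99th percentile
(hot-pixel robustness; the clip percentile is a parameter).  Group
differences are tested channel-by-channel with the two-tailed Mann-Whitney
U test (an unpaired t-test is available as an alternative); P values are
reported raw, without multiple-testing correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import mean_column
from .io import LabelMask

SIZE_COLUMNS = ["area_um2", "perimeter_um", "major_axis_um", "minor_axis_um"]


def resolve_column(table: pd.DataFrame, name: str) -> str:
    """Map a marker or column name onto an existing table column."""
    if name in table.columns:
        return name
    cand = mean_column(name)
    if cand in table.columns:
        return cand
    raise KeyError(f"no column for {name!r} (tried {name!r} and {cand!r})")


def zscore(
    table: pd.DataFrame,
    channels: list[str],
    clip_percentile: float | None = 99.0,
) -> pd.DataFrame:
    """Add ``z_<name>`` columns: percentile-clipped, pooled Z-scores.

    Per channel, values above the ``clip_percentile``-th percentile of the
    pooled table are set to that percentile, then z = (x - mean)/sd with the
    sample (ddof=1) standard deviation.  Constant columns map to all-zeros.
    """
    if len(table) == 0:
        raise ValueError("cannot z-score an empty table")
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 cells")
    out = table.copy()
    for name in channels:
        col = resolve_column(table, name)
        x = table[col].to_numpy(dtype=float)
        if clip_percentile is not None:
            cap = np.percentile(x, clip_percentile)
            x = np.minimum(x, cap)
        sd = x.std(ddof=1)
        zname = "z_" + col.removeprefix("mean_")
        out[zname] = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    return out


def z_column(table: pd.DataFrame, name: str) -> str:
    """Existing z-column for a marker/column name."""
    for cand in (f"z_{name}", "z_" + resolve_column(table, name).removeprefix("mean_")):
        if cand in table.columns:
            return cand
    raise KeyError(f"no z-scored column for {name!r}; run zscore() first")


def mann_whitney(a, b, method: str = "auto") -> dict[str, float]:
    """Two-sided Mann-Whitney U test.

    ``method='auto'`` uses the exact null distribution when the pooled
    sample is small (n_a + n_b <= 12) and tie-free, otherwise the normal
    approximation with tie and continuity corrections.  Returns the U
    statistic of the first sample and the two-tailed P value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (a.size + b.size <= 12 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return {"U": float(res.statistic), "P_two_tailed": float(res.pvalue)}


def unpaired_t(a, b) -> dict[str, float]:
    """Welch-free classic unpaired two-sided t-test (pooled variance)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return {"t": float(res.statistic), "P_two_tailed": float(res.pvalue)}


def compare_conditions(
    table: pd.DataFrame,
    channels: list[str],
    reference_conditions: list[str],
    test: str = "mann-whitney",
    alpha: float = 0.05,
    use_z: bool = True,
) -> pd.DataFrame:
    """Per-channel statistics of every non-reference condition vs references.

    For each channel and each (condition, reference) pair: group means,
    SEM = sd/sqrt(n), the test statistic and two-tailed P, and a
    significance flag at ``alpha``.  Values are taken from the z-scored
    columns when present (``use_z``), else from the raw means.
    """
    conditions = list(dict.fromkeys(table["condition"]))
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions to compare")
    for ref in reference_conditions:
        if ref not in conditions:
            raise KeyError(f"unknown reference condition {ref!r}")
    others = [c for c in conditions if c not in reference_conditions]

    rows = []
    for name in channels:
        if use_z:
            try:
                col = z_column(table, name)
            except KeyError:
                col = resolve_column(table, name)
        else:
            col = resolve_column(table, name)
        for cond in others:
            x = table.loc[table["condition"] == cond, col].to_numpy(float)
            for ref in reference_conditions:
                y = table.loc[table["condition"] == ref, col].to_numpy(float)
                if test == "mann-whitney":
                    r = mann_whitney(x, y)
                    stat_name, stat = "U", r["U"]
                elif test == "t":
                    r = unpaired_t(x, y)
                    stat_name, stat = "t", r["t"]
                else:
                    raise ValueError(f"unknown test {test!r}")
                p = r["P_two_tailed"]
                rows.append({
                    "channel": name,
                    "condition": cond,
                    "reference": ref,
                    "column": col,
                    "mean": x.mean(),
                    "sem": x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0,
                    "ref_mean": y.mean(),
                    "ref_sem": y.std(ddof=1) / np.sqrt(y.size) if y.size > 1 else 0.0,
                    "n": x.size,
                    "ref_n": y.size,
                    "statistic": stat,
                    "statistic_name": stat_name,
                    "P_two_tailed": p,
                    "significant": bool(p < alpha),
                })
    out = pd.DataFrame(rows)
    out.attrs["note"] = "raw per-channel P values; no multiplicity correction"
    return out


def spatial_heatmap(
    mask: LabelMask,
    table: pd.DataFrame,
    channel_z: str,
) -> np.ndarray:
    """Paint each cell's pixels with its Z-score; background is NaN.

    Every mask label must have a row in ``table`` (matched on ``cell_id``);
    missing labels raise with the offending label list.
    """
    col = channel_z if channel_z in table.columns else z_column(table, channel_z)
    values = dict(zip(table["cell_id"].astype(int), table[col].astype(float)))
    labels = mask.labels
    missing = [int(l) for l in np.unique(labels) if l > 0 and int(l) not in values]
    if missing:
        raise KeyError(f"mask labels missing from table: {missing[:10]}")
    img = np.full(labels.shape, np.nan, dtype=float)
    for lab, v in values.items():
        img[labels == lab] = v
    return img


def render_spatial_heatmaps(
    images: list[np.ndarray],
    titles: list[str] | None = None,
    vmax: float | None = None,
    cmap: str = "coolwarm",
):
    """Render one or more Z-score heat maps on a shared symmetric scale.

    A single color scale across ROIs keeps their spatial patterns
    comparable; ``vmax`` defaults to the largest |z| over all images.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if vmax is None:
        vmax = max(float(np.nanmax(np.abs(im))) for im in images if np.isfinite(im).any())
    fig, axes = plt.subplots(1, len(images), figsize=(4 * len(images), 4),
                             squeeze=False)
    for i, (ax, im) in enumerate(zip(axes[0], images)):
        h = ax.imshow(im, cmap=cmap, vmin=-vmax, vmax=vmax)
        ax.set_axis_off()
        if titles:
            ax.set_title(titles[i])
    fig.colorbar(h, ax=axes[0], shrink=0.8, label="Z-score")
    return fig
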