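"""t-SNE embedding of single-cell feature profiles.

Cells are embedded in 2D from their Z-scored marker intensities and size
parameters (t-distributed stochastic neighbor embedding, PCA-initialized,
perplexity 30 by default, fixed seed recorded in the result).  Feature
columns are sorted canonically before fitting, so the embedding does not
depend on the column order of the input table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

#: palette roles for condition coloring
CONDITION_COLORS = {
    "nontreated": "tab:blue",
    "DMSO": "tab:red",
    "EGF": "tab:green",
    "etoposide": "black",
    "nocodazole": "purple",
}


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # N x 2
    feature_names: list[str]
    seed: int
    perplexity: float

    def to_frame(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates, columns=["tsne1", "tsne2"])
        if table is not None:
            df.insert(0, "cell_id", table["cell_id"].to_numpy())
        return df


def tsne_embed(
    table: pd.DataFrame,
    feature_names: list[str] | None = None,
    seed: int = 42,
    perplexity: float = 30.0,
) -> EmbeddingResult:
    """Embed cells in 2D with t-SNE on the given (z-scored) features.

    ``feature_names`` defaults to every ``z_`` column of the table; run
    ``stats.zscore`` over markers and size parameters first.  Requires
    N > 3 * perplexity cells; deterministic for a fixed seed.
    """
    if feature_names is None:
        feature_names = [c for c in table.columns if c.startswith("z_")]
        if not feature_names:
            raise ValueError("no z_ columns found; z-score features first")
    feature_names = sorted(feature_names)  # canonical order
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise KeyError(f"feature column(s) missing: {missing}")
    n = len(table)
    if n <= 3 * perplexity:
        raise ValueError(
            f"N={n} too small for perplexity={perplexity}; need N > {3 * perplexity:g}"
        )
    X = table.loc[:, feature_names].to_numpy(dtype=float)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        learning_rate="auto",
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    return EmbeddingResult(np.asarray(coords, dtype=float),
                           list(feature_names), int(seed), float(perplexity))


def plot_embedding(
    result: EmbeddingResult,
    table: pd.DataFrame,
    color_by: str = "condition",
    ax=None,
):
    """Scatter the embedding colored by condition or by a single feature."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xy = result.coordinates
    if color_by == "condition":
        for cond, grp in table.reset_index(drop=True).groupby("condition", sort=False):
            idx = grp.index.to_numpy()
            ax.scatter(xy[idx, 0], xy[idx, 1], s=4,
                       color=CONDITION_COLORS.get(cond), label=cond)
        ax.legend(markerscale=3, fontsize=8)
    else:
        sc = ax.scatter(xy[:, 0], xy[:, 1], s=4, c=table[color_by], cmap="viridis")
        ax.figure.colorbar(sc, ax=ax, label=color_by)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    return ax
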