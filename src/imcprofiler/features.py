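"""Per-cell measurement extraction.

For every segmented cell we record the mean ion count of each panel channel
over the whole-cell mask plus the standard morphology descriptors: area,
perimeter, major/minor axis of the second-moment ellipse, eccentricity and
centroid.  Lengths are reported in micrometres, areas in um^2 (pixel size
from the stack).

Intensities are measured over the whole-cell mask for every channel,
regardless of its compartment annotation: the output schema carries one mean
per marker per cell.  The perimeter estimator is the weighted
boundary-step contour length of ``skimage.measure.regionprops`` (Benkrid's
weights), pinned here so tests can rely on it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops_table

from .io import LabelMask, ROIStack, TABLE_LEAD_COLUMNS


def mean_column(marker: str) -> str:
    """Column name carrying the mean intensity of *marker*."""
    return f"mean_{marker}"


def extract_features(
    stack: ROIStack,
    cells: LabelMask,
    nuclei: LabelMask | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Quantify every cell of ``cells`` on ``stack``.

    Parameters
    ----------
    stack
        Multichannel ion-count image.
    cells
        Whole-cell label mask (labels are the cell ids).
    nuclei
        Optional matching nuclei mask; when given, its label set must equal
        the cell mask's (the segmentation contract), otherwise a
        ``ValueError`` is raised.
    condition
        Treatment condition recorded in the output; defaults to the stack's.

    Returns
    -------
    DataFrame with one row per cell, sorted by ``cell_id``, columns
    ``cell_id, roi_id, condition, centroid_x_um, centroid_y_um, area_um2,
    perimeter_um, major_axis_um, minor_axis_um, eccentricity`` and one
    ``mean_<marker>`` per panel channel.
    """
    h, w, _ = stack.shape
    if cells.labels.shape != (h, w):
        raise ValueError(
            f"cell mask shape {cells.labels.shape} does not match stack {(h, w)}"
        )
    if nuclei is not None:
        if nuclei.labels.shape != (h, w):
            raise ValueError("nuclei mask shape does not match stack")
        cell_ids = set(cells.label_ids.tolist())
        nuc_ids = set(nuclei.label_ids.tolist())
        if cell_ids != nuc_ids:
            raise ValueError(
                "cell and nuclei label sets differ: "
                f"only-cells={sorted(cell_ids - nuc_ids)[:5]} "
                f"only-nuclei={sorted(nuc_ids - cell_ids)[:5]}"
            )

    ps = stack.pixel_size
    condition = stack.condition if condition is None else condition
    labels = cells.labels
    ids = cells.label_ids

    if ids.size == 0:
        cols = TABLE_LEAD_COLUMNS + [mean_column(m) for m in stack.panel.markers]
        return pd.DataFrame(columns=cols)

    props = regionprops_table(
        labels,
        properties=(
            "label", "area", "perimeter",
            "axis_major_length", "axis_minor_length",
            "eccentricity", "centroid",
        ),
    )
    df = pd.DataFrame(
        {
            "cell_id": props["label"].astype(int),
            "roi_id": stack.roi_id,
            "condition": condition,
            "centroid_x_um": props["centroid-1"] * ps,
            "centroid_y_um": props["centroid-0"] * ps,
            "area_um2": props["area"] * ps * ps,
            "perimeter_um": props["perimeter"] * ps,
            "major_axis_um": props["axis_major_length"] * ps,
            "minor_axis_um": props["axis_minor_length"] * ps,
            "eccentricity": props["eccentricity"],
        }
    )
    # regionprops_table orders by label already, but make the contract explicit
    order = np.argsort(df["cell_id"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    sorted_ids = df["cell_id"].to_numpy()

    for c, marker in enumerate(stack.panel.markers):
        means = ndi.mean(stack.pixels[:, :, c], labels=labels, index=sorted_ids)
        df[mean_column(marker)] = np.asarray(means, dtype=float)
    return df
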