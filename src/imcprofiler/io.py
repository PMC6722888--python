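"""On-disk artifacts: multichannel TIFF stacks, label-mask TIFFs, CSV tables.

The ingestion boundary is the TIFF export of an IMC acquisition: one
grayscale page per isotope channel, 16- or 32-bit, 1 um per pixel.  Object
masks are single-page unsigned 16-bit TIFFs (0 = background, k > 0 = object
k), and per-cell measurement tables are plain CSV so they diff and round-trip
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .panel import ChannelPanel

MASK_MAX_LABEL = 65535


@dataclass
class ROIStack:
    """One acquired region of interest: H x W x C nonnegative ion counts."""

    pixels: np.ndarray
    panel: ChannelPanel
    pixel_size: float = 1.0  # um per pixel
    roi_id: str = "roi"
    condition: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be H x W x C, got shape {self.pixels.shape}")
        h, w, c = self.pixels.shape
        if h < 1 or w < 1:
            raise ValueError("empty image")
        if c != len(self.panel):
            raise ValueError(
                f"stack has {c} channels but panel has {len(self.panel)}"
            )
        if np.any(self.pixels < 0):
            raise ValueError("ion counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def channel(self, marker: str) -> np.ndarray:
        """2D image of one marker, selected by name."""
        return self.pixels[:, :, self.panel.index(marker)]


@dataclass
class LabelMask:
    """Integer object mask; 0 is background, labels identify objects."""

    labels: np.ndarray
    kind: str = "cells"  # "nuclei" | "cells"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if np.any(self.labels < 0):
            raise ValueError("labels must be nonnegative")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.label_ids.size)


# ---------------------------------------------------------------------------
# stacks


def _sidecar_panel_path(path: Path) -> Path:
    return path.with_suffix(".panel.csv")


def write_stack(stack: ROIStack, path, bit_depth: int = 16) -> Path:
    """Write a multipage TIFF, one page per channel in panel order.

    Channel names go into per-page descriptions; ROI metadata rides in the
    first page description; a sidecar panel CSV is written alongside.
    16-bit writing refuses to clip: values above 65535 are an error.
    """
    path = Path(path)
    data = np.asarray(stack.pixels)
    if bit_depth == 16:
        rounded = np.rint(data)
        if rounded.max(initial=0) > 65535:
            raise ValueError(
                f"value {data.max():g} exceeds the 16-bit range; "
                "use bit_depth=32 or rescale"
            )
        pages = rounded.astype(np.uint16)
    elif bit_depth == 32:
        pages = data.astype(np.float32)
    else:
        raise ValueError("bit_depth must be 16 or 32")

    meta = {
        "roi_id": stack.roi_id,
        "condition": stack.condition,
        "pixel_size_um": stack.pixel_size,
    }
    with tifffile.TiffWriter(path) as tw:
        for c, ch in enumerate(stack.panel):
            desc = json.dumps({"marker": ch.marker, **(meta if c == 0 else {})})
            tw.write(
                pages[:, :, c],
                photometric="minisblack",
                description=desc,
                contiguous=False,
            )
    stack.panel.to_csv(_sidecar_panel_path(path))
    return path


def read_stack(path, panel: ChannelPanel | None = None) -> ROIStack:
    """Read a multipage TIFF stack back into an :class:`ROIStack`.

    Panel resolution order: explicit argument, sidecar CSV, auto-named
    fallback (ch00.. with compartment ``any``).  Page order defines channel
    order; no reordering happens on read.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
        desc0 = tf.pages[0].description
    data = np.stack(pages, axis=-1)

    if panel is None:
        sidecar = _sidecar_panel_path(path)
        if sidecar.exists():
            panel = ChannelPanel.from_csv(sidecar)
        else:
            panel = ChannelPanel.auto_named(data.shape[-1])
    if len(panel) != data.shape[-1]:
        raise ValueError(
            f"TIFF has {data.shape[-1]} pages but panel has {len(panel)} channels"
        )

    roi_id, condition, pixel_size = path.stem, "", 1.0
    try:
        meta = json.loads(desc0)
        roi_id = meta.get("roi_id", roi_id)
        condition = meta.get("condition", condition)
        pixel_size = float(meta.get("pixel_size_um", pixel_size))
    except (json.JSONDecodeError, TypeError):
        pass
    return ROIStack(data, panel, pixel_size=pixel_size, roi_id=roi_id,
                    condition=condition)


# ---------------------------------------------------------------------------
# label masks


def write_mask(mask: LabelMask, path) -> Path:
    """Persist a label mask as a single-page unsigned 16-bit TIFF."""
    path = Path(path)
    labels = mask.labels
    if labels.max(initial=0) > MASK_MAX_LABEL:
        raise ValueError(
            f"label {int(labels.max())} exceeds the unsigned 16-bit mask limit "
            f"({MASK_MAX_LABEL})"
        )
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack",
                     description=json.dumps({"kind": mask.kind}))
    return path


def read_mask(path, kind: str | None = None) -> LabelMask:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        labels = tf.pages[0].asarray()
        desc = tf.pages[0].description
    if kind is None:
        try:
            kind = json.loads(desc).get("kind", "cells")
        except (json.JSONDecodeError, TypeError):
            kind = "cells"
    return LabelMask(labels.astype(np.int64), kind=kind)


# ---------------------------------------------------------------------------
# cell tables

#: canonical column order for the leading (non-intensity) columns
TABLE_LEAD_COLUMNS = [
    "cell_id", "roi_id", "condition",
    "centroid_x_um", "centroid_y_um",
    "area_um2", "perimeter_um", "major_axis_um", "minor_axis_um",
    "eccentricity",
]


def write_cell_table(table: pd.DataFrame, path) -> Path:
    """Write a per-cell measurement table as CSV (header always present)."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell CSV; unknown columns are preserved verbatim."""
    df = pd.read_csv(path)
    # an empty table reads back with object dtype; that is fine
    return df
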