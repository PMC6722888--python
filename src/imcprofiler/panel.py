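"""Antibody panel handling.

An imaging-mass-cytometry acquisition is a stack of single-isotope ion-count
images; the *panel* is the ordered list of metal-conjugated antibodies that
defines which page of the stack is which marker.  Each channel additionally
carries a coarse subcellular *compartment* annotation (nucleus, cytoplasm,
membrane or any) used by the synthetic renderer to decide where signal is
deposited.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

COMPARTMENTS = ("nucleus", "cytoplasm", "membrane", "any")


@dataclass(frozen=True)
class Channel:
    """One isotope channel: metal tag, marker name and compartment class."""

    metal_tag: str
    marker: str
    compartment: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for marker "
                f"{self.marker!r}; expected one of {COMPARTMENTS}"
            )


class ChannelPanel(Sequence[Channel]):
    """Ordered, immutable list of channels; order defines stack page order."""

    def __init__(self, channels: Iterable[Channel]):
        self._channels = tuple(channels)
        markers = [c.marker for c in self._channels]
        if len(set(markers)) != len(markers):
            raise ValueError("duplicate marker names in panel")

    def __len__(self) -> int:
        return len(self._channels)

    def __getitem__(self, i):
        return self._channels[i]

    def __iter__(self) -> Iterator[Channel]:
        return iter(self._channels)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChannelPanel) and self._channels == other._channels

    def __repr__(self) -> str:
        return f"ChannelPanel({len(self)} channels)"

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self._channels]

    def index(self, marker: str) -> int:
        """Stack page index of *marker*; raises KeyError if absent."""
        for i, c in enumerate(self._channels):
            if c.marker == marker:
                return i
        raise KeyError(f"marker {marker!r} not in panel")

    def __contains__(self, marker) -> bool:
        if isinstance(marker, Channel):
            return marker in self._channels
        return marker in self.markers

    def markers_by_compartment(self, compartment: str) -> list[str]:
        return [c.marker for c in self._channels if c.compartment == compartment]

    # ---- persistence (CSV with columns metal_tag,marker,compartment) ----

    def to_csv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metal_tag", "marker", "compartment"])
            for c in self._channels:
                w.writerow([c.metal_tag, c.marker, c.compartment])
        return path

    @classmethod
    def from_csv(cls, path) -> "ChannelPanel":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            Channel(r["metal_tag"], r["marker"], r["compartment"]) for r in rows
        )

    @classmethod
    def auto_named(cls, n: int) -> "ChannelPanel":
        """Fallback panel of ``n`` anonymous channels (ch00..), compartment any."""
        return cls(
            Channel(f"ch{i:02d}", f"ch{i:02d}", "any") for i in range(n)
        )


# Default MCF-7 profiling panel: 29 isotope channels covering DNA content,
# viability, cell-cycle and signalling state (nuclear), cytoskeleton
# (cytoplasmic) and adhesion/surface phenotype (membrane), plus a carrier
# blank.  The metal assignments are conventional lanthanide/platinum-group
# choices; downstream code keys on marker names only.
_DEFAULT_PANEL_ROWS = [
    ("Ir191", "Ir191-DNA", "nucleus"),
    ("Ir193", "Ir193-DNA", "nucleus"),
    ("Rh103", "Rh103-viability", "any"),
    ("I127", "IdU", "nucleus"),
    ("Gd156", "pHistone3-S28", "nucleus"),
    ("Dy164", "pH2A.X-S139", "nucleus"),
    ("Er168", "Ki-67", "nucleus"),
    ("Sm152", "p53", "nucleus"),
    ("Tb159", "cyclin B1", "nucleus"),
    ("Er170", "cyclin D3", "nucleus"),
    ("Ho165", "p4E-BP1-T37/T46", "nucleus"),
    ("Yb174", "cPARP", "nucleus"),
    ("Nd146", "ERa", "nucleus"),
    ("Lu175", "pan-keratin", "cytoplasm"),
    ("Nd148", "CK19", "cytoplasm"),
    ("Eu153", "MUC-1", "membrane"),
    ("Nd150", "EpCAM", "membrane"),
    ("Sm147", "CD29", "membrane"),
    ("Yb171", "CD81", "membrane"),
    ("Nd144", "CD98", "membrane"),
    ("Sm149", "CD47", "membrane"),
    ("Gd155", "CD49e", "membrane"),
    ("Eu151", "E-cadherin", "membrane"),
    ("Nd143", "EGFR", "membrane"),
    ("Sm154", "HER2", "membrane"),
    ("Gd158", "CD107b", "membrane"),
    ("Nd145", "vimentin", "cytoplasm"),
    ("Tm169", "CK5", "cytoplasm"),
    ("Pt195", "carrier-blank", "any"),
]


def make_default_panel() -> ChannelPanel:
    """The default 29-channel MCF-7 drug-profiling panel.

    Stable across calls: repeated invocations return equal panels with
    identical channel order.
    """
    return ChannelPanel(Channel(*row) for row in _DEFAULT_PANEL_ROWS)
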