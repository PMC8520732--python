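"""FACS-style gating of two-channel mKeima populations.

Per-cell events carry (i_neutral, i_low): emission after 488 nm and 561 nm
excitation.  Analysis is two gates deep: an mKeima-positive gate (total
intensity threshold; scatter-based singlet gating is out of scope) and a
region-of-interest gate in log10 intensity space whose occupancy percentage
is the readout.  Boundary points count as inside (deterministic tie rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .sim.facs import FACSEvent

__all__ = ["Gate", "gate_positive", "roi_fraction"]


@dataclass(frozen=True)
class Gate:
    """A named gate: axis thresholds or a polygon in log10 space.

    ``threshold`` kind: ``params`` maps axis name (``log_i_neutral`` /
    ``log_i_low``) to (lo, hi) bounds, None meaning unbounded.
    ``polygon`` kind: ``params["vertices"]`` is a list of
    (log10 i_neutral, log10 i_low) vertices of a simple polygon.
    """

    name: str
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "polygon"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind == "polygon":
            verts = self.params.get("vertices", [])
            if len(verts) < 3:
                raise ValueError("polygon gate needs >= 3 vertices")
            if not Polygon(verts).is_simple:
                raise ValueError("polygon gate must be simple (non-self-intersecting)")

    def contains(self, event: FACSEvent) -> bool:
        return bool(self.contains_many([event])[0])

    def contains_many(self, events: list[FACSEvent]) -> np.ndarray:
        x = np.log10([e.i_neutral for e in events])
        y = np.log10([e.i_low for e in events])
        if self.kind == "threshold":
            keep = np.ones(len(events), dtype=bool)
            for axis, value in (("log_i_neutral", x), ("log_i_low", y)):
                lo, hi = self.params.get(axis, (None, None))
                if lo is not None:
                    keep &= value >= lo
                if hi is not None:
                    keep &= value <= hi
            return keep
        poly = Polygon(self.params["vertices"])
        # intersects includes the boundary, the deterministic tie rule
        return shapely.intersects_xy(poly, x, y)


def gate_positive(events: list[FACSEvent], min_total: float = 0.0) -> list[FACSEvent]:
    """Keep mKeima-positive cells: i_neutral + i_low >= min_total."""
    if not events:
        raise ValueError("no events to gate")
    return [e for e in events if e.i_neutral + e.i_low >= min_total]


def roi_fraction(events: list[FACSEvent], gate: Gate) -> float:
    """Percentage of gated events inside the region of interest."""
    if not events:
        raise ValueError("ROI fraction undefined on an empty event subset")
    inside = int(gate.contains_many(events).sum())
    return 100.0 * inside / len(events)
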