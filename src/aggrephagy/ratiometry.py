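"""Per-particle mKeima ratios, histograms, and clearance statistics.

The mKeima ratio of a particle is I(ex445) / (I(ex445) + I(ex561)) on
background-subtracted integrated intensities: near 1 for a particle in the
neutral cytosol, near 0 inside an acidic lysosome.  A particle is scored
"cleared" (delivered to the lysosome) when its ratio falls strictly below
0.35, and the cleared fraction of a condition is the unweighted mean of the
per-experiment fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLEARANCE_THRESHOLD",
    "RatioRecord",
    "ClearanceSummary",
    "mkeima_ratio",
    "classify_acidified",
    "ratio_histogram",
    "clearance_summary",
    "records_from_detections",
]

#: Ratio below which a particle is scored as residing in an acidic
#: (lysosomal) environment.
CLEARANCE_THRESHOLD = 0.35


@dataclass(frozen=True)
class RatioRecord:
    """One particle's ratio measurement within a replicate/condition."""

    particle_id: int
    frame: int
    ratio: float
    acidified: bool
    replicate_id: str
    condition: str


@dataclass(frozen=True)
class ClearanceSummary:
    """Cleared fractions per replicate and their unweighted mean."""

    fractions: tuple[float, ...]
    n_particles: tuple[int, ...]
    threshold: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def percent(self) -> float:
        return 100.0 * self.mean


def mkeima_ratio(i445: float, i561: float) -> float:
    """i445 / (i445 + i561), in [0, 1]; undefined when both are zero."""
    if i445 < 0 or i561 < 0:
        raise ValueError("intensities must be non-negative")
    total = i445 + i561
    if total == 0:
        raise ValueError("ratio undefined for zero total intensity")
    return float(i445 / total)


def classify_acidified(ratio: float, threshold: float = CLEARANCE_THRESHOLD) -> bool:
    """True iff ratio < threshold (strict)."""
    if not (0.0 <= ratio <= 1.0):
        raise ValueError(f"ratio must be in [0, 1], got {ratio}")
    return ratio < threshold


def ratio_histogram(ratios, bin_width: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Normalized ratio histogram over [0, 1].

    Bins are left-closed right-open, the last bin closed; returns
    (bin_edges, fractions) with fractions summing to 1.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("cannot histogram an empty ratio list")
    if np.any((ratios < 0) | (ratios > 1)):
        raise ValueError("ratios must lie in [0, 1]")
    n_bins = int(np.ceil(1.0 / bin_width - 1e-12))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts, _ = np.histogram(ratios, bins=edges)
    return edges, counts / ratios.size


def records_from_detections(
    detections: pd.DataFrame,
    replicate_id: str = "rep1",
    condition: str = "control",
    threshold: float = CLEARANCE_THRESHOLD,
) -> list[RatioRecord]:
    """Build ratio records from a detections table.

    Border-flagged detections and zero-total particles are excluded (the
    ratio is undefined or unreliable for them).
    """
    records = []
    for idx, row in detections.iterrows():
        flags = str(row.get("flags", "") or "")
        if "border" in flags:
            continue
        total = row["i445"] + row["i561"]
        if total <= 0:
            continue
        ratio = mkeima_ratio(row["i445"], row["i561"])
        records.append(RatioRecord(
            particle_id=int(idx),
            frame=int(row["frame"]),
            ratio=ratio,
            acidified=classify_acidified(ratio, threshold),
            replicate_id=replicate_id,
            condition=condition,
        ))
    return records


def clearance_summary(
    records_by_replicate: dict[str, list[RatioRecord]],
    threshold: float = CLEARANCE_THRESHOLD,
    method: str = "count",
    bin_width: float = 0.05,
) -> ClearanceSummary:
    """Cleared fraction per replicate, averaged without weighting.

    ``method="count"`` (canonical) counts ratios strictly below
    ``threshold``.  ``method="histogram"`` sums histogram fractions of the
    bins wholly below the threshold, the alternative stated form of the
    rule (bin-dependent, kept for comparability).
    """
    fractions, ns = [], []
    for rep, records in records_by_replicate.items():
        ratios = np.array([r.ratio for r in records])
        if ratios.size == 0:
            warnings.warn(f"replicate {rep!r} has no valid records; excluded")
            continue
        if method == "count":
            frac = float(np.mean(ratios < threshold))
        elif method == "histogram":
            edges, freqs = ratio_histogram(ratios, bin_width)
            keep = edges[1:] <= threshold + 1e-12
            frac = float(freqs[keep].sum())
        else:
            raise ValueError(f"unknown method {method!r}")
        fractions.append(frac)
        ns.append(int(ratios.size))
    if not fractions:
        raise ValueError("no replicate contained valid records")
    return ClearanceSummary(tuple(fractions), tuple(ns), threshold)


def records_to_frame(records: list[RatioRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
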