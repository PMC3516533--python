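"""Range-change accounting and 2-D binned gain/loss summaries.

Gains and losses are counted against the *observed* current occurrence:
a gain is a cell projected suitable in the future where the species is
currently absent, a loss is a currently occupied cell projected
unsuitable, and both are reported relative to the number of currently
occupied cells (so gain percentages above 100 are expected for range
expansions).  A modelled-current variant is available behind a flag for
sensitivity analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid_io import (
    ABSENT,
    PRESENT,
    UNKNOWN,
    BinaryRangeMap,
    ClimateLayerSet,
    OccurrenceMap,
    assert_aligned,
)

__all__ = [
    "RangeChangeSummary",
    "BinnedGainLoss",
    "range_change",
    "binned_gain_loss",
    "change_table",
]


@dataclass(frozen=True)
class RangeChangeSummary:
    """Counts and percentages of projected range change for one map pair."""

    n_current: int
    n_gain: int
    n_loss: int
    n_stable: int
    gain_pct: float
    loss_pct: float
    relative_change: float
    n_gain_unknown_status: int = 0

    def as_row(self) -> dict:
        return {
            "n_current": self.n_current,
            "n_gain": self.n_gain,
            "n_loss": self.n_loss,
            "n_stable": self.n_stable,
            "gain_pct": round(self.gain_pct, 2),
            "loss_pct": round(self.loss_pct, 2),
            "relative_change": round(self.relative_change, 4),
            "n_gain_unknown_status": self.n_gain_unknown_status,
        }


def range_change(
    current_observed: OccurrenceMap, future_binary: BinaryRangeMap
) -> RangeChangeSummary:
    """Gains, losses and relative change of ``future_binary`` vs observation.

    Cells with unknown current status are excluded from the main counts;
    projected-suitable unknown cells are reported separately.
    """
    assert_aligned(current_observed, future_binary)
    status = current_observed.status
    future = future_binary.presence
    present = status == PRESENT
    absent = status == ABSENT
    n_current = int(present.sum())
    if n_current == 0:
        raise ValueError("range change undefined: no currently occupied cells")
    n_gain = int((absent & future).sum())
    n_loss = int((present & ~future).sum())
    n_unknown_gain = int(((status == UNKNOWN) & future & ~future_binary.missing).sum())
    return RangeChangeSummary(
        n_current=n_current,
        n_gain=n_gain,
        n_loss=n_loss,
        n_stable=n_current - n_loss,
        gain_pct=100.0 * n_gain / n_current,
        loss_pct=100.0 * n_loss / n_current,
        relative_change=(n_gain - n_loss) / n_current,
        n_gain_unknown_status=n_unknown_gain,
    )


@dataclass(frozen=True)
class BinnedGainLoss:
    """Per-bin gain/loss counts over two climate variables."""

    v1: str
    v2: str
    edges_v1: np.ndarray
    edges_v2: np.ndarray
    gain_counts: np.ndarray  # (n_bins_v1, n_bins_v2)
    loss_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.edges_v1) - 1):
            for j in range(len(self.edges_v2) - 1):
                rows.append(
                    {
                        "v1_bin_lo": self.edges_v1[i],
                        "v1_bin_hi": self.edges_v1[i + 1],
                        "v2_bin_lo": self.edges_v2[j],
                        "v2_bin_hi": self.edges_v2[j + 1],
                        "n_gain": int(self.gain_counts[i, j]),
                        "n_loss": int(self.loss_counts[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _edges(values: np.ndarray, n_bins: int, name: str) -> np.ndarray:
    lo, hi = np.nanmin(values), np.nanmax(values)
    if lo == hi:
        warnings.warn(f"variable {name!r} is constant: using a single bin")
        return np.array([lo - 0.5, hi + 0.5])
    return np.linspace(lo, hi, n_bins + 1)


def binned_gain_loss(
    current_observed: OccurrenceMap,
    future_binary: BinaryRangeMap,
    layers: ClimateLayerSet,
    v1: str,
    v2: str,
    n_bins: int = 20,
) -> BinnedGainLoss:
    """Histogram gain and loss cells over two climate variables.

    Bins are equal-width over each variable's observed range across all
    non-missing cells, with the final bin right-closed (numpy histogram
    convention), so every gain/loss cell with finite climate lands in
    exactly one bin and per-bin counts conserve the summary totals.
    """
    assert_aligned(current_observed, layers)
    assert_aligned(future_binary, layers)
    for v in (v1, v2):
        if v not in layers.variables:
            raise KeyError(f"variable {v!r} not in layer set")
    x1, x2 = layers.variables[v1], layers.variables[v2]
    edges1 = _edges(x1, n_bins, v1)
    edges2 = _edges(x2, n_bins, v2)
    status = current_observed.status
    gain = (status == ABSENT) & future_binary.presence
    loss = (status == PRESENT) & ~future_binary.presence & ~future_binary.missing
    finite = np.isfinite(x1) & np.isfinite(x2)
    gain_counts, _, _ = np.histogram2d(x1[gain & finite], x2[gain & finite], bins=[edges1, edges2])
    loss_counts, _, _ = np.histogram2d(x1[loss & finite], x2[loss & finite], bins=[edges1, edges2])
    return BinnedGainLoss(v1, v2, edges1, edges2, gain_counts.astype(int), loss_counts.astype(int))


def change_table(results, current_observed: OccurrenceMap) -> pd.DataFrame:
    """One :func:`range_change` row per approach, as a DataFrame.

    ``results`` is an iterable of ``ApproachResult``; each contributes
    its future binary map.
    """
    rows = []
    for result in results:
        summary = range_change(current_observed, result.binary["future"])
        rows.append({"approach": result.approach, **summary.as_row()})
    return pd.DataFrame(rows)
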