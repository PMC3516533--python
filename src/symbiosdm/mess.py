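"""Multivariate Environmental Similarity Surface (MESS) screening.

MESS compares each projection cell with the calibration climate sample.
For one variable with reference sample ``ref`` and projection value
``p``, let ``f`` be 100 times the fraction of reference values strictly
below ``p`` (ties at ``p`` count as not-below).  The component is:

* ``f = 0``:       ``100 * (p - min) / (max - min)``  (negative below the minimum)
* ``0 < f <= 50``: ``2 f``
* ``50 < f < 100``: ``2 (100 - f)``
* ``f = 100``:     ``100 * (max - p) / (max - min)``  (negative above the maximum)

The cell's similarity is the minimum component over variables; negative
values flag non-analogue climate (the projection point lies outside the
calibration range in at least one variable).  Projections into such
cells must be interpreted with caution; the package flags but never
truncates them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid_io import ClimateLayerSet, Grid

__all__ = ["MESSMap", "mess_component", "mess_map", "NEG_INFINITY_SENTINEL"]

#: component value for a point off a degenerate (constant) reference sample
NEG_INFINITY_SENTINEL = -1e9


@dataclass(frozen=True)
class MESSMap:
    """Similarity surface with per-variable components and argmin variable."""

    grid: Grid
    similarity: np.ndarray
    components: dict  # variable -> per-cell component values
    most_dissimilar: np.ndarray  # per-cell variable name (object array)

    def fraction_negative(self) -> float:
        sim = self.similarity[~np.isnan(self.similarity)]
        if sim.size == 0:
            return float("nan")
        return float((sim < 0).mean())


def mess_component(reference_values, p: float) -> float:
    """Similarity of one projection value against one reference sample."""
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("empty reference sample")
    lo, hi = ref.min(), ref.max()
    if hi == lo:
        if p == lo:
            return 0.0
        warnings.warn("constant reference sample: off-value points get -inf sentinel")
        return NEG_INFINITY_SENTINEL
    f = 100.0 * np.count_nonzero(ref < p) / ref.size
    if f == 0.0:
        return float(100.0 * (p - lo) / (hi - lo))
    if f <= 50.0:
        return float(2.0 * f)
    if f < 100.0:
        return float(2.0 * (100.0 - f))
    return float(100.0 * (hi - p) / (hi - lo))


def _component_vector(ref: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Vectorised :func:`mess_component` over projection values."""
    ref = ref[np.isfinite(ref)]
    lo, hi = ref.min(), ref.max()
    out = np.full(values.shape, np.nan)
    ok = np.isfinite(values)
    v = values[ok]
    if hi == lo:
        comp = np.where(v == lo, 0.0, NEG_INFINITY_SENTINEL)
        if (v != lo).any():
            warnings.warn("constant reference sample: off-value points get -inf sentinel")
    else:
        srt = np.sort(ref)
        f = 100.0 * np.searchsorted(srt, v, side="left") / ref.size
        comp = np.where(
            f == 0.0,
            100.0 * (v - lo) / (hi - lo),
            np.where(
                f <= 50.0,
                2.0 * f,
                np.where(f < 100.0, 2.0 * (100.0 - f), 100.0 * (hi - v) / (hi - lo)),
            ),
        )
    out[ok] = comp
    return out


def mess_map(
    calibration_layers: ClimateLayerSet,
    projection_layers: ClimateLayerSet,
    calibration_cells=None,
) -> MESSMap:
    """MESS of projection climate against the calibration climate sample.

    ``calibration_cells`` optionally restricts the reference sample (for
    the reference-area scheme: the host-presence training cells).  The
    most-dissimilar variable per cell is the argmin component, ties
    resolved lexicographically by variable name.
    """
    if set(calibration_layers.variables) != set(projection_layers.variables):
        raise ValueError(
            "variable mismatch between calibration and projection layer sets: "
            f"{sorted(calibration_layers.variables)} vs {sorted(projection_layers.variables)}"
        )
    names = sorted(projection_layers.variables)
    components = {}
    for name in names:
        ref = calibration_layers.variables[name]
        if calibration_cells is not None:
            ref = ref[np.asarray(calibration_cells)]
        components[name] = _component_vector(ref, projection_layers.variables[name])
    stack = np.vstack([components[n] for n in names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        similarity = np.nanmin(stack, axis=0)
    all_nan = np.isnan(stack).all(axis=0)
    similarity[all_nan] = np.nan
    # lexicographic tie-break: first name (names are sorted) achieving the min
    arg = np.argmax(stack == similarity[None, :], axis=0)
    most = np.array(names, dtype=object)[arg]
    most[all_nan] = None
    return MESSMap(projection_layers.grid, similarity, components, most)
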