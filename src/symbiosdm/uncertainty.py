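"""Factorial projection-outcome tables and hierarchical variance partitioning.

The outcome table holds one relative-change value per (algorithm,
approach) combination, each obtained from a *single-member* projection
(no ensemble averaging), mirroring a factorial uncertainty design.  Its
variance is attributed to the factors by hierarchical partitioning on a
Gaussian linear model: ordinary least squares is fitted for every subset
of factors, goodness of fit is R-squared, and each factor's independent
contribution is the average, over all orderings of factor entry, of the
R-squared increase when it enters.  For two factors A and B::

    I_A = 0.5 * [ R2({A}) + ( R2({A,B}) - R2({B}) ) ]

The joint contribution is ``J_k = R2({k}) - I_k``.  Independent
contributions can come out slightly negative; they are reported as-is.
Shares normalise the independent contributions to sum to 100%.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .change_metrics import range_change
from .grid_io import OccurrenceMap

__all__ = [
    "VariancePartition",
    "build_outcome_table",
    "hierarchical_partition",
]


@dataclass(frozen=True)
class VariancePartition:
    """Independent/joint variance contributions per factor."""

    independent: dict  # factor -> I_k (R-squared units)
    joint: dict  # factor -> J_k
    share_pct: dict  # factor -> 100 * I_k / sum(I)
    r2_full: float
    r2_subsets: dict  # frozenset of factors -> R-squared


def build_outcome_table(results: dict, current_observed: OccurrenceMap) -> pd.DataFrame:
    """Relative change per (algorithm, approach) single-member projection.

    ``results`` maps ``(algorithm, approach)`` to an ``ApproachResult``
    (or any object with a future binary map under ``.binary["future"]``).
    The factorial must be complete: every algorithm crossed with every
    approach exactly once.
    """
    if not results:
        raise ValueError("empty results mapping")
    algorithms = sorted({k[0] for k in results})
    approaches = sorted({k[1] for k in results})
    rows = []
    for alg in algorithms:
        for app in approaches:
            if (alg, app) not in results:
                raise ValueError(f"incomplete factorial: missing combination ({alg!r}, {app!r})")
            summary = range_change(current_observed, results[(alg, app)].binary["future"])
            rows.append(
                {"algorithm": alg, "approach": app, "relative_change": summary.relative_change}
            )
    return pd.DataFrame(rows)


def _r_squared(y: np.ndarray, X: np.ndarray | None) -> float:
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        return 0.0
    if X is None or X.shape[1] == 0:
        return 0.0
    D = np.hstack([np.ones((len(y), 1)), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    rss = float(((y - D @ beta) ** 2).sum())
    return 1.0 - rss / tss


def hierarchical_partition(
    table: pd.DataFrame,
    response: str = "relative_change",
    factors=("algorithm", "approach"),
) -> VariancePartition:
    """All-subsets hierarchical partitioning of an outcome table.

    Each factor is entered as a categorical (dummy-encoded) block; R2 is
    computed for every subset of factors and the independent and joint
    contributions follow the ordering-average scheme described in the
    module docstring.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("need at least one factor")
    y = table[response].to_numpy(dtype=float)
    blocks = {}
    for f in factors:
        levels = table[f].astype("category")
        if len(levels.cat.categories) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels: singular fit")
        blocks[f] = pd.get_dummies(levels, drop_first=True).to_numpy(dtype=float)

    r2 = {frozenset(): 0.0}
    for r in range(1, len(factors) + 1):
        for subset in combinations(factors, r):
            X = np.hstack([blocks[f] for f in subset])
            r2[frozenset(subset)] = _r_squared(y, X)

    independent = {}
    n_orders = 0
    for f in factors:
        gains = []
        for order in permutations(factors):
            before = frozenset(order[: order.index(f)])
            gains.append(r2[before | {f}] - r2[before])
        independent[f] = float(np.mean(gains))
        n_orders = len(gains)
    joint = {f: r2[frozenset([f])] - independent[f] for f in factors}
    total_i = sum(independent.values())
    share = {
        f: (100.0 * independent[f] / total_i if total_i != 0 else float("nan"))
        for f in factors
    }
    return VariancePartition(
        independent=independent,
        joint=joint,
        share_pct=share,
        r2_full=r2[frozenset(factors)],
        r2_subsets=r2,
    )
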