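"""Discrimination metrics and probability-to-presence thresholding rules.

AUC is the Mann–Whitney statistic (midrank treatment of ties).  Two
threshold rules are provided: the prevalence of the model-building data
(the default), and the cutoff whose resulting presence fraction best
matches the mean predicted probability.  Binarisation puts ties on the
presence side (``probability >= threshold``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .grid_io import (
    ABSENT,
    PRESENT,
    BinaryRangeMap,
    OccurrenceMap,
    SuitabilityMap,
    assert_aligned,
)

__all__ = [
    "EvaluationReport",
    "auc",
    "prevalence_threshold",
    "mean_probability_threshold",
    "binarize",
    "omission_commission",
    "evaluate",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Test-set discrimination and error rates at one recorded threshold."""

    auc: float | None
    omission_rate: float
    commission_rate: float
    threshold: float
    threshold_method: str
    n_test_presences: int
    n_test_absences: int

    def as_row(self) -> dict:
        """Row for the evaluation table; rates printed as percentages."""
        return {
            "auc": None if self.auc is None else round(self.auc, 4),
            "omission_rate_pct": round(100.0 * self.omission_rate, 2),
            "commission_rate_pct": round(100.0 * self.commission_rate, 2),
            "occurrence_threshold": round(self.threshold, 4),
            "threshold_method": self.threshold_method,
        }


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann–Whitney formulation.

    ``(#concordant pairs + 0.5 * #tied pairs) / (n_pres * n_abs)``,
    computed from midranks in O(n log n).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one presence and one absence")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def prevalence_threshold(occurrence: OccurrenceMap, cells) -> float:
    """Prevalence of the model-building data: #present / #surveyed over ``cells``."""
    cells = np.asarray(cells)
    if cells.size == 0:
        raise ValueError("prevalence threshold undefined on an empty cell set")
    return occurrence.prevalence(cells)


def mean_probability_threshold(suitability: SuitabilityMap) -> float:
    """Cutoff whose presence fraction best matches the mean probability.

    Let ``m`` be the mean probability over non-missing cells.  Scan the
    observed probability values as candidate cutoffs and return the one
    minimising ``|fraction(p >= t) - m|``; ties go to the smaller ``t``.
    """
    p = suitability.probability[~suitability.missing]
    if p.size == 0:
        raise ValueError("no non-missing cells")
    m = p.mean()
    candidates = np.unique(p)
    # fraction of cells >= t for each candidate t, via a sorted scan
    srt = np.sort(p)
    frac = 1.0 - np.searchsorted(srt, candidates, side="left") / p.size
    err = np.abs(frac - m)
    best = np.flatnonzero(err == err.min())
    return float(candidates[best[0]])


def binarize(suitability: SuitabilityMap, threshold: float) -> BinaryRangeMap:
    """Presence iff ``probability >= threshold``; missing cells stay missing."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    missing = suitability.missing
    presence = np.where(missing, False, suitability.probability >= threshold)
    return BinaryRangeMap(
        suitability.grid,
        suitability.species,
        suitability.period,
        presence,
        float(threshold),
        missing,
    )


def omission_commission(predicted: BinaryRangeMap, observed: OccurrenceMap, cells):
    """(omission, commission) = (FN/(FN+TP), FP/(FP+TN)) over ``cells``."""
    assert_aligned(predicted, observed)
    cells = np.asarray(cells)
    status = observed.status[cells]
    pred = predicted.presence[cells]
    known = status != -1
    status, pred = status[known], pred[known]
    obs_pres = status == PRESENT
    obs_abs = status == ABSENT
    if obs_pres.sum() == 0:
        raise ValueError("omission rate undefined: no observed presences among cells")
    if obs_abs.sum() == 0:
        raise ValueError("commission rate undefined: no observed absences among cells")
    omission = float((obs_pres & ~pred).sum() / obs_pres.sum())
    commission = float((obs_abs & pred).sum() / obs_abs.sum())
    return omission, commission


def evaluate(
    suitability: SuitabilityMap,
    observed: OccurrenceMap,
    test_cells,
    threshold: float,
    threshold_method: str = "prevalence",
) -> EvaluationReport:
    """AUC plus omission/commission of the thresholded map on test cells."""
    assert_aligned(suitability, observed)
    cells = np.asarray(test_cells)
    known = (observed.status[cells] != -1) & ~suitability.missing[cells]
    cells = cells[known]
    status = observed.status[cells]
    scores = suitability.probability[cells]
    the_auc = None
    if (status == PRESENT).any() and (status == ABSENT).any():
        the_auc = auc(scores, status == PRESENT)
    binary = binarize(suitability, threshold)
    omission, commission = omission_commission(binary, observed, cells)
    return EvaluationReport(
        auc=the_auc,
        omission_rate=omission,
        commission_rate=commission,
        threshold=float(threshold),
        threshold_method=threshold_method,
        n_test_presences=int((status == PRESENT).sum()),
        n_test_absences=int((status == ABSENT).sum()),
    )
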