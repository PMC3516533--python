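"""The four modelling schemes for an obligately dependent species.

* ``none`` — climate-only baseline: the dependent species is modelled on
  climate alone, ignoring its host.
* ``overlap`` — both species are modelled separately on climate and the
  thresholded projections are intersected cellwise.
* ``explanatory`` — the host's modelled current occurrence probability
  enters the dependent species' model as one additional predictor; the
  future projection substitutes the host's future probability.
* ``reference_area`` — the dependent species' model is calibrated only
  within the host's observed current range, yielding the conditional
  probability P(dependent | host); the final map is that conditional
  probability multiplied by the host's modelled probability.

Each scheme returns an :class:`ApproachResult` bundling suitability and
binary maps for both periods, the thresholds used, and an evaluation
report on held-out test cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import (
    EvaluationReport,
    binarize,
    evaluate,
    mean_probability_threshold,
    prevalence_threshold,
)
from .grid_io import (
    PRESENT,
    UNKNOWN,
    BinaryRangeMap,
    ClimateLayerSet,
    OccurrenceMap,
    SuitabilityMap,
    assert_aligned,
)
from .sdm_core import DataSplit, EnsembleModel, fit_ensemble, predict_prob, split_data

__all__ = [
    "APPROACHES",
    "ApproachResult",
    "model_no_interaction",
    "approach_overlap",
    "approach_explanatory",
    "approach_reference_area",
]

APPROACHES = ("none", "overlap", "explanatory", "reference_area")


@dataclass
class ApproachResult:
    """Per-approach bundle of maps, thresholds, evaluation and provenance."""

    approach: str
    species: str
    suitability: dict  # period -> SuitabilityMap (final maps)
    binary: dict  # period -> BinaryRangeMap
    thresholds: dict  # species -> threshold used
    report: EvaluationReport | None
    split: DataSplit | None = None
    model: EnsembleModel | None = None
    conditional_suitability: dict | None = None  # reference_area only
    host_suitability: dict | None = None
    calibration_cells: np.ndarray | None = None
    non_analogue: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def _choose_threshold(
    method: str,
    occurrence: OccurrenceMap,
    training_cells: np.ndarray,
    suitability_current: SuitabilityMap,
) -> float:
    if method == "prevalence":
        return prevalence_threshold(occurrence, training_cells)
    if method == "mean_probability":
        return mean_probability_threshold(suitability_current)
    raise ValueError(f"unknown threshold method {method!r}")


def model_no_interaction(
    occurrence: OccurrenceMap,
    climate_current: ClimateLayerSet,
    climate_future: ClimateLayerSet,
    learner_specs: Sequence,
    split: DataSplit | None = None,
    seed=None,
    threshold_method: str = "prevalence",
    approach_label: str = "none",
) -> ApproachResult:
    """Climate-only ensemble for one species, evaluated on its test cells."""
    assert_aligned(climate_current, occurrence)
    assert_aligned(climate_current, climate_future)
    if split is None:
        split = split_data(occurrence, seed=seed)
    model = fit_ensemble(learner_specs, climate_current, occurrence, split.training)
    suit = {
        "current": predict_prob(model, climate_current),
        "future": predict_prob(model, climate_future),
    }
    threshold = _choose_threshold(
        threshold_method, occurrence, split.training, suit["current"]
    )
    binary = {p: binarize(s, threshold) for p, s in suit.items()}
    report = None
    if not split.empty_test:
        report = evaluate(
            suit["current"], occurrence, split.test, threshold, threshold_method
        )
    return ApproachResult(
        approach=approach_label,
        species=occurrence.species,
        suitability=suit,
        binary=binary,
        thresholds={occurrence.species: threshold},
        report=report,
        split=split,
        model=model,
        provenance={
            "learners": [s.name for s in learner_specs],
            "split_seed": split.seed,
            "threshold_method": threshold_method,
        },
    )


def _intersect(a: BinaryRangeMap, b: BinaryRangeMap, species: str) -> BinaryRangeMap:
    assert_aligned(a, b)
    missing = a.missing | b.missing
    return BinaryRangeMap(
        a.grid,
        species,
        a.period,
        a.presence & b.presence & ~missing,
        a.threshold,
        missing,
    )


def approach_overlap(
    dep_result: ApproachResult,
    host_result: ApproachResult,
    observed: OccurrenceMap | None = None,
) -> ApproachResult:
    """Cellwise AND of the two species' thresholded projections.

    Each species keeps its own threshold; by construction the result's
    presence set is a subset of the dependent species' climate-only
    presence set in every period.  If the dependent species' observed
    occurrence is supplied, omission/commission of the intersected
    current map are recomputed on the dependent species' test cells;
    AUC is not defined for an intersection of binary maps, so the
    dependent model's AUC is carried over for reference.
    """
    assert_aligned(dep_result.binary["future"], host_result.binary["future"])
    binary = {
        p: _intersect(dep_result.binary[p], host_result.binary[p], dep_result.species)
        for p in ("current", "future")
    }
    report = dep_result.report
    if (
        observed is not None
        and dep_result.split is not None
        and not dep_result.split.empty_test
        and dep_result.report is not None
    ):
        from .evaluation import omission_commission

        om, com = omission_commission(binary["current"], observed, dep_result.split.test)
        report = EvaluationReport(
            auc=dep_result.report.auc,
            omission_rate=om,
            commission_rate=com,
            threshold=dep_result.binary["current"].threshold,
            threshold_method=dep_result.report.threshold_method,
            n_test_presences=dep_result.report.n_test_presences,
            n_test_absences=dep_result.report.n_test_absences,
        )
    return ApproachResult(
        approach="overlap",
        species=dep_result.species,
        suitability=dict(dep_result.suitability),
        binary=binary,
        thresholds={**dep_result.thresholds, **host_result.thresholds},
        report=report,
        split=dep_result.split,
        model=dep_result.model,
        host_suitability=dict(host_result.suitability),
        provenance={
            "dependent": dep_result.provenance,
            "host": host_result.provenance,
        },
    )


def approach_explanatory(
    occurrence: OccurrenceMap,
    climate_current: ClimateLayerSet,
    climate_future: ClimateLayerSet,
    host_suitability_current: SuitabilityMap,
    host_suitability_future: SuitabilityMap,
    learner_specs: Sequence,
    split: DataSplit | None = None,
    seed=None,
    threshold_method: str = "prevalence",
) -> ApproachResult:
    """Host modelled probability as an additional predictor.

    The model is fitted with the host's *current* modelled probability
    (never observed host presence) and projected into the future with
    the host's *future* probability substituted for that predictor.
    """
    if host_suitability_current is None or host_suitability_future is None:
        raise ValueError("explanatory approach requires host suitability maps")
    assert_aligned(climate_current, host_suitability_current)
    assert_aligned(climate_future, host_suitability_future)
    if split is None:
        split = split_data(occurrence, seed=seed)
    model = fit_ensemble(
        learner_specs,
        climate_current,
        occurrence,
        split.training,
        extra_predictors=[host_suitability_current],
    )
    suit = {
        "current": predict_prob(
            model, climate_current, extra_predictors=[host_suitability_current]
        ),
        "future": predict_prob(
            model, climate_future, extra_predictors=[host_suitability_future]
        ),
    }
    threshold = _choose_threshold(
        threshold_method, occurrence, split.training, suit["current"]
    )
    binary = {p: binarize(s, threshold) for p, s in suit.items()}
    report = None
    if not split.empty_test:
        report = evaluate(
            suit["current"], occurrence, split.test, threshold, threshold_method
        )
    return ApproachResult(
        approach="explanatory",
        species=occurrence.species,
        suitability=suit,
        binary=binary,
        thresholds={occurrence.species: threshold},
        report=report,
        split=split,
        model=model,
        host_suitability={
            "current": host_suitability_current,
            "future": host_suitability_future,
        },
        provenance={
            "learners": [s.name for s in learner_specs],
            "split_seed": split.seed,
            "threshold_method": threshold_method,
            "host_predictor": f"p_{host_suitability_current.species}",
        },
    )


def approach_reference_area(
    occurrence: OccurrenceMap,
    host_occurrence: OccurrenceMap,
    climate_current: ClimateLayerSet,
    climate_future: ClimateLayerSet,
    host_suitability_current: SuitabilityMap,
    host_suitability_future: SuitabilityMap,
    learner_specs: Sequence,
    split: DataSplit | None = None,
    seed=None,
    threshold_method: str = "prevalence",
) -> ApproachResult:
    """Conditional model within the host's range, times host probability.

    Training data are restricted to cells where the host is observed
    present (the calibration area), so the fitted ensemble estimates
    P(dependent | host present, climate).  The final suitability for
    each period multiplies this conditional probability by the host's
    modelled probability for the same period; the threshold is the
    dependent species' prevalence within the calibration model-building
    cells, and evaluation uses calibration test cells.
    """
    assert_aligned(climate_current, occurrence)
    assert_aligned(climate_current, host_occurrence)
    if (host_occurrence.status == PRESENT).sum() == 0:
        raise ValueError("reference-area approach requires at least one host presence")
    calibration = host_occurrence.status == PRESENT
    restricted_status = np.where(calibration, occurrence.status, UNKNOWN).astype(np.int8)
    restricted = OccurrenceMap(occurrence.grid, occurrence.species, restricted_status)
    if split is None:
        split = split_data(restricted, seed=seed)
    model = fit_ensemble(learner_specs, climate_current, restricted, split.training)
    conditional = {
        "current": predict_prob(model, climate_current),
        "future": predict_prob(model, climate_future),
    }
    suit = {}
    for period, host_suit in (
        ("current", host_suitability_current),
        ("future", host_suitability_future),
    ):
        assert_aligned(conditional[period], host_suit)
        prob = conditional[period].probability * host_suit.probability
        suit[period] = SuitabilityMap(
            occurrence.grid,
            occurrence.species,
            period,
            prob,
            f"{conditional[period].source}*p_{host_suit.species}",
        )
    threshold = _choose_threshold(threshold_method, restricted, split.training, suit["current"])
    binary = {p: binarize(s, threshold) for p, s in suit.items()}
    report = None
    if not split.empty_test:
        report = evaluate(suit["current"], restricted, split.test, threshold, threshold_method)
    return ApproachResult(
        approach="reference_area",
        species=occurrence.species,
        suitability=suit,
        binary=binary,
        thresholds={occurrence.species: threshold},
        report=report,
        split=split,
        model=model,
        conditional_suitability=conditional,
        host_suitability={
            "current": host_suitability_current,
            "future": host_suitability_future,
        },
        calibration_cells=np.flatnonzero(calibration),
        provenance={
            "learners": [s.name for s in learner_specs],
            "split_seed": split.seed,
            "threshold_method": threshold_method,
            "n_calibration_cells": int(calibration.sum()),
        },
    )
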