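"""Envelope-model fitting, probability-mean ensembles and permutation importance.

Two learners are built in:

``glm_poly2``
    Logistic regression on linear + quadratic terms of every predictor,
    fitted by iteratively reweighted least squares with a small ridge
    penalty (default 1e-6 on non-intercept terms, applied on the
    standardised feature scale) so that perfectly separable data still
    yield a finite fit.  Coefficients and their standard errors are
    reported on the raw feature scale.

``sre``
    Surface range envelope: predicts 1 iff every predictor lies within
    the ``[q, 1-q]`` empirical quantile interval of the presence-only
    training values (default q = 0.025), else 0.

Any object honouring the ``fit(X, y)`` / ``predict_proba(X)`` contract
can be registered as a plug-in learner.  Ensembles combine members by
the arithmetic mean of their predicted probabilities.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .grid_io import (
    ABSENT,
    PRESENT,
    ClimateLayerSet,
    OccurrenceMap,
    SuitabilityMap,
    assert_aligned,
)

__all__ = [
    "LearnerSpec",
    "DataSplit",
    "FittedLearner",
    "EnsembleModel",
    "GlmPoly2",
    "SurfaceRangeEnvelope",
    "register_learner",
    "make_learner",
    "split_data",
    "fit_learner",
    "fit_ensemble",
    "predict_prob",
    "variable_importance",
    "rank_variables",
    "extra_predictor_name",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LearnerSpec:
    """Name + hyperparameters of one modelling algorithm."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None


@dataclass(frozen=True)
class DataSplit:
    """Seeded uniform partition of surveyed cells into training and test."""

    training: np.ndarray
    test: np.ndarray
    fraction: float
    seed: int | None
    empty_test: bool = False


def split_data(occurrence: OccurrenceMap, fraction: float = 0.7, seed=None) -> DataSplit:
    """Randomly partition surveyed cells into training/test (no stratification).

    ``|training| = round(fraction * n_surveyed)``.  A fraction of 1.0
    gives an empty test set and sets the ``empty_test`` warning flag.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    cells = np.flatnonzero(occurrence.surveyed)
    status = occurrence.status[cells]
    if (status == PRESENT).sum() == 0 or (status == ABSENT).sum() == 0:
        raise ValueError(
            "cannot split single-class data: need at least one presence and one absence"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cells)
    n_train = int(round(fraction * len(cells)))
    empty = n_train == len(cells)
    if empty:
        warnings.warn("fraction 1.0 leaves an empty test set", stacklevel=2)
    return DataSplit(
        training=np.sort(perm[:n_train]),
        test=np.sort(perm[n_train:]),
        fraction=fraction,
        seed=seed,
        empty_test=empty,
    )


# ---------------------------------------------------------------------------
# learners


class GlmPoly2:
    """Ridge-penalised quadratic logistic regression fitted by IRLS."""

    def __init__(self, ridge: float = 1e-6, max_iter: int = 200, tol: float = 1e-10):
        self.ridge = float(ridge)
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    @staticmethod
    def _features(X: np.ndarray) -> np.ndarray:
        return np.hstack([X, X**2])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GlmPoly2":
        F = self._features(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        self._mean = F.mean(axis=0)
        scale = F.std(axis=0)
        self._scale = np.where(scale > 0, scale, 1.0)
        Z = (F - self._mean) / self._scale
        n, k = Z.shape
        D = np.hstack([np.ones((n, 1)), Z])
        pen = np.full(k + 1, self.ridge)
        pen[0] = 0.0  # intercept unpenalised
        beta = np.zeros(k + 1)

        def objective(b):
            eta = np.clip(D @ b, -30, 30)
            # penalised negative log-likelihood (stable via log1p)
            nll = np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta)
            return nll + np.sum(pen * b**2)

        obj = objective(beta)
        for _ in range(self.max_iter):
            eta = np.clip(D @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1.0 - mu), 1e-12)
            grad = D.T @ (y - mu) - 2.0 * pen * beta
            H = (D * w[:, None]).T @ D + 2.0 * np.diag(pen)
            step = np.linalg.solve(H, grad)
            # Newton can overshoot on (near-)separable data: backtrack on
            # the penalised deviance until it no longer increases
            scale = 1.0
            for _ in range(40):
                candidate = beta + scale * step
                new_obj = objective(candidate)
                if new_obj <= obj + 1e-12:
                    break
                scale *= 0.5
            else:
                break
            beta, obj = candidate, new_obj
            if scale * np.max(np.abs(step)) < self.tol:
                break
        eta = np.clip(D @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        H = (D * w[:, None]).T @ D + 2.0 * np.diag(pen)
        cov_std = np.linalg.inv(H)
        # map (intercept, standardised features) back to the raw scale:
        # eta = b0 + sum b_j (f_j - m_j)/s_j  =>  c_j = b_j/s_j,
        # c_0 = b0 - sum b_j m_j / s_j; the map is linear so the
        # covariance transforms as T C T'.
        T = np.zeros((k + 1, k + 1))
        T[0, 0] = 1.0
        T[0, 1:] = -self._mean / self._scale
        T[1:, 1:] = np.diag(1.0 / self._scale)
        self.coef_std_ = beta
        self.coef_ = T @ beta
        self.cov_ = T @ cov_std @ T.T
        self.se_ = np.sqrt(np.diag(self.cov_))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        F = self._features(np.asarray(X, dtype=float))
        Z = (F - self._mean) / self._scale
        eta = np.clip(self.coef_std_[0] + Z @ self.coef_std_[1:], -700, 700)
        return 1.0 / (1.0 + np.exp(-eta))


class SurfaceRangeEnvelope:
    """Presence-only quantile box classifier (rectilinear envelope)."""

    def __init__(self, q: float = 0.025):
        if not 0 <= q < 0.5:
            raise ValueError("q must lie in [0, 0.5)")
        self.q = float(q)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SurfaceRangeEnvelope":
        X = np.asarray(X, dtype=float)
        pres = X[np.asarray(y) == 1]
        if len(pres) < 2:
            raise ValueError("surface range envelope needs at least 2 presences")
        self.lower_ = np.quantile(pres, self.q, axis=0)
        self.upper_ = np.quantile(pres, 1.0 - self.q, axis=0)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        inside = np.all((X >= self.lower_) & (X <= self.upper_), axis=1)
        return inside.astype(float)


_REGISTRY: dict = {}


def register_learner(name: str, factory: Callable[[LearnerSpec], object]) -> None:
    """Register a plug-in learner factory under ``name``."""
    _REGISTRY[name] = factory


def make_learner(spec: LearnerSpec):
    if spec.name not in _REGISTRY:
        raise KeyError(f"unknown learner {spec.name!r}; registered: {sorted(_REGISTRY)}")
    return _REGISTRY[spec.name](spec)


register_learner("glm_poly2", lambda spec: GlmPoly2(**spec.hyperparameters))
register_learner("sre", lambda spec: SurfaceRangeEnvelope(**spec.hyperparameters))


# ---------------------------------------------------------------------------
# fitting and prediction on gridded data


def extra_predictor_name(extra: SuitabilityMap) -> str:
    """Canonical predictor name for a suitability map used as covariate."""
    return f"p_{extra.species}"


@dataclass
class FittedLearner:
    """A fitted learner bound to its predictor names and training summary."""

    spec: LearnerSpec
    predictor_names: list
    learner: object
    species: str
    n_presences: int
    n_absences: int
    dropped: list = field(default_factory=list)


@dataclass
class EnsembleModel:
    """Probability-mean ensemble of fitted learners."""

    members: list
    member_auc: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError("an ensemble needs at least one member")

    @property
    def species(self) -> str:
        return self.members[0].species

    @property
    def predictor_names(self) -> list:
        names: list = []
        for m in self.members:
            for n in m.predictor_names + m.dropped:
                if n not in names:
                    names.append(n)
        return names


def _design(
    layers: ClimateLayerSet,
    names: Sequence[str],
    extra_predictors: Sequence[SuitabilityMap] | None,
):
    """(n_cells, p) matrix over ``names`` drawn from layers + extras."""
    columns = {}
    for extra in extra_predictors or ():
        assert_aligned(layers, extra)
        columns[extra_predictor_name(extra)] = extra.probability
    out = []
    for n in names:
        if n in layers.variables:
            out.append(layers.variables[n])
        elif n in columns:
            out.append(columns[n])
        else:
            raise KeyError(f"predictor {n!r} not found in layers or extra predictors")
    return np.column_stack(out)


def fit_learner(
    spec: LearnerSpec,
    layers: ClimateLayerSet,
    occurrence: OccurrenceMap,
    cells: np.ndarray,
    extra_predictors: Sequence[SuitabilityMap] | None = None,
) -> FittedLearner:
    """Fit one learner on the given training cells.

    Cells with unknown status or any missing predictor are dropped;
    zero-variance predictors are dropped with a logged warning (this is
    what makes a constant host-probability covariate degrade gracefully
    to the climate-only model).
    """
    assert_aligned(layers, occurrence)
    names = list(layers.variables) + [
        extra_predictor_name(e) for e in (extra_predictors or ())
    ]
    X_all = _design(layers, names, extra_predictors)
    cells = np.asarray(cells)
    X = X_all[cells]
    y = (occurrence.status[cells] == PRESENT).astype(float)
    ok = np.isfinite(X).all(axis=1) & (occurrence.status[cells] != -1)
    X, y = X[ok], y[ok]
    keep, dropped = [], []
    for j, n in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            dropped.append(n)
            log.warning("dropping zero-variance predictor %r for learner %s", n, spec.name)
        else:
            keep.append(j)
    names_kept = [names[j] for j in keep]
    learner = make_learner(spec)
    learner.fit(X[:, keep], y)
    return FittedLearner(
        spec=spec,
        predictor_names=names_kept,
        learner=learner,
        species=occurrence.species,
        n_presences=int(y.sum()),
        n_absences=int(len(y) - y.sum()),
        dropped=dropped,
    )


def fit_ensemble(
    specs: Sequence[LearnerSpec],
    layers: ClimateLayerSet,
    occurrence: OccurrenceMap,
    cells: np.ndarray,
    extra_predictors: Sequence[SuitabilityMap] | None = None,
) -> EnsembleModel:
    return EnsembleModel(
        members=[fit_learner(s, layers, occurrence, cells, extra_predictors) for s in specs]
    )


def predict_prob(
    model,
    layers: ClimateLayerSet,
    extra_predictors: Sequence[SuitabilityMap] | None = None,
) -> SuitabilityMap:
    """Project a fitted learner or ensemble onto a layer set.

    Ensemble output is the arithmetic mean of member probabilities;
    cells with any missing predictor propagate as missing.
    """
    if isinstance(model, EnsembleModel):
        probs = [
            predict_prob(m, layers, extra_predictors).probability for m in model.members
        ]
        out = np.mean(probs, axis=0)
        source = "ensemble(" + "+".join(m.spec.name for m in model.members) + ")"
        return SuitabilityMap(layers.grid, model.species, layers.period, out, source)
    X = _design(layers, model.predictor_names, extra_predictors)
    valid = np.isfinite(X).all(axis=1) & ~layers.missing
    prob = np.full(layers.grid.n_cells, np.nan)
    if valid.any():
        prob[valid] = np.clip(model.learner.predict_proba(X[valid]), 0.0, 1.0)
    return SuitabilityMap(layers.grid, model.species, layers.period, prob, model.spec.name)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the conventions the importance score needs.

    Identical vectors correlate 1 (a permutation that changes nothing
    carries no importance); a constant vector correlates 0 (a
    permutation that flattens predictions has destroyed all signal).
    """
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def variable_importance(
    model,
    layers: ClimateLayerSet,
    n_perm: int = 10,
    seed=None,
    extra_predictors: Sequence[SuitabilityMap] | None = None,
) -> dict:
    """Randomisation importance: mean of ``1 - cor(reference, permuted)``.

    For each variable the values are permuted across non-missing cells
    ``n_perm`` times (one seeded stream, variables processed in layer
    order) and the drop in correlation with the reference predictions is
    averaged.  A predictor the model ignores scores exactly 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    extras = list(extra_predictors or ())
    names = list(layers.variables) + [extra_predictor_name(e) for e in extras]
    X = _design(layers, names, extras)
    valid = np.isfinite(X).all(axis=1)
    members = model.members if isinstance(model, EnsembleModel) else [model]

    def _predict(mat: np.ndarray) -> np.ndarray:
        cols = {n: mat[:, j] for j, n in enumerate(names)}
        preds = []
        for m in members:
            sub = np.column_stack([cols[n] for n in m.predictor_names])
            preds.append(np.clip(m.learner.predict_proba(sub), 0.0, 1.0))
        return np.mean(preds, axis=0)

    reference = _predict(X[valid])
    rng = np.random.default_rng(seed)
    importance = {}
    for j, name in enumerate(names):
        scores = []
        for _ in range(n_perm):
            perm = rng.permutation(valid.sum())
            Xp = X[valid].copy()
            Xp[:, j] = Xp[perm, j]
            scores.append(1.0 - _pearson(reference, _predict(Xp)))
        importance[name] = float(np.mean(scores))
    return importance


def rank_variables(importances: dict) -> list:
    """Variable names in descending importance; ties break lexicographically."""
    if not importances:
        raise ValueError("empty importance mapping")
    return [n for n, _ in sorted(importances.items(), key=lambda kv: (-kv[1], kv[0]))]
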