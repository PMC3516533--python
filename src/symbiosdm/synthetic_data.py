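"""Virtual host and dependent species on synthetic climate grids.

The generator emulates the structure of continental atlas data: a few
spatially smooth, correlated climate variables on a regular grid; a host
species with a unimodal (quadratic-logistic) climatic response; and an
obligately dependent species whose true occupancy is the product of its
own climatic suitability and host presence.  The future period shifts
climate so that suitability moves poleward (toward row 0).

The packaged default scenario (:func:`default_config`) is built so that
the host's future range limits the dependent species' climatically
suitable area: the host is thermally narrower and cooler-adapted than
the dependent and additionally requires moist conditions, and future
drying contracts the host while warming pushes both species poleward.
Under those conditions climate-only projections of the dependent species
overshoot the area its host will actually occupy, which is exactly the
regime in which the three interaction-coupling schemes disagree with a
climate-only model in an informative way.

Every operation is reproducible from ``(config, seed)``; independent
random streams are derived from the scenario seed, never from global
state.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid_io import (
    ABSENT,
    PRESENT,
    UNKNOWN,
    ClimateLayerSet,
    Grid,
    OccurrenceMap,
    SuitabilityMap,
    assert_aligned,
)

__all__ = [
    "VariableSpec",
    "SpeciesResponse",
    "VirtualScenarioConfig",
    "VirtualTruth",
    "Scenario",
    "default_config",
    "uncertainty_config",
    "generate_climate",
    "logistic_suitability",
    "realize_occurrence",
    "generate_scenario",
]


@dataclass(frozen=True)
class VariableSpec:
    """One synthetic climate variable.

    The field is a linear gradient along ``direction`` rescaled to
    ``[lo, hi]`` plus Gaussian-smoothed white noise of standard
    deviation ``noise_sd`` and correlation length ``noise_length``
    (in cells).
    """

    name: str
    direction: str = "row"
    lo: float = 0.0
    hi: float = 1.0
    noise_sd: float = 0.0
    noise_length: float = 3.0

    def __post_init__(self):
        if self.direction not in ("row", "col"):
            raise ValueError(f"direction must be 'row' or 'col', got {self.direction!r}")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise ValueError("gradient range must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SpeciesResponse:
    """Quadratic-logistic climatic response.

    The linear predictor is ``intercept + sum_v b1[v]*x_v + b2[v]*x_v**2``
    and suitability is its logistic transform; a quadratic with a
    negative ``b2`` gives the usual unimodal niche.
    """

    intercept: float
    linear: dict = field(default_factory=dict)
    quadratic: dict = field(default_factory=dict)


@dataclass(frozen=True)
class VirtualScenarioConfig:
    n_rows: int = 60
    n_cols: int = 60
    variables: tuple = ()
    future_shift: dict = field(default_factory=dict)
    host_response: SpeciesResponse = None  # type: ignore[assignment]
    dependent_response: SpeciesResponse = None  # type: ignore[assignment]
    obligate: bool = True
    detection: float = 1.0
    sample_fraction: float = 1.0
    host_species: str = "host"
    dependent_species: str = "dependent"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must lie in (0, 1]")
        if not 0 <= self.detection <= 1:
            raise ValueError("detection must lie in [0, 1]")


def default_config(seed: int = 0) -> VirtualScenarioConfig:
    """The packaged default scenario (60x60 grid, host-limited future).

    ``temperature`` runs from 2 (row 0, the pole) to 14 along rows and
    warms by +2 in the future; ``moisture`` runs from 600 to 900 along
    columns and dries by -150.  The host peaks at 7 deg with a narrow
    thermal breadth and requires moist conditions; the dependent
    (conditional on its host) peaks at 9 deg with a broad breadth and no
    direct moisture response.  Warming pushes both thermal bands
    poleward, but drying contracts the host toward the moist columns.
    The host's moisture limit is plainly expressed in its own current
    data, whereas the dependent's observed distribution carries it only
    in attenuated form (through host occupancy), so climate-only
    projections of the dependent overshoot the area its host will
    actually occupy.
    """
    return VirtualScenarioConfig(
        n_rows=60,
        n_cols=60,
        variables=(
            VariableSpec("temperature", "row", 2.0, 14.0, noise_sd=0.4, noise_length=3.0),
            VariableSpec("moisture", "col", 600.0, 900.0, noise_sd=20.0, noise_length=3.0),
        ),
        future_shift={"temperature": 2.0, "moisture": -150.0},
        # host: eta = 3.0 - 0.5*(T-7)^2 + 0.02*(M-750)
        host_response=SpeciesResponse(
            intercept=3.0 - 0.5 * 49.0 - 0.02 * 750.0,
            linear={"temperature": 0.5 * 14.0, "moisture": 0.02},
            quadratic={"temperature": -0.5},
        ),
        # dependent (conditional on host): eta = 0.2 - 0.07*(T-9)^2.
        # The moderate conditional peak (~0.55) matters: it attenuates the
        # host's moisture imprint on the dependent's observed data, so a
        # climate-only model of the dependent underestimates how strongly
        # the (drying) future clips its host.
        dependent_response=SpeciesResponse(
            intercept=0.2 - 0.07 * 81.0,
            linear={"temperature": 0.07 * 18.0},
            quadratic={"temperature": -0.07},
        ),
        obligate=True,
        detection=1.0,
        sample_fraction=1.0,
        seed=seed,
    )


def uncertainty_config(seed: int = 0) -> VirtualScenarioConfig:
    """Scenario for attributing projection variance to its sources.

    Same climate as :func:`default_config`, but the host is widespread
    and thermally broad (and indifferent to moisture), so the four
    coupling schemes project nearly the same range for the dependent
    species and the spread among projections is dominated by the choice
    of modelling algorithm.  This isolates algorithm heterogeneity the
    way a non-limiting host does in nature; the host-limited default
    scenario is the complementary regime.
    """
    base = default_config(seed=seed)
    return replace(
        base,
        # host: eta = 4.0 - 0.08*(T-8)^2, no moisture dependence
        host_response=SpeciesResponse(
            intercept=4.0 - 0.08 * 64.0,
            linear={"temperature": 0.08 * 16.0},
            quadratic={"temperature": -0.08},
        ),
        future_shift={"temperature": 2.0, "moisture": 0.0},
    )


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stream]))


def _smooth_noise(rng: np.random.Generator, shape, sd: float, length: float) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise rescaled to standard deviation ``sd``."""
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    smooth = gaussian_filter(white, sigma=length, mode="reflect")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def _gradient(spec: VariableSpec, n_rows: int, n_cols: int) -> np.ndarray:
    if spec.direction == "row":
        axis = np.linspace(spec.lo, spec.hi, n_rows) if n_rows > 1 else np.array([spec.lo])
        return np.repeat(axis[:, None], n_cols, axis=1)
    axis = np.linspace(spec.lo, spec.hi, n_cols) if n_cols > 1 else np.array([spec.lo])
    return np.repeat(axis[None, :], n_rows, axis=0)


def generate_climate(config: VirtualScenarioConfig):
    """Return ``(current, future)`` :class:`ClimateLayerSet` on one grid.

    The future layers add the per-variable ``future_shift`` to the
    gradient and redraw the smooth noise with a derived sub-seed.
    """
    grid = Grid.regular(config.n_rows, config.n_cols)
    shape = (config.n_rows, config.n_cols)
    rng_cur = _rng(config.seed, 0)
    rng_fut = _rng(config.seed, 1)
    current, future = {}, {}
    for spec in config.variables:
        base = _gradient(spec, *shape)
        shift = config.future_shift.get(spec.name, 0.0)
        current[spec.name] = (
            base + _smooth_noise(rng_cur, shape, spec.noise_sd, spec.noise_length)
        ).reshape(-1)
        future[spec.name] = (
            base + shift + _smooth_noise(rng_fut, shape, spec.noise_sd, spec.noise_length)
        ).reshape(-1)
    return (
        ClimateLayerSet(grid, "current", current),
        ClimateLayerSet(grid, "future", future),
    )


def logistic_suitability(
    response: SpeciesResponse,
    layers: ClimateLayerSet,
    species: str = "species",
    source: str = "truth",
) -> SuitabilityMap:
    """Suitability ``1 / (1 + exp(-eta))`` from a quadratic-logistic response."""
    eta = np.full(layers.grid.n_cells, float(response.intercept))
    for name, b1 in response.linear.items():
        if name not in layers.variables:
            raise KeyError(f"response references unknown variable {name!r}")
        eta = eta + b1 * layers.variables[name]
    for name, b2 in response.quadratic.items():
        if name not in layers.variables:
            raise KeyError(f"response references unknown variable {name!r}")
        eta = eta + b2 * layers.variables[name] ** 2
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    prob[layers.missing] = np.nan
    return SuitabilityMap(layers.grid, species, layers.period, prob, source)


def realize_occurrence(
    suitability: SuitabilityMap,
    host: OccurrenceMap | None = None,
    obligate: bool = False,
    detection: float = 1.0,
    sample_fraction: float = 1.0,
    seed=0,
    return_occupancy: bool = False,
):
    """Sample an observed :class:`OccurrenceMap` from a suitability surface.

    True occupancy is Bernoulli(probability), masked to host presences
    when ``obligate``; observed presence thins occupancy by a Bernoulli
    ``detection`` trial; a seeded fraction ``1 - sample_fraction`` of
    cells is left unsurveyed (status unknown).  Cells with missing
    suitability are unknown.
    """
    if not 0 <= detection <= 1:
        raise ValueError("detection must lie in [0, 1]")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must lie in (0, 1]")
    if obligate and host is None:
        raise ValueError("obligate occurrence requires a host map")
    if host is not None:
        assert_aligned(suitability, host)
    rng = np.random.default_rng(seed)
    n = suitability.grid.n_cells
    p = np.nan_to_num(suitability.probability, nan=0.0)
    occupancy = rng.random(n) < p
    if obligate:
        occupancy &= host.presence
    detected = occupancy & (rng.random(n) < detection)
    status = np.where(detected, PRESENT, ABSENT).astype(np.int8)
    unsurveyed = rng.random(n) >= sample_fraction
    status[unsurveyed] = UNKNOWN
    status[suitability.missing] = UNKNOWN
    observed = OccurrenceMap(suitability.grid, suitability.species, status)
    if return_occupancy:
        truth = OccurrenceMap(
            suitability.grid,
            suitability.species,
            np.where(occupancy, PRESENT, ABSENT).astype(np.int8),
        )
        return observed, truth
    return observed


@dataclass(frozen=True)
class VirtualTruth:
    """Ground-truth suitabilities and occupancies behind a scenario."""

    host_suitability: dict
    dependent_suitability: dict  # conditional on host presence
    host_occupancy: dict
    dependent_occupancy: dict


@dataclass(frozen=True)
class Scenario:
    config: VirtualScenarioConfig
    climate_current: ClimateLayerSet
    climate_future: ClimateLayerSet
    host_occurrence: OccurrenceMap
    dependent_occurrence: OccurrenceMap
    truth: VirtualTruth


def generate_scenario(config: VirtualScenarioConfig | None = None, seed=None) -> Scenario:
    """Compose climate, suitabilities and occurrence realisations.

    Fully reproducible from ``(config, seed)``; passing ``seed``
    overrides ``config.seed``.
    """
    config = default_config() if config is None else config
    if seed is not None:
        config = replace(config, seed=int(seed))
    clim_cur, clim_fut = generate_climate(config)
    host_suit = {
        period: logistic_suitability(config.host_response, layers, config.host_species)
        for period, layers in (("current", clim_cur), ("future", clim_fut))
    }
    dep_suit = {
        period: logistic_suitability(config.dependent_response, layers, config.dependent_species)
        for period, layers in (("current", clim_cur), ("future", clim_fut))
    }
    host_occ, host_truth, dep_occ, dep_truth = {}, {}, {}, {}
    for k, period in enumerate(("current", "future")):
        host_occ[period], host_truth[period] = realize_occurrence(
            host_suit[period],
            detection=config.detection,
            sample_fraction=config.sample_fraction,
            seed=np.random.SeedSequence([config.seed & 0x7FFFFFFF, 10 + k]),
            return_occupancy=True,
        )
        dep_occ[period], dep_truth[period] = realize_occurrence(
            dep_suit[period],
            host=host_truth[period],
            obligate=config.obligate,
            detection=config.detection,
            sample_fraction=config.sample_fraction,
            seed=np.random.SeedSequence([config.seed & 0x7FFFFFFF, 20 + k]),
            return_occupancy=True,
        )
    return Scenario(
        config=config,
        climate_current=clim_cur,
        climate_future=clim_fut,
        host_occurrence=host_occ["current"],
        dependent_occurrence=dep_occ["current"],
        truth=VirtualTruth(host_suit, dep_suit, host_truth, dep_truth),
    )
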