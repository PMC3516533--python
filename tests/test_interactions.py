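import numpy as np
import pytest

from symbiosdm.grid_io import BinaryRangeMap, Grid, OccurrenceMap, SuitabilityMap
from symbiosdm.interactions import (
    ApproachResult,
    approach_explanatory,
    approach_overlap,
    approach_reference_area,
    model_no_interaction,
)
from symbiosdm.sdm_core import LearnerSpec, variable_importance
from symbiosdm.synthetic_data import (
    SpeciesResponse,
    default_config,
    generate_climate,
    logistic_suitability,
    realize_occurrence,
)

SPECS = (LearnerSpec("glm_poly2"), LearnerSpec("sre"))


def _fake_result(presence_cur, presence_fut, species="dep", threshold=0.5, n_cols=None):
    n = len(presence_cur)
    grid = Grid.regular(1 if n_cols is None else n // n_cols, n_cols or n)
    suit = {
        p: SuitabilityMap(grid, species, p, np.where(v, 0.9, 0.1))
        for p, v in (("current", presence_cur), ("future", presence_fut))
    }
    binary = {
        p: BinaryRangeMap(grid, species, p, np.asarray(v, bool), threshold)
        for p, v in (("current", presence_cur), ("future", presence_fut))
    }
    return ApproachResult(
        approach="none",
        species=species,
        suitability=suit,
        binary=binary,
        thresholds={species: threshold},
        report=None,
    )


class TestOverlap:
    def test_host_everywhere_is_identity(self):
        dep = _fake_result([1, 0, 1, 0], [1, 1, 0, 0])
        host = _fake_result([1, 1, 1, 1], [1, 1, 1, 1], species="host")
        out = approach_overlap(dep, host)
        np.testing.assert_array_equal(
            out.binary["future"].presence, dep.binary["future"].presence
        )

    def test_host_nowhere_empties_range(self):
        dep = _fake_result([1, 0, 1, 0], [1, 1, 0, 0])
        host = _fake_result([0, 0, 0, 0], [0, 0, 0, 0], species="host")
        out = approach_overlap(dep, host)
        assert not out.binary["future"].presence.any()

    def test_set_intersection(self):
        # dependent {a,b,c}, host {b,c,d} -> overlap {b,c}
        dep = _fake_result([0, 0, 0, 0], [1, 1, 1, 0])
        host = _fake_result([0, 0, 0, 0], [0, 1, 1, 1], species="host")
        out = approach_overlap(dep, host)
        assert list(out.binary["future"].presence) == [False, True, True, False]

    def test_both_thresholds_reported(self, approach_results):
        _, results = approach_results
        assert set(results["overlap"].thresholds) == {"dependent", "host"}

    def test_future_containment_in_climate_only(self, approach_results):
        _, results = approach_results
        overlap = results["overlap"].binary["future"].presence
        none = results["none"].binary["future"].presence
        assert not (overlap & ~none).any()


class TestNoInteraction:
    def test_future_equals_current_climate_gives_identical_maps(self, scenario):
        res = model_no_interaction(
            scenario.dependent_occurrence,
            scenario.climate_current,
            scenario.climate_current,
            SPECS,
            seed=0,
        )
        np.testing.assert_array_equal(
            res.binary["current"].presence, res.binary["future"].presence
        )

    def test_single_member_equals_that_learner(self, scenario):
        res = model_no_interaction(
            scenario.dependent_occurrence,
            scenario.climate_current,
            scenario.climate_future,
            (LearnerSpec("glm_poly2"),),
            seed=0,
        )
        from symbiosdm.sdm_core import predict_prob

        member = res.model.members[0]
        np.testing.assert_array_equal(
            res.suitability["future"].probability,
            predict_prob(member, scenario.climate_future).probability,
        )

    def test_climate_only_virtual_species_is_well_discriminated(self):
        # steep purely climatic niche: the ensemble should separate
        # presences from absences almost perfectly on held-out cells
        cfg = default_config(seed=4)
        cur, fut = generate_climate(cfg)
        resp = SpeciesResponse(
            intercept=(4.0 - 0.5 * 49.0 - 0.02 * 750.0) * 3.0,
            linear={"temperature": 0.5 * 14.0 * 3.0, "moisture": 0.02 * 3.0},
            quadratic={"temperature": -0.5 * 3.0},
        )
        suit = logistic_suitability(resp, cur, "virtual")
        occ = realize_occurrence(suit, seed=4)
        res = model_no_interaction(occ, cur, fut, SPECS, seed=4)
        assert res.report.auc > 0.9


class TestExplanatory:
    def test_constant_host_probability_degenerates_to_climate_only(self, scenario):
        none = model_no_interaction(
            scenario.dependent_occurrence,
            scenario.climate_current,
            scenario.climate_future,
            SPECS,
            seed=2,
        )
        grid = scenario.climate_current.grid
        const = SuitabilityMap(grid, "host", "current", np.full(grid.n_cells, 0.35))
        const_fut = SuitabilityMap(grid, "host", "future", np.full(grid.n_cells, 0.35))
        exp = approach_explanatory(
            scenario.dependent_occurrence,
            scenario.climate_current,
            scenario.climate_future,
            const,
            const_fut,
            SPECS,
            split=none.split,
        )
        for period in ("current", "future"):
            np.testing.assert_array_equal(
                exp.suitability[period].probability,
                none.suitability[period].probability,
            )

    def test_host_predictor_is_informative_for_obligate_species(
        self, scenario, approach_results
    ):
        host, results = approach_results
        exp = results["explanatory"]
        imp = variable_importance(
            exp.model,
            scenario.climate_current,
            n_perm=5,
            seed=0,
            extra_predictors=[host.suitability["current"]],
        )
        assert imp["p_host"] > 0.0

    def test_zeroed_future_host_lowers_probability_where_effect_positive(self, scenario):
        host_cur = logistic_suitability(
            scenario.config.host_response, scenario.climate_current, "host"
        )
        grid = scenario.climate_current.grid
        host_zero = SuitabilityMap(grid, "host", "future", np.zeros(grid.n_cells))
        res = approach_explanatory(
            scenario.dependent_occurrence,
            scenario.climate_current,
            scenario.climate_current,  # same climate: isolate the host term
            host_cur,
            host_zero,
            (LearnerSpec("glm_poly2"),),
            seed=3,
        )
        glm = res.model.members[0].learner
        names = res.model.members[0].predictor_names
        j = names.index("p_host")
        b1, b2 = glm.coef_[1 + j], glm.coef_[1 + len(names) + j]
        p = host_cur.probability
        positive_effect = (b1 * p + b2 * p**2) > 0
        cur = res.suitability["current"].probability
        fut = res.suitability["future"].probability
        ok = np.isfinite(cur) & np.isfinite(fut) & positive_effect
        assert (fut[ok] <= cur[ok] + 1e-12).all()

    def test_missing_host_map_rejected(self, scenario):
        with pytest.raises(ValueError, match="host suitability"):
            approach_explanatory(
                scenario.dependent_occurrence,
                scenario.climate_current,
                scenario.climate_future,
                None,
                None,
                SPECS,
                seed=0,
            )


class TestReferenceArea:
    def test_final_probability_is_product(self, approach_results):
        _, results = approach_results
        ref = results["reference_area"]
        for period in ("current", "future"):
            cond = ref.conditional_suitability[period].probability
            host_p = ref.host_suitability[period].probability
            final = ref.suitability[period].probability
            ok = np.isfinite(final)
            np.testing.assert_allclose(final[ok], (cond * host_p)[ok], rtol=1e-12)

    def test_product_bounded_by_both_factors(self, approach_results):
        _, results = approach_results
        ref = results["reference_area"]
        for period in ("current", "future"):
            cond = ref.conditional_suitability[period].probability
            host_p = ref.host_suitability[period].probability
            final = ref.suitability[period].probability
            ok = np.isfinite(final)
            assert (final[ok] <= np.minimum(cond, host_p)[ok] + 1e-12).all()

    def test_certain_host_leaves_conditional_unchanged(self, scenario):
        grid = scenario.climate_current.grid
        ones_cur = SuitabilityMap(grid, "host", "current", np.ones(grid.n_cells))
        ones_fut = SuitabilityMap(grid, "host", "future", np.ones(grid.n_cells))
        res = approach_reference_area(
            scenario.dependent_occurrence,
            scenario.host_occurrence,
            scenario.climate_current,
            scenario.climate_future,
            ones_cur,
            ones_fut,
            SPECS,
            seed=5,
        )
        np.testing.assert_array_equal(
            res.suitability["future"].probability,
            res.conditional_suitability["future"].probability,
        )

    def test_training_restricted_to_host_range(self, scenario, approach_results):
        _, results = approach_results
        ref = results["reference_area"]
        host_present = set(np.flatnonzero(scenario.host_occurrence.presence))
        assert set(ref.split.training) <= host_present

    def test_hostless_map_rejected(self, scenario):
        empty_host = OccurrenceMap(
            scenario.host_occurrence.grid,
            "host",
            np.zeros(scenario.host_occurrence.grid.n_cells, np.int8),
        )
        with pytest.raises(ValueError, match="host presence"):
            approach_reference_area(
                scenario.dependent_occurrence,
                empty_host,
                scenario.climate_current,
                scenario.climate_future,
                None,
                None,
                SPECS,
                seed=0,
            )
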