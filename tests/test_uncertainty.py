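"""One-way sensitivity, utility-set scenarios, PrSA and CEAC behaviour."""

import numpy as np
import pytest

from crc_cea.engine import evaluate_strategies
from crc_cea.params import (
    DistEntry,
    ParameterValidationError,
    PrsaDistributionSpec,
    UTILITY_SETS,
)
from crc_cea.uncertainty import (
    DEFAULT_LAMBDA_GRID,
    OneWayResult,
    ceac,
    one_way,
    prsa,
    scenario_utilities,
    tornado,
)

PAIR = ("no_screening", "annual_ifobt")


def degenerate_spec(params):
    spec = params.prsa or PrsaDistributionSpec.default_for(params)
    return PrsaDistributionSpec(
        entries={path: DistEntry("fixed") for path in spec.entries},
        excluded=spec.excluded,
    )


@pytest.fixture(scope="module")
def prsa_run(fixture_params):
    """Shared moderate-size PrSA run on the fixture (seeded)."""
    return prsa(fixture_params.prsa, 1500, seed=11, params=fixture_params)


class TestOneWay:
    def test_degenerate_bounds_equal_base(self, fixture_params):
        base = fixture_params.compliance.c_screen
        res = one_way("compliance.c_screen", (base, base), PAIR, "qaly", fixture_params)
        assert res.icer_low == res.icer_base
        assert res.icer_high == res.icer_base

    def test_out_of_range_bound_fails_before_any_run(self, fixture_params):
        with pytest.raises(ParameterValidationError, match="c_screen"):
            one_way("compliance.c_screen", (0.1, 1.2), PAIR, "qaly", fixture_params)

    def test_zero_discount_scenario_structure(self, fixture_params):
        """A zero discount rate lowers the pair ICER (more future life-years
        count) but leaves the comparison well-defined, mirroring the
        published non-discounted scenario rows."""
        res = one_way("econ.discount_rate", (0.0, 0.07), PAIR, "qaly", fixture_params)
        assert isinstance(res.icer_low, float) and isinstance(res.icer_high, float)
        assert res.icer_low < res.icer_base < res.icer_high

    def test_lower_ifobt_specificity_raises_annual_vs_biennial_icer(self, fixture_params):
        """More false positives mean more follow-up colonoscopy spending,
        and annual testing doubles the exposure."""
        base_spec = fixture_params.tests["i_fobt"].specificity
        res = one_way("tests.i_fobt.specificity", (base_spec - 0.10, base_spec),
                      ("biennial_ifobt", "annual_ifobt"), "qaly", fixture_params)
        assert res.icer_low > res.icer_high

    def test_tornado_orders_by_interval_width(self, fixture_params):
        frame = tornado({
            "compliance.c_screen": (0.4, 0.8),
            "costs.unit_cost.i_fobt": (4.0, 16.0),
        }, PAIR, "qaly", fixture_params)
        widths = frame["width"].tolist()
        assert widths == sorted(widths, reverse=True)


class TestScenarios:
    def test_sharp_set_loads_exact_values(self, fixture_params):
        p = fixture_params.copy()
        p.utilities = p.utility_sets["sharp"]
        assert p.utilities.u_normal == 0.94
        assert p.utilities.u_diag == [0.80] * 4

    def test_unknown_set_raises(self, fixture_params):
        with pytest.raises(KeyError, match="nonexistent"):
            scenario_utilities("nonexistent", fixture_params)

    def test_all_ones_scenario_equates_qaly_and_ly(self, fixture_params):
        result = scenario_utilities("all_ones", fixture_params)
        base = evaluate_strategies(fixture_params)
        for o in result.ordered:
            assert o.qaly_per_person == o.ly_per_person
            assert o.ly_per_person == base[o.strategy].ly_per_person

    @pytest.mark.parametrize("set_name", ["ramsey", "ness", "sharp"])
    def test_named_scenarios_return_full_analysis(self, fixture_params, set_name):
        result = scenario_utilities(set_name, fixture_params)
        assert len(result.ordered) == 6
        assert result.frontier  # non-empty ladder with increasing ICERs
        assert result.frontier_icers == sorted(result.frontier_icers)


class TestPrsa:
    def test_same_seed_reproduces_draw_matrix_bitwise(self, fixture_params):
        a = prsa(fixture_params.prsa, 20, seed=3, params=fixture_params)
        b = prsa(fixture_params.prsa, 20, seed=3, params=fixture_params)
        assert a.draws.equals(b.draws)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)

    def test_degenerate_distributions_reproduce_base_case_exactly(self, fixture_params):
        draws = prsa(degenerate_spec(fixture_params), 3, seed=1, params=fixture_params)
        base = evaluate_strategies(fixture_params)
        ref = base["no_screening"]
        for j, name in enumerate(draws.strategies):
            expected_dc = base[name].cost_per_person - ref.cost_per_person
            expected_dq = base[name].qaly_per_person - ref.qaly_per_person
            assert np.all(draws.delta_cost[:, j] == expected_dc)
            assert np.all(draws.delta_qaly[:, j] == expected_dq)

    def test_probability_draws_stay_in_unit_interval(self, prsa_run):
        for path in prsa_run.draws.columns:
            values = prsa_run.draws[path].to_numpy()
            if path.startswith(("compliance.", "tests.", "utilities.", "natural_history.")):
                assert np.all((values >= 0) & (values <= 1)), path
            if path.startswith("costs."):
                assert np.all(values > 0), path

    def test_excluded_parameters_never_drawn(self, fixture_params, prsa_run):
        assert not any(c.startswith("econ.") or c.startswith("natural_history.m_crc")
                       for c in prsa_run.draws.columns)

    def test_requires_at_least_one_iteration(self, fixture_params):
        with pytest.raises(ValueError):
            prsa(fixture_params.prsa, 0, seed=1, params=fixture_params)


class TestCeac:
    def test_fractions_partition_unity_at_every_lambda(self, prsa_run):
        curve = ceac(prsa_run, DEFAULT_LAMBDA_GRID[::10], "qaly")
        np.testing.assert_allclose(curve.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_single_iteration_gives_indicator_curve(self, fixture_params):
        draws = prsa(degenerate_spec(fixture_params), 1, seed=1, params=fixture_params)
        curve = ceac(draws, [0.0, 10_000.0, 100_000.0], "qaly")
        assert set(np.unique(curve.probabilities)) <= {0.0, 1.0}

    def test_lambda_zero_selects_cost_minimiser(self, prsa_run):
        """At a zero ceiling ratio the optimal strategy in every iteration
        is the cheapest one (no screening whenever screening carries a net
        positive cost)."""
        curve = ceac(prsa_run, [0.0], "qaly")
        winners = np.argmax(0.0 * prsa_run.delta_qaly - prsa_run.delta_cost, axis=1)
        np.testing.assert_array_equal(winners, np.argmin(prsa_run.delta_cost, axis=1))
        j = curve.strategies.index("no_screening")
        frac_net_costly = np.mean(np.all(
            np.delete(prsa_run.delta_cost, j, axis=1) > 0, axis=1))
        assert curve.probabilities[0, j] == pytest.approx(frac_net_costly)

    def test_most_effective_strategy_dominates_upper_tail(self, prsa_run):
        """Under base-centred distributions, the probability that the most
        effective frontier strategy is optimal is non-decreasing at high
        ceiling ratios."""
        lams = np.array([40_000.0, 60_000.0, 80_000.0, 100_000.0])
        curve = ceac(prsa_run, lams, "qaly")
        top = curve.strategies[int(np.argmax(
            [prsa_run.delta_qaly[:, j].mean() for j in range(len(curve.strategies))]))]
        j = curve.strategies.index(top)
        probs = curve.probabilities[:, j]
        assert np.all(np.diff(probs) >= -0.02)

    def test_monte_carlo_error_shrinks_with_iterations(self, prsa_run):
        """Empirical CEAC standard error scales like 1/sqrt(n): disjoint
        batches of 125 vs 500 iterations give a std ratio near 2."""
        lam = 20_000.0
        de = prsa_run.delta_qaly
        dc = prsa_run.delta_cost
        best = np.argmax(lam * de - dc, axis=1)
        top = np.bincount(best).argmax()
        wins = (best == top).astype(float)
        p_small = wins[:1500].reshape(12, 125).mean(axis=1)
        p_large = wins[:1500].reshape(3, 500).mean(axis=1)
        ratio = p_small.std(ddof=1) / max(p_large.std(ddof=1), 1e-9)
        assert 1.0 < ratio < 4.0

    def test_curve_frame_schema(self, prsa_run):
        frame = ceac(prsa_run, [0.0, 500.0], "ly").to_frame()
        assert list(frame.columns) == ["measure", "lambda", "strategy", "probability_optimal"]
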