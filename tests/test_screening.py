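"""Screening cascade: kernel mass conservation, cascade products,
surveillance schedules, complications, and the null-screening limit."""

import numpy as np
import pytest

from crc_cea.engine import evaluate_strategies, run_strategy
from crc_cea.params import ScreeningStrategy, synthesize_parameters
from crc_cea.screening import (
    SurveillanceTrack,
    build_screening_operator,
    screening_round_kernel,
    surveillance_due,
)
from crc_cea.states import (
    HealthState as S,
    N_EXPANDED,
    TRACKS,
    TRACK_LOW0,
    expanded_index,
)

NONE_TRACK = SurveillanceTrack()


def kernel_branches(state, params, strategy_name="annual_ifobt", track=NONE_TRACK, cycle=0):
    strat = {s.name: s for s in params.strategies}[strategy_name]
    return screening_round_kernel(state, track, strat, cycle, params)


class TestKernel:
    @pytest.mark.parametrize("strategy", ["no_screening", "annual_gfobt", "biennial_ifobt",
                                          "colonoscopy_10y"])
    @pytest.mark.parametrize("params_seed", [None, 0, 1])
    def test_mass_conservation_everywhere(self, fixture_params, strategy, params_seed):
        params = fixture_params if params_seed is None else synthesize_parameters(params_seed)
        strat = {s.name: s for s in params.strategies}[strategy]
        for state in S:
            for kind, years in TRACKS:
                track = SurveillanceTrack(kind, years)
                for cycle in (0, 1, 3):
                    branches, _ = screening_round_kernel(state, track, strat, cycle, params)
                    assert sum(b.prob for b in branches) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_specificity_means_no_positives(self, fixture_params):
        params = fixture_params.copy()
        params.tests["i_fobt"].specificity = 1.0
        branches, events = kernel_branches(S.NORMAL, params)
        assert events["positives"] == 0.0
        # Participants still pay the test kit; expected cost is c_screen x unit cost.
        expected = params.compliance.c_screen * params.costs.unit_cost["i_fobt"]
        assert sum(b.prob * b.cost for b in branches) == pytest.approx(expected)
        # No mass moves anywhere.
        assert all(b.state == S.NORMAL for b in branches)

    def test_colonoscopy_detects_with_participation_probability(self, fixture_params):
        """Colonoscopy is perfectly sensitive, so an undiagnosed stage-II
        cancer is diagnosed exactly when the person attends (60%)."""
        params = fixture_params.copy()
        colo = params.tests["colonoscopy"]
        colo.p_bleed = colo.p_perforation = colo.m_bleed = colo.m_perforation = 0.0
        branches, _ = kernel_branches(S.UNDIAG_CRC_II, params, "colonoscopy_10y")
        to_diag = sum(b.prob for b in branches if b.state == S.DIAG_CRC_II)
        assert to_diag == pytest.approx(0.60)

    def test_low_polyp_cascade_matches_enumerated_event_tree(self, fixture_params):
        """Hand-enumerated tree: participate -> test positive (sens_low) ->
        attend follow-up -> survive colonoscopy -> polypectomy -> normal
        epithelium on the 5-yearly surveillance track."""
        p = fixture_params
        colo = p.tests["colonoscopy"]
        p_fatal = colo.p_bleed * colo.m_bleed + colo.p_perforation * colo.m_perforation
        expected = (p.compliance.c_screen
                    * p.tests["i_fobt"].sens_low_polyp
                    * p.compliance.c_followup
                    * (1.0 - p_fatal))
        branches, events = kernel_branches(S.LOW_RISK_POLYP, p)
        moved = sum(b.prob for b in branches
                    if b.state == S.NORMAL and b.track == TRACK_LOW0)
        assert moved == pytest.approx(expected, abs=1e-15)
        assert events["polypectomies"] == pytest.approx(expected, abs=1e-15)

    def test_no_screening_strategy_never_screens(self, fixture_params):
        for state in (S.NORMAL, S.HIGH_RISK_POLYP, S.UNDIAG_CRC_III):
            branches, events = kernel_branches(state, fixture_params, "no_screening")
            assert branches == [(1.0, state, NONE_TRACK.index, 0.0)]
            assert not events

    def test_diagnosed_patients_receive_no_screening(self, fixture_params):
        branches, events = kernel_branches(S.DIAG_CRC_I, fixture_params, "annual_ifobt")
        assert len(branches) == 1 and branches[0].prob == 1.0
        assert branches[0].state == S.DIAG_CRC_I
        assert not events

    def test_surveillance_supersedes_routine_screening(self, fixture_params):
        """A patient on a not-yet-due surveillance track is not offered the
        routine stool test that cycle."""
        track = SurveillanceTrack("post_low_risk_polypectomy", 2)
        branches, events = kernel_branches(S.NORMAL, fixture_params, "annual_ifobt", track)
        assert len(branches) == 1 and branches[0].prob == 1.0
        assert not events


class TestSurveillanceSchedule:
    def test_low_risk_track_is_five_yearly(self):
        assert surveillance_due(SurveillanceTrack("post_low_risk_polypectomy", 5))
        assert not surveillance_due(SurveillanceTrack("post_low_risk_polypectomy", 4))

    def test_high_risk_track_is_annual(self):
        assert surveillance_due(SurveillanceTrack("post_high_risk_polypectomy", 1))
        assert not surveillance_due(SurveillanceTrack("post_high_risk_polypectomy", 0))

    def test_none_track_has_no_schedule(self):
        with pytest.raises(ValueError):
            surveillance_due(SurveillanceTrack("none", 3))

    def test_due_surveillance_triggers_colonoscopy(self, fixture_params):
        track = SurveillanceTrack("post_high_risk_polypectomy", 1)
        _, events = kernel_branches(S.NORMAL, fixture_params, "no_screening", track)
        assert events["surveillance_colonoscopies"] == pytest.approx(
            fixture_params.compliance.c_followup)


class TestHarmAccounting:
    def test_certain_fatal_perforation_kills_every_participant(self, fixture_params):
        params = fixture_params.copy()
        colo = params.tests["colonoscopy"]
        colo.p_perforation = 1.0
        colo.m_perforation = 1.0
        colo.p_bleed = 0.0
        for state in (S.NORMAL, S.LOW_RISK_POLYP, S.UNDIAG_CRC_I):
            branches, events = kernel_branches(state, params, "annual_ifobt")
            attend = (params.compliance.c_screen
                      * (1 - params.tests["i_fobt"].specificity
                         if state == S.NORMAL
                         else params.tests["i_fobt"].sensitivity_for(state))
                      * params.compliance.c_followup)
            dead = sum(b.prob for b in branches if b.state == S.DEATH_COMPLICATION)
            assert dead == pytest.approx(attend, abs=1e-15)
            assert events["complication_deaths"] == pytest.approx(attend, abs=1e-15)

    def test_complication_deaths_bounded_by_colonoscopy_harm(self, fixture_params):
        op = build_screening_operator(fixture_params, fixture_params.tests["i_fobt"])
        colo = fixture_params.tests["colonoscopy"]
        bound = colo.p_bleed * colo.m_bleed + colo.p_perforation * colo.m_perforation
        assert np.all(op.events["complication_deaths"]
                      <= op.events["colonoscopies"] * bound + 1e-12)


class TestOperators:
    @pytest.mark.parametrize("test_name", [None, "g_fobt", "i_fobt", "colonoscopy"])
    def test_operator_rows_are_stochastic(self, fixture_params, test_name):
        test = fixture_params.tests[test_name] if test_name else None
        op = build_screening_operator(fixture_params, test)
        np.testing.assert_allclose(op.S.sum(axis=1), np.ones(N_EXPANDED), atol=1e-12)

    def test_operator_matches_kernel(self, fixture_params):
        op = build_screening_operator(fixture_params, fixture_params.tests["i_fobt"])
        branches, _ = kernel_branches(S.LOW_RISK_POLYP, fixture_params)
        i = expanded_index(0, S.LOW_RISK_POLYP)
        for b in branches:
            j = expanded_index(b.track, b.state)
            assert op.S[i, j] >= b.prob - 1e-15


class TestNullScreeningEquivalence:
    def test_zero_participation_equals_no_screening_exactly(self, fixture_params):
        params = fixture_params.copy()
        params.compliance.c_screen = 0.0
        by_name = {s.name: s for s in params.strategies}
        _, none_out = run_strategy(by_name["no_screening"], params)
        for name in ("annual_gfobt", "biennial_ifobt", "colonoscopy_10y"):
            traces, out = run_strategy(by_name[name], params)
            assert out.cost_per_person == none_out.cost_per_person
            assert out.ly_per_person == none_out.ly_per_person
            assert out.qaly_per_person == none_out.qaly_per_person
            for trace in traces.values():
                assert all(ev.screening_cost == 0.0 for ev in trace.events)

    def test_blind_but_specific_test_changes_nothing_clinically(self, fixture_params):
        params = fixture_params.copy()
        ifobt = params.tests["i_fobt"]
        ifobt.sens_low_polyp = ifobt.sens_high_polyp = 0.0
        ifobt.sens_crc = [0.0] * 4
        ifobt.specificity = 1.0
        by_name = {s.name: s for s in params.strategies}
        _, none_out = run_strategy(by_name["no_screening"], params)
        _, out = run_strategy(by_name["annual_ifobt"], params)
        assert out.ly_per_person == pytest.approx(none_out.ly_per_person, abs=1e-14)
        assert out.qaly_per_person == pytest.approx(none_out.qaly_per_person, abs=1e-14)
        assert out.cost_per_person > none_out.cost_per_person  # test kits still paid


class TestInformationDominance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_higher_sensitivity_never_reduces_life_years(self, seed):
        """With complication-free colonoscopy, scaling every I-FOBT
        sensitivity up cannot reduce discounted life-years."""
        params = synthesize_parameters(seed)
        colo = params.tests["colonoscopy"]
        colo.p_bleed = colo.p_perforation = colo.m_bleed = colo.m_perforation = 0.0
        strat = {s.name: s for s in params.strategies}["annual_ifobt"]
        lys = []
        for scale in (0.25, 0.5, 1.0):
            p = params.copy()
            t = p.tests["i_fobt"]
            base = params.tests["i_fobt"]
            t.sens_low_polyp = base.sens_low_polyp * scale
            t.sens_high_polyp = base.sens_high_polyp * scale
            t.sens_crc = [s * scale for s in base.sens_crc]
            _, out = run_strategy(strat, p)
            lys.append(out.ly_per_person)
        assert lys == sorted(lys)
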