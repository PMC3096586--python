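import math

import numpy as np
import pytest
from scipy import stats

from ptimebox import (
    CompileError,
    HmmState,
    LinearHMM,
    PROBABILISTIC,
    QuerySpec,
    Timebox,
    TimeCourseSet,
    ValidationError,
    box_to_state,
    compile_hmm,
    emission_logdensity,
    forward_loglik,
)
from ptimebox.hmm import NORMAL, UNIFORM, _normalize_durations

from conftest import random_tcs
from oracles import forward_by_enumeration, random_course, random_linear_hmm


def _pspec(*boxes, m=1):
    return QuerySpec(boxes=tuple(boxes), mode=PROBABILISTIC, stringency_m=m)


def _flat_tcs(n_times, lo=0.0, hi=2.0):
    values = np.vstack([np.full(n_times, lo), np.full(n_times, hi)])
    return TimeCourseSet(["low", "high"], list(range(1, n_times + 1)), values)


class TestBoxToState:
    def test_midpoint_quarter_height_rule(self):
        s = box_to_state(Timebox(1, 3, 0, 2))
        assert s.kind == NORMAL
        assert s.mu == 1.0
        assert s.sigma == 0.5
        assert s.expected_duration == 2.0
        assert s.self_prob == 0.5

    def test_unit_duration_box_emits_exactly_once(self):
        s = box_to_state(Timebox(2, 3, -1, 1))
        assert s.self_prob == 0.0
        assert s.expected_duration == 1.0

    def test_box_interval_holds_955_percent_of_mass(self):
        b = Timebox(1, 3, 0.7, 4.1)
        s = box_to_state(b)
        mass = stats.norm.cdf(b.x_hi, s.mu, s.sigma) - stats.norm.cdf(b.x_lo, s.mu, s.sigma)
        assert mass == pytest.approx(2 * stats.norm.cdf(2) - 1, abs=1e-12)
        assert mass == pytest.approx(0.9545, abs=5e-5)


class TestHmmState:
    def test_duration_self_prob_consistency_enforced(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            HmmState(NORMAL, expected_duration=2.0, self_prob=0.9, mu=0, sigma=1)

    def test_sub_unit_duration_rejected(self):
        with pytest.raises(ValidationError):
            HmmState(NORMAL, expected_duration=0.5, self_prob=-1.0, mu=0, sigma=1)

    def test_uniform_needs_positive_width(self):
        with pytest.raises(ValidationError):
            HmmState(UNIFORM, expected_duration=1.0, self_prob=0.0, lo=1.0, hi=1.0)


class TestEmissionLogdensity:
    def test_standard_normal_at_mean(self):
        s = HmmState(NORMAL, 2.0, 0.5, mu=0.0, sigma=1.0)
        assert emission_logdensity(s, 0.0) == pytest.approx(-0.9189385332046727, abs=1e-12)

    def test_uniform_inside_support(self):
        s = HmmState(UNIFORM, 2.0, 0.5, lo=0.0, hi=2.0)
        assert emission_logdensity(s, 1.0) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_uniform_outside_support_is_minus_inf(self):
        s = HmmState(UNIFORM, 2.0, 0.5, lo=0.0, hi=2.0)
        assert emission_logdensity(s, 3.0) == -math.inf

    def test_missing_observation_is_marginalized(self):
        s = HmmState(NORMAL, 2.0, 0.5, mu=0.0, sigma=1.0)
        assert emission_logdensity(s, math.nan) == 0.0
        assert emission_logdensity(s, None) == 0.0

    def test_matches_scipy_everywhere(self, rng):
        s = HmmState(NORMAL, 3.0, 1 - 1 / 3, mu=1.3, sigma=0.7)
        xs = rng.normal(0, 3, size=20)
        np.testing.assert_allclose(
            s.log_density_array(xs), stats.norm.logpdf(xs, 1.3, 0.7), rtol=1e-12
        )


class TestCompile:
    def test_two_abutting_boxes_cover_everything(self):
        tcs = _flat_tcs(6)
        hmm = compile_hmm(_pspec(Timebox(1, 3.5, 0, 1), Timebox(3.5, 6, 1, 2)), tcs)
        assert hmm.K == 2
        assert all(s.kind == NORMAL for s in hmm.states)
        assert hmm.total_expected_duration() == pytest.approx(6.0, abs=1e-9)

    def test_single_interior_box_gets_flanking_uniforms(self):
        tcs = _flat_tcs(7)
        hmm = compile_hmm(_pspec(Timebox(3, 5, 0, 2)), tcs)
        assert [s.kind for s in hmm.states] == [UNIFORM, NORMAL, UNIFORM]
        assert hmm.total_expected_duration() == pytest.approx(7.0, abs=1e-9)

    def test_full_span_box_degenerates_to_one_state(self):
        T = 5
        tcs = _flat_tcs(T)
        hmm = compile_hmm(_pspec(Timebox(1, T, 0, 2)), tcs)
        assert hmm.K == 1
        assert hmm.states[0].self_prob == pytest.approx(1 - 1 / T, abs=1e-12)
        # forward likelihood = product of normal densities * p^(T-1)
        course = np.full(T, 1.0)
        s = hmm.states[0]
        expected = T * stats.norm.logpdf(1.0, s.mu, s.sigma) + (T - 1) * math.log(s.self_prob)
        assert forward_loglik(hmm, course) == pytest.approx(expected, rel=1e-12)

    def test_gap_between_boxes_becomes_one_uniform(self):
        tcs = _flat_tcs(10)
        hmm = compile_hmm(_pspec(Timebox(1, 3, 0, 1), Timebox(6, 10, 1, 2)), tcs)
        assert [s.kind for s in hmm.states] == [NORMAL, UNIFORM, NORMAL]

    def test_uniform_support_is_data_range(self, rng):
        tcs = random_tcs(rng, 10, 7)
        lo, hi = tcs.data_range()
        hmm = compile_hmm(_pspec(Timebox(3, 5, 0, 2)), tcs)
        u = hmm.states[0]
        assert (u.lo, u.hi) == (lo, hi)

    def test_support_pad_widens_uniforms(self, rng):
        tcs = random_tcs(rng, 10, 7)
        lo, hi = tcs.data_range()
        hmm = compile_hmm(_pspec(Timebox(3, 5, 0, 2)), tcs, support_pad=1.5)
        assert hmm.states[0].lo == pytest.approx(lo - 1.5)
        assert hmm.states[0].hi == pytest.approx(hi + 1.5)

    def test_transition_conservation(self, rng):
        tcs = random_tcs(rng, 5, 9)
        hmm = compile_hmm(_pspec(Timebox(2, 4, 0, 1), Timebox(5.5, 8, -1, 0)), tcs)
        for s in hmm.states:
            assert s.self_prob + (1 - s.self_prob) == 1.0

    def test_deterministic_spec_rejected(self, rng):
        tcs = random_tcs(rng, 3, 5)
        with pytest.raises(CompileError):
            compile_hmm(QuerySpec(boxes=(Timebox(1, 5, 0, 1),), mode="deterministic"), tcs)

    def test_constant_data_gets_token_uniform_support(self):
        values = np.full((2, 6), 1.0)
        tcs = TimeCourseSet(["a", "b"], list(range(1, 7)), values)
        hmm = compile_hmm(_pspec(Timebox(2, 4, 0, 2)), tcs)
        u = hmm.states[0]
        assert u.hi > u.lo


class TestDurationNormalization:
    def test_plain_rescale(self):
        d = _normalize_durations([2.0, 2.0], 6.0)
        np.testing.assert_allclose(d, [3.0, 3.0])

    def test_clamp_and_redistribute(self):
        # scale 5/10 would push the short state to 0.5 -> clamp to 1,
        # remaining 4 goes to the long state
        d = _normalize_durations([1.0, 9.0], 5.0)
        np.testing.assert_allclose(d, [1.0, 4.0])
        assert d.sum() == pytest.approx(5.0, abs=1e-12)

    def test_iterated_fixpoint(self):
        d = _normalize_durations([1.0, 1.2, 20.0], 4.0)
        assert d.sum() == pytest.approx(4.0, abs=1e-9)
        assert (d >= 1.0 - 1e-12).all()

    def test_too_many_states_raises(self):
        with pytest.raises(CompileError):
            _normalize_durations([1.0, 1.0, 1.0], 2.0)


class TestForward:
    def test_single_state_single_step(self):
        hmm = LinearHMM(states=(HmmState(NORMAL, 2.0, 0.5, mu=1.0, sigma=0.5),))
        got = forward_loglik(hmm, np.array([1.0]))
        assert got == pytest.approx(float(stats.norm.logpdf(1.0, 1.0, 0.5)), rel=1e-12)

    def test_two_state_three_step_hand_enumeration(self):
        s1 = HmmState(NORMAL, 2.0, 0.5, mu=0.0, sigma=1.0)
        s2 = HmmState(NORMAL, 2.0, 0.5, mu=2.0, sigma=0.5)
        hmm = LinearHMM(states=(s1, s2))
        o = np.array([0.1, 1.5, 2.2])
        # paths: 1-1-2 and 1-2-2
        def e(s, x):
            return float(stats.norm.pdf(x, s.mu, s.sigma))

        p112 = e(s1, o[0]) * 0.5 * e(s1, o[1]) * 0.5 * e(s2, o[2])
        p122 = e(s1, o[0]) * 0.5 * e(s2, o[1]) * 0.5 * e(s2, o[2])
        assert forward_loglik(hmm, o) == pytest.approx(math.log(p112 + p122), rel=1e-9)

    def test_uniform_only_closed_form(self):
        T, w, d = 5, 4.0, 3.0
        p = 1 - 1 / d
        hmm = LinearHMM(states=(HmmState(UNIFORM, d, p, lo=-2.0, hi=2.0),))
        o = np.zeros(T)
        expected = T * math.log(1 / w) + (T - 1) * math.log(p)
        assert forward_loglik(hmm, o) == pytest.approx(expected, rel=1e-12)
        assert forward_loglik(hmm, o) == pytest.approx(forward_by_enumeration(hmm, o), rel=1e-9)

    def test_course_shorter_than_chain_scores_minus_inf(self):
        s = HmmState(NORMAL, 2.0, 0.5, mu=0.0, sigma=1.0)
        hmm = LinearHMM(states=(s, s, s))
        assert forward_loglik(hmm, np.zeros(2)) == -math.inf

    def test_out_of_support_observation_can_zero_the_likelihood(self):
        hmm = LinearHMM(states=(HmmState(UNIFORM, 2.0, 0.5, lo=0.0, hi=1.0),))
        assert forward_loglik(hmm, np.array([0.5, 7.0])) == -math.inf

    def test_missing_values_are_marginalized(self):
        s = HmmState(NORMAL, 2.0, 0.5, mu=0.0, sigma=1.0)
        hmm = LinearHMM(states=(s,))
        full = forward_loglik(hmm, np.array([0.0, 0.0]))
        with_gap = forward_loglik(hmm, np.array([0.0, np.nan]))
        # the missing step contributes only its self-transition
        assert with_gap == pytest.approx(full - float(stats.norm.logpdf(0.0, 0, 1)), rel=1e-12)

    def test_oracle_equivalence_random_models(self, rng):
        for _ in range(200):
            hmm = random_linear_hmm(rng, max_states=4)
            T = int(rng.integers(1, 7))
            o = random_course(rng, T, missing_prob=0.15)
            got = forward_loglik(hmm, o)
            want = forward_by_enumeration(hmm, o)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, rel=1e-9)


class TestModelProperties:
    def test_translation_equivariance(self, rng):
        tcs = random_tcs(rng, 12, 8, missing_prob=0.1)
        spec = _pspec(Timebox(2, 4, -1, 1), Timebox(5, 7.5, 0.5, 2.5), m=5)
        c = 3.7
        shifted = TimeCourseSet(tcs.ids, tcs.times, tcs.values + c)
        shifted_spec = _pspec(
            *[Timebox(b.t_lo, b.t_hi, b.x_lo + c, b.x_hi + c) for b in spec.boxes], m=5
        )
        base = [forward_loglik(compile_hmm(spec, tcs), row) for row in tcs.values]
        moved = [
            forward_loglik(compile_hmm(shifted_spec, shifted), row) for row in shifted.values
        ]
        base_diffs = np.diff([b for b in base if not math.isinf(b)])
        moved_diffs = np.diff([m for m in moved if not math.isinf(m)])
        np.testing.assert_allclose(base_diffs, moved_diffs, rtol=1e-9, atol=1e-9)

    def test_mean_trajectory_beats_noisy_versions_in_expectation(self, rng):
        T = 8
        tcs = _flat_tcs(T, lo=-3.0, hi=3.0)
        spec = _pspec(Timebox(1, 4.5, 1, 3), Timebox(4.5, T, -3, -1))
        hmm = compile_hmm(spec, tcs)
        ideal = np.array([2.0] * 4 + [-2.0] * 4)
        ideal_ll = forward_loglik(hmm, ideal)
        noisy_lls = [
            forward_loglik(hmm, ideal + rng.normal(0, 0.5, size=T)) for _ in range(100)
        ]
        assert ideal_ll >= np.mean(noisy_lls)

    def test_no_adjacent_uniform_states_allowed(self):
        u = HmmState(UNIFORM, 2.0, 0.5, lo=0.0, hi=1.0)
        with pytest.raises(ValidationError, match="adjacent uniform"):
            LinearHMM(states=(u, u))


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        tcs = random_tcs(rng, 5, 9)
        hmm = compile_hmm(_pspec(Timebox(2, 4, 0, 1), Timebox(6, 8, -1, 0)), tcs)
        p = tmp_path / "model.json"
        hmm.save(p)
        back = LinearHMM.load(p)
        assert back == hmm
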