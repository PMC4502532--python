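"""Mean-field analysis over the four action-score classes: expected
payoffs under assorted matching, replicator flow, fixed points and
stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scorepgg as sp


def masses(draw_floats):
    raw = np.array(draw_floats)
    return raw / raw.sum()


class TestClassState:
    def test_mass_bookkeeping(self):
        cs = sp.ClassState(0.4, 0.1, 0.3, 0.2)
        assert cs.p_C == pytest.approx(0.7)
        assert cs.p_D == pytest.approx(0.3)

    def test_rejects_unnormalized_or_negative(self):
        with pytest.raises(ValueError):
            sp.ClassState(0.5, 0.5, 0.5, 0.0)
        with pytest.raises(ValueError):
            sp.ClassState(-0.2, 0.5, 0.5, 0.2)


class TestExpectedClassPayoffs:
    def test_benchmark_state_reproduces_printed_formulas(self, params_fig1):
        """At p_C1=(n-s)/n, p_D1=0 the class payoffs are pi_C1 = r,
        pi_C0 = (s - n p_D0) r/s and pi_D0 = 1 + (s - n p_D0) r/s."""
        n, s, r = 1500, 5, 4.0
        p_D0 = 0.001
        cs = sp.reference_state(params_fig1, p_D0)
        pay = sp.expected_class_payoffs(cs, params_fig1)
        assert pay.pi_C1 == pytest.approx(r)
        assert pay.pi_C0 == pytest.approx((s - n * p_D0) * r / s)
        assert pay.pi_D0 == pytest.approx(1 + (s - n * p_D0) * r / s)
        assert pay.pi_D0 - pay.pi_C0 == pytest.approx(1.0)

    def test_spec_numeric_example(self, params_fig1):
        cs = sp.reference_state(params_fig1, 0.001)
        pay = sp.expected_class_payoffs(cs, params_fig1)
        assert pay.pi_C0 == pytest.approx((5 - 1.5) * 0.8)
        assert pay.pi_D0 == pytest.approx(3.8)

    def test_lone_cooperator_class_payoff(self, params_fig1):
        n = params_fig1.n
        cs = sp.ClassState(1 / n, 0.0, 0.0, 1 - 1 / n)
        pay = sp.expected_class_payoffs(cs, params_fig1)
        assert pay.pi_C1 == pytest.approx(0.8)
        assert pay.pi_C1 < 1.0

    def test_pi_bar_is_mass_weighted_average(self):
        params = sp.validate_params(n=100, s=5, r=3.0)
        cs = sp.ClassState(0.3, 0.2, 0.1, 0.4)
        pay = sp.expected_class_payoffs(cs, params)
        assert pay.pi_bar == pytest.approx(
            cs.as_array() @ pay.as_array(), abs=1e-12
        )

    def test_oracle_equivalence_with_stochastic_matcher(self):
        """The mean-field class payoffs agree with the exact expectation
        of the random score-ranked matcher, estimated by Monte Carlo on
        a small population (3 standard errors)."""
        params = sp.validate_params(n=20, s=5, r=4.0)
        counts = {"C1": 9, "D1": 3, "C0": 4, "D0": 4}
        strategies = np.array([1] * 9 + [0] * 3 + [1] * 4 + [0] * 4)
        scores = np.array([1] * 12 + [0] * 8)
        cs = sp.ClassState(9 / 20, 3 / 20, 4 / 20, 4 / 20)
        pay = sp.expected_class_payoffs(cs, params)
        rng = np.random.Generator(np.random.PCG64(11))
        reps = 4000
        class_masks = {
            "C1": (strategies == 1) & (scores == 1),
            "D1": (strategies == 0) & (scores == 1),
            "C0": (strategies == 1) & (scores == 0),
            "D0": (strategies == 0) & (scores == 0),
        }
        sums = {name: np.empty(reps) for name in counts}
        for rep in range(reps):
            groups = sp.match_by_score(scores, params, rng)
            state = sp.PopulationState(strategies, scores, groups)
            phi = sp.compute_payoffs(state, params)
            for name, mask in class_masks.items():
                sums[name][rep] = phi[mask].mean()
        expected = {
            "C1": pay.pi_C1, "D1": pay.pi_D1, "C0": pay.pi_C0, "D0": pay.pi_D0
        }
        for name in counts:
            mc_mean = sums[name].mean()
            se = sums[name].std(ddof=1) / np.sqrt(reps)
            assert abs(mc_mean - expected[name]) < 3 * se + 1e-12, name


class TestReplicatorDerivative:
    def test_monomorphic_cooperation_is_stationary(self):
        params = sp.validate_params(n=100, s=5, r=3.0)
        cs = sp.ClassState(1.0, 0.0, 0.0, 0.0)
        pay = sp.expected_class_payoffs(cs, params)
        dC, dD = sp.replicator_derivative(cs, pay)
        assert dC == pytest.approx(0.0, abs=1e-12)
        assert dD == pytest.approx(0.0, abs=1e-12)

    def test_lone_cooperator_shrinks(self, params_fig1):
        n = params_fig1.n
        cs = sp.ClassState(1 / n, 0.0, 0.0, 1 - 1 / n)
        pay = sp.expected_class_payoffs(cs, params_fig1)
        dC, _ = sp.replicator_derivative(cs, pay)
        assert dC < 0

    @settings(max_examples=50, deadline=None)
    @given(
        raw=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        n=st.sampled_from([60, 150, 1500]),
        r=st.floats(1.1, 5.0),
    )
    def test_growth_rates_sum_to_zero(self, raw, n, r):
        params = sp.validate_params(n=n, s=5, r=r)
        cs = sp.ClassState.from_array(masses(raw))
        pay = sp.expected_class_payoffs(cs, params)
        dC, dD = sp.replicator_derivative(cs, pay)
        assert dC + dD == pytest.approx(0.0, abs=1e-12)


class TestStationaryPD0:
    @pytest.mark.parametrize("n, r", [(1500, 4.0), (1500, 1.1), (150, 4.0), (150, 1.1)])
    def test_root_is_interior_and_high_cooperation(self, n, r):
        params = sp.validate_params(n=n, s=5, r=r)
        x = sp.stationary_pD0_image(params)
        assert 0 < x < params.s / params.n
        cs = sp.reference_state(params, x)
        pay = sp.expected_class_payoffs(cs, params)
        dC, _ = sp.replicator_derivative(cs, pay)
        assert abs(dC) < 1e-10
        assert cs.p_C > (params.s - 1) / params.s

    def test_value_against_symbolic_oracle(self, params_fig1):
        """Solve the zero-growth condition symbolically from the printed
        payoff expressions and compare (expected ~8.354e-4)."""
        import sympy

        x = sympy.Symbol("x", positive=True)
        n, s, r = 1500, 5, sympy.Rational(4)
        pC1 = sympy.Rational(n - s, n)
        pC0 = sympy.Rational(s, n) - x
        piC1 = r
        piC0 = (s - n * x) * r / s
        piD0 = 1 + piC0
        pibar = pC1 * piC1 + pC0 * piC0 + x * piD0
        growth = pC1 * (piC1 - pibar) + pC0 * (piC0 - pibar)
        roots = [
            sympy.nsimplify(sol)
            for sol in sympy.solve(sympy.expand(growth), x)
            if 0 < sol < sympy.Rational(s, n)
        ]
        assert len(roots) == 1
        assert float(roots[0]) == pytest.approx(1 / 1197)
        assert sp.stationary_pD0_image(params_fig1) == pytest.approx(
            float(roots[0]), abs=1e-12
        )

    def test_root_is_bracketed_by_opposite_signs(self, params_fig1):
        x = sp.stationary_pD0_image(params_fig1)

        def growth(v):
            cs = sp.reference_state(params_fig1, v)
            return sp.replicator_derivative(
                cs, sp.expected_class_payoffs(cs, params_fig1)
            )[0]

        assert growth(x / 2) * growth(2 * x) < 0


class TestScoreTransition:
    def test_image_sends_actions_to_their_scores(self):
        params = sp.validate_params(n=100, s=5, r=3.0)
        cs = sp.ClassState(0.3, 0.2, 0.1, 0.4)
        out = sp.score_transition(cs, params, "image")
        assert out.p_C1 == pytest.approx(0.4)
        assert out.p_D0 == pytest.approx(0.6)
        assert out.p_D1 == out.p_C0 == 0.0

    def test_image_monomorphic_tie_retains(self):
        params = sp.validate_params(n=100, s=5, r=3.0)
        cs = sp.ClassState(0.7, 0.0, 0.3, 0.0)
        out = sp.score_transition(cs, params, "image")
        assert out == cs

    def test_group_keeps_free_riders_promoted(self, params_fig1):
        """Near the benchmark state, score-one defectors stay in the
        top groups under group scoring (they inherit their groupmates'
        reputation) while image scoring demotes them."""
        eps = 1e-4
        base = sp.reference_state(params_fig1, sp.stationary_pD0_image(params_fig1))
        raw = base.as_array() * (1 - eps)
        raw[1] += eps
        cs = sp.ClassState.from_array(raw)
        grp = sp.score_transition(cs, params_fig1, "group")
        img = sp.score_transition(cs, params_fig1, "image")
        assert grp.p_D1 >= cs.p_D1 * 0.99
        assert img.p_D1 == 0.0

    def test_mass_conserved_by_all_rules(self):
        params = sp.validate_params(n=100, s=5, r=3.0, p=0.3)
        cs = sp.ClassState(0.35, 0.15, 0.25, 0.25)
        for rule in sp.SCORING_RULES:
            out = sp.score_transition(cs, params, rule)
            assert out.as_array().sum() == pytest.approx(1.0, abs=1e-12)


class TestIntegrateAndProbe:
    def test_monomorphic_defection_is_fixed_point(self):
        params = sp.validate_params(n=100, s=5, r=3.0)
        cs = sp.ClassState(0.0, 0.0, 0.0, 1.0)
        traj = sp.integrate_replicator(cs, params, "image", horizon=20)
        assert all(state.p_D0 == pytest.approx(1.0) for state in traj)

    @pytest.mark.parametrize("rule", sp.SCORING_RULES)
    def test_near_all_defect_converges_to_zero_cooperation(self, rule):
        params = sp.validate_params(n=1500, s=5, r=4.0, p=0.5)
        cs = sp.ClassState(1 / 1500, 0.0, 0.0, 1 - 1 / 1500)
        traj = sp.integrate_replicator(cs, params, rule, horizon=2000)
        assert traj[-1].p_C < 1e-12

    def test_image_benchmark_probe_is_stable(self, params_fig1):
        ref = sp.reference_state(
            params_fig1, sp.stationary_pD0_image(params_fig1)
        )
        report = sp.stability_probe(ref, params_fig1, "image", epsilon=1e-4)
        assert report.stable
        assert report.trajectory[-1].p_C >= ref.p_C - 2e-4

    def test_group_benchmark_probe_is_unstable(self, params_fig1):
        ref = sp.reference_state(
            params_fig1, sp.stationary_pD0_image(params_fig1)
        )
        report = sp.stability_probe(ref, params_fig1, "group", epsilon=1e-4)
        assert not report.stable
        assert report.trajectory[-1].p_C < 0.1

    def test_zero_epsilon_is_trivially_stable(self, params_fig1):
        ref = sp.reference_state(params_fig1, 1e-3)
        report = sp.stability_probe(ref, params_fig1, "group", epsilon=0.0)
        assert report.stable
        assert report.trajectory == [ref]

    def test_negative_epsilon_rejected(self, params_fig1):
        with pytest.raises(ValueError):
            sp.stability_probe(
                sp.reference_state(params_fig1, 1e-3),
                params_fig1, "image", epsilon=-1e-4,
            )
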