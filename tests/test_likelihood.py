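"""Biallelic two-population likelihood: closed forms, normalization,
symmetries, and agreement between the exact root treatment and long
finite-time propagation."""

import math
from collections import namedtuple

import numpy as np
import pytest
from scipy.linalg import expm

from codivergence.likelihood import (
    BranchPartial,
    PairModel,
    build_generator,
    comparison_log_likelihood,
    mc_oracle_log_likelihood,
    pattern_log_likelihood,
    propagate_branch,
    state_index,
    survival_to_root,
    transition_prob_same,
)

Pat = namedtuple("Pat", "n1 r1 n2 r2")


class TestTransitionProb:
    def test_identity_at_zero(self):
        assert transition_prob_same(0.0) == 1.0

    def test_stationary_limit(self):
        assert transition_prob_same(50.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        assert transition_prob_same(math.log(2) / 2) == pytest.approx(0.75)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_prob_same(-0.1)


class TestPropagateBranch:
    def test_zero_length_is_identity(self):
        p = BranchPartial.from_tip_counts(1, 1)
        out = propagate_branch(p, 0.0, theta=0.01)
        np.testing.assert_allclose(out.mass, p.mass, atol=1e-12)

    def test_single_lineage_mixes_like_two_state_chain(self):
        length = 0.37
        p = BranchPartial.from_tip_counts(1, 1)
        out = propagate_branch(p, length, theta=0.01)
        p_same = transition_prob_same(length)
        assert out.mass[state_index(1, 1)] == pytest.approx(p_same, abs=1e-9)
        assert out.mass[state_index(1, 0)] == pytest.approx(1 - p_same, abs=1e-9)

    def test_small_theta_forces_instant_coalescence(self):
        p = BranchPartial.from_tip_counts(2, 2)
        out = propagate_branch(p, 0.05, theta=1e-7)
        mass_m2 = sum(out.mass[state_index(2, j)] for j in range(3))
        assert mass_m2 < 1e-6
        assert out.total() == pytest.approx(1.0, abs=1e-4)  # same-state pair survives

    def test_infinite_root_matches_long_finite_propagation(self):
        # exact absorption solve vs explicit propagation until <1e-10 mass
        # remains on multi-lineage states; agreement within 1e-8
        theta = 0.004
        p = BranchPartial.from_tip_counts(4, 2)
        exact = propagate_branch(p, math.inf, theta)
        q = build_generator(4, theta)
        t = 1.0
        while True:
            mass = p.mass @ expm(q * t)
            multi = sum(
                mass[state_index(m, j)] for m in range(2, 5) for j in range(m + 1)
            )
            if multi < 1e-10:
                break
            t *= 2
        surviving = mass[state_index(1, 0)] + mass[state_index(1, 1)]
        assert exact.mass[state_index(1, 0)] + exact.mass[state_index(1, 1)] == pytest.approx(
            surviving, abs=1e-8
        )

    def test_bad_theta_rejected(self):
        with pytest.raises(ValueError):
            propagate_branch(BranchPartial.from_tip_counts(1, 0), 1.0, theta=0.0)


MODEL = PairModel(tau=0.002, theta1=0.004, theta2=0.003, root_multiplier=1.1)


class TestPatternLogLikelihood:
    def test_single_copy_is_stationary_half(self):
        for r in (0, 1):
            assert math.exp(pattern_log_likelihood(Pat(1, r, 0, 0), MODEL)) == (
                pytest.approx(0.5, abs=1e-10)
            )

    def test_two_lineage_closed_form(self):
        # P(two copies, one per population, share a state)
        # = (1 + exp(-4 tau) / (1 + 8 theta_root)) / 2
        same = math.exp(pattern_log_likelihood(Pat(1, 1, 1, 1), MODEL)) + math.exp(
            pattern_log_likelihood(Pat(1, 0, 1, 0), MODEL)
        )
        closed = 0.5 * (1 + math.exp(-4 * MODEL.tau) / (1 + 8 * MODEL.theta_root))
        assert same == pytest.approx(closed, abs=1e-10)

    @pytest.mark.parametrize(
        "n1,n2", [(1, 1), (2, 2), (3, 2), (4, 2), (3, 3), (5, 1), (6, 0)]
    )
    @pytest.mark.parametrize(
        "model",
        [
            MODEL,
            PairModel(tau=0.0, theta1=0.01, theta2=0.01),
            PairModel(tau=0.1, theta1=0.05, theta2=0.001, root_multiplier=0.3),
            PairModel(tau=1.5, theta1=0.5, theta2=0.2, root_multiplier=3.0),
        ],
    )
    def test_normalization(self, n1, n2, model):
        total = sum(
            math.exp(pattern_log_likelihood(Pat(n1, r1, n2, r2), model))
            for r1 in range(n1 + 1)
            for r2 in range(n2 + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_relabeling_flips_leave_likelihood_unchanged(self):
        a = pattern_log_likelihood(Pat(3, 1, 2, 2), MODEL)
        b = pattern_log_likelihood(Pat(3, 2, 2, 0), MODEL)
        assert a == pytest.approx(b, abs=1e-12)

    def test_population_label_symmetry(self):
        swapped = PairModel(
            tau=MODEL.tau,
            theta1=MODEL.theta2,
            theta2=MODEL.theta1,
            root_multiplier=MODEL.root_multiplier,
        )
        a = pattern_log_likelihood(Pat(3, 1, 2, 2), MODEL)
        b = pattern_log_likelihood(Pat(2, 2, 3, 1), swapped)
        assert a == pytest.approx(b, abs=1e-12)

    def test_identity_probability_decreases_with_tau_and_root_size(self):
        def p_same(tau, mult):
            m = PairModel(tau=tau, theta1=0.004, theta2=0.004, root_multiplier=mult)
            return math.exp(pattern_log_likelihood(Pat(1, 1, 1, 1), m))

        taus = [0.0, 0.001, 0.01, 0.1, 1.0]
        vals = [p_same(t, 1.0) for t in taus]
        assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))
        mults = [0.1, 0.5, 1.0, 5.0]
        vals = [p_same(0.01, m) for m in mults]
        assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            pattern_log_likelihood(Pat(0, 0, 0, 0), MODEL)


class TestComparisonLogLikelihood:
    def test_one_constant_single_copy_site(self):
        class Data:
            @staticmethod
            def pattern_arrays():
                return (
                    np.array([1]),
                    np.array([0]),
                    np.array([0]),
                    np.array([0]),
                    np.array([1.0]),
                )

        assert comparison_log_likelihood(Data(), MODEL) == pytest.approx(math.log(0.5))

    def test_global_relabeling_invariance(self, study_priors):
        from tests.conftest import make_binary_comparison

        cols = [[0, 1, 0, 1], [1, 1, 0, 0], [0, 0, 0, 1], [1, None, 1, 0]]
        data = make_binary_comparison("flip", cols, 2, 2)
        flipped = make_binary_comparison(
            "flip2", [[1 - v if v is not None else None for v in c] for c in cols], 2, 2
        )
        a = comparison_log_likelihood(data, MODEL)
        b = comparison_log_likelihood(flipped, MODEL)
        assert a == pytest.approx(b, abs=1e-10)


class TestMonteCarloOracle:
    def test_half_probability_for_single_copy(self):
        mean, se = mc_oracle_log_likelihood(Pat(1, 1, 0, 0), MODEL, replicates=1000, seed=1)
        assert mean == pytest.approx(0.5, abs=3 * se + 1e-12)

    def test_matches_two_lineage_closed_form(self):
        mean, se = mc_oracle_log_likelihood(Pat(1, 1, 1, 1), MODEL, replicates=20000, seed=2)
        closed = 0.25 * (1 + math.exp(-4 * MODEL.tau) / (1 + 8 * MODEL.theta_root))
        assert abs(mean - closed) < 3 * se

    def test_exchangeable_at_zero_divergence(self):
        m = PairModel(tau=0.0, theta1=0.004, theta2=0.004, root_multiplier=1.0)
        within, se_w = mc_oracle_log_likelihood(Pat(2, 1, 0, 0), m, replicates=20000, seed=3)
        between, se_b = mc_oracle_log_likelihood(Pat(1, 1, 1, 0), m, replicates=20000, seed=4)
        between2, se_b2 = mc_oracle_log_likelihood(Pat(1, 0, 1, 1), m, replicates=20000, seed=5)
        assert abs(within - (between + between2)) < 3 * (se_w + se_b + se_b2)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            mc_oracle_log_likelihood(Pat(1, 1, 0, 0), MODEL, replicates=10)
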