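"""Model-choice summaries: Bayes-factor arithmetic, codivergence
probabilities, diversity, the loci-splitting workflow, and performance
reports."""

import numpy as np
import pandas as pd
import pytest

from codivergence.dpp import GammaPrior
from codivergence.mcmc import McmcSettings, Trace
from codivergence.summarize import (
    PerformanceReport,
    ReplicateResult,
    bayes_factor,
    expected_divergence_gap,
    most_similar_pair_prior,
    nucleotide_diversity,
    performance_report,
    summarize_traces,
    vet_split,
)
from tests.conftest import make_binary_comparison


class TestBayesFactor:
    def test_equal_probabilities_give_unity(self):
        assert bayes_factor(0.3, 0.3) == pytest.approx(1.0)

    def test_posterior_below_prior_supports_against(self):
        bf_for = bayes_factor(0.385, 0.5)
        assert bf_for == pytest.approx(0.626, abs=0.005)
        assert 1.0 / bf_for == pytest.approx(1.6, abs=0.01)

    def test_for_times_against_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            post, prior = rng.uniform(0.01, 0.99, 2)
            assert bayes_factor(post, prior) * bayes_factor(1 - post, 1 - prior) == (
                pytest.approx(1.0)
            )

    def test_boundary_probability_guidance(self):
        with pytest.raises(ValueError, match="pseudo-sample"):
            bayes_factor(1.0, 0.5)


class TestMostSimilarPairPrior:
    def test_independent_heavy_hyperprior_gives_half(self):
        assert most_similar_pair_prior(8, GammaPrior(1.1, 56.1)) == pytest.approx(0.5, abs=0.05)

    def test_extreme_fixed_alphas(self):
        assert most_similar_pair_prior(8, 1e9) == pytest.approx(0.0, abs=1e-6)
        assert most_similar_pair_prior(8, 1e-9) == pytest.approx(1.0, abs=1e-6)


def _trace_from_frame(df, labels, settings=None):
    settings = settings or McmcSettings(
        generations=len(df) - 1, sample_interval=1, burn_in=0, n_chains=1
    )
    return Trace(samples=df, chain_id=0, settings=settings, labels=labels)


def _synthetic_trace(k_values, events, times, labels):
    rows = []
    for i, k in enumerate(k_values):
        row = {"generation": i, "ln_likelihood": 0.0, "alpha": 1.0, "k": k}
        for c, lab in enumerate(labels):
            row[f"{lab}_event"] = events[i][c]
            row[f"{lab}_time"] = times[i][c]
            row[f"{lab}_theta1"] = 0.004
            row[f"{lab}_theta2"] = 0.004
            row[f"{lab}_root_mult"] = 1.0
        rows.append(row)
    return _trace_from_frame(pd.DataFrame(rows), labels)


class TestSummarizeTraces:
    def test_degenerate_posterior_reported_as_bound(self):
        labels = ["a", "b", "c"]
        trace = _synthetic_trace(
            [3] * 10, [[0, 1, 2]] * 10, [[0.1, 0.2, 0.3]] * 10, labels
        )
        summary = summarize_traces([trace], prior_num_events=np.array([0.2, 0.3, 0.5]))
        assert summary.posterior_num_events[2] == 1.0
        assert summary.bf_is_bound[2]
        assert np.isfinite(summary.bayes_factors).all()

    def test_pooled_probability_is_weighted_chain_average(self):
        labels = ["a", "b"]
        t1 = _synthetic_trace([1] * 8, [[0, 0]] * 8, [[0.1, 0.1]] * 8, labels)
        t2 = _synthetic_trace([2] * 4, [[0, 1]] * 4, [[0.1, 0.2]] * 4, labels)
        summary = summarize_traces([t1, t2])
        assert summary.posterior_num_events[0] == pytest.approx(8 / 12)
        assert summary.codivergence_matrix[0, 1] == pytest.approx(8 / 12)

    def test_codivergence_matrix_symmetric_unit_diagonal(self):
        labels = ["a", "b", "c"]
        rng = np.random.default_rng(5)
        events = [[0, int(rng.integers(2)), int(rng.integers(3))] for _ in range(50)]
        trace = _synthetic_trace(
            [max(e) + 1 for e in events], events, [[0.1, 0.2, 0.3]] * 50, labels
        )
        m = summarize_traces([trace]).codivergence_matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_time_summary_is_mean_and_equal_tailed_interval(self):
        labels = ["a"]
        times = np.linspace(0.0, 1.0, 1001)
        trace = _synthetic_trace(
            [1] * 1001, [[0]] * 1001, [[t] for t in times], labels
        )
        row = summarize_traces([trace]).time_summaries.iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["ci_low"] == pytest.approx(0.025, abs=0.002)
        assert row["ci_high"] == pytest.approx(0.975, abs=0.002)


class TestVetSplit:
    def test_paper_scale_split_halves(self):
        data = make_binary_comparison("big", [[0, 1, 0, 1]], 2, 2)
        # replicate the locus to the empirical count
        from codivergence.data_io import ComparisonData, Locus

        loci = [
            Locus(locus_id=f"l{i}", states=data.loci[0].states.copy())
            for i in range(21_426)
        ]
        big = ComparisonData.from_binary_loci("big", data.population_map, loci)
        a, b = vet_split(big, seed=0)
        assert (a.n_loci, b.n_loci) == (10_713, 10_713)

    def test_odd_count_differs_by_one(self):
        data = make_binary_comparison("odd", [[0, 1, 0, 1]], 2, 2)
        from codivergence.data_io import ComparisonData, Locus

        loci = [Locus(locus_id=f"l{i}", states=data.loci[0].states.copy()) for i in range(5)]
        five = ComparisonData.from_binary_loci("odd", data.population_map, loci)
        a, b = vet_split(five, seed=1)
        assert (a.n_loci, b.n_loci) == (3, 2)

    def test_same_seed_same_split(self, study_priors):
        from codivergence.simulate import SimulationTemplate, simulate_replicate

        rep = simulate_replicate(
            SimulationTemplate.uniform(1, 10, 5, (2, 2)), study_priors, seed=3
        )
        a1, b1 = vet_split(rep.data[0], seed=9)
        a2, b2 = vet_split(rep.data[0], seed=9)
        assert [l.locus_id for l in a1.loci] == [l.locus_id for l in a2.loci]

    def test_too_few_loci(self):
        data = make_binary_comparison("tiny", [[0, 1, 0, 1]], 2, 2)
        with pytest.raises(ValueError):
            vet_split(data, seed=0)


class TestNucleotideDiversity:
    def test_identical_sequences_have_zero_diversity(self):
        data = make_binary_comparison("zero", [[0, 0, 0, 0]] * 10, 2, 2)
        pi = nucleotide_diversity(data)
        assert pi["pi1"] == 0.0 and pi["pi2"] == 0.0 and pi["pi_between"] == 0.0

    def test_one_difference_in_ten_sites(self):
        # two copies in population 1 differing at 1 of 10 sites; a single
        # copy in population 2, so pi2 is omitted with a reason
        cols = [[0, 1, 0]] + [[0, 0, 0]] * 9
        data = make_binary_comparison("pair", cols, 2, 1)
        pi = nucleotide_diversity(data)
        assert pi["pi1"] == pytest.approx(0.1)
        assert pi["pi2"] is None
        assert "pi2" in pi["omitted"]

    def test_between_population_diversity(self):
        cols = [[0, 0, 1, 1]] * 2 + [[0, 0, 0, 0]] * 8
        data = make_binary_comparison("btw", cols, 2, 2)
        assert nucleotide_diversity(data)["pi_between"] == pytest.approx(0.2)


class TestPerformanceReport:
    def _result(self, true_t, est_t, lo, hi, true_k, pk):
        return ReplicateResult(
            true_times=np.asarray(true_t, float),
            true_k=true_k,
            post_mean_times=np.asarray(est_t, float),
            ci_low=np.asarray(lo, float),
            ci_high=np.asarray(hi, float),
            posterior_num_events=np.asarray(pk, float),
        )

    def test_perfect_estimates(self):
        res = [
            self._result([0.1, 0.2], [0.1, 0.2], [0.05, 0.15], [0.15, 0.25], 2, [0.1, 0.9])
        ]
        rep = performance_report(res)
        assert rep.rmse == 0.0
        assert rep.coverage == 1.0
        assert rep.confusion.loc[2, 2] == 1

    def test_hand_computed_rmse_and_coverage(self):
        res = [
            self._result([0.1], [0.2], [0.0], [0.15], 1, [1.0, 0.0]),
            self._result([0.3], [0.3], [0.2], [0.4], 1, [1.0, 0.0]),
            self._result([0.5], [0.1], [0.0], [0.2], 2, [0.2, 0.8]),
        ]
        rep = performance_report(res)
        assert rep.rmse == pytest.approx(np.sqrt((0.1**2 + 0.0 + 0.4**2) / 3))
        assert rep.coverage == pytest.approx(2 / 3)
        assert rep.confusion.loc[1, 1] == 2 and rep.confusion.loc[2, 2] == 1

    def test_mode_ties_break_toward_smaller_k(self):
        res = [self._result([0.1], [0.1], [0.0], [0.2], 2, [0.5, 0.5])]
        rep = performance_report(res)
        assert rep.confusion.loc[2, 1] == 1


class TestExpectedDivergenceGap:
    def test_interglacial_yardstick(self):
        gap = expected_divergence_gap(1.18e-9, 3000)
        assert gap == pytest.approx(3.54e-6, rel=1e-6)

    def test_zero_rate(self):
        assert expected_divergence_gap(0.0, 3000) == 0.0

    def test_posterior_gap_exceeds_yardstick(self):
        assert 9.66e-6 / 3.5e-6 >= 2.7
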