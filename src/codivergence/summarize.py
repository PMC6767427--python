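"""Posterior summaries and model-choice outputs.

Turns MCMC traces into the inferential quantities of a co-divergence
analysis: posterior probabilities of the number of divergence events,
Bayes factors comparing each event count against all others, pairwise
codivergence probabilities (with the most-similar-pair prior correction for
pairs singled out a posteriori), divergence-time summaries, nucleotide
diversity, the loci-splitting vetting workflow, and simulation-performance
reports (RMSE, credible-interval coverage, confusion of true versus
estimated event counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import ComparisonData, InputError
from .dpp import GammaPrior, prob_num_events_given_alpha, prob_num_events_marginal
from .mcmc import PSRF_HIGHLIGHT, Trace

__all__ = [
    "ModelChoiceSummary",
    "PerformanceReport",
    "ReplicateResult",
    "bayes_factor",
    "most_similar_pair_prior",
    "summarize_traces",
    "vet_split",
    "nucleotide_diversity",
    "performance_report",
    "expected_divergence_gap",
]


def bayes_factor(posterior_prob: float, prior_prob: float) -> float:
    """Posterior odds over prior odds; the Bayes factor *against* is the
    reciprocal.  Degenerate probabilities must be regularized by the caller
    (e.g. a one-pseudo-sample bound) before forming odds."""
    for name, p in (("posterior", posterior_prob), ("prior", prior_prob)):
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"{name} probability {p} is on the boundary; add a pseudo-sample "
                "correction or report a bound instead"
            )
    return (posterior_prob / (1.0 - posterior_prob)) / (prior_prob / (1.0 - prior_prob))


def most_similar_pair_prior(n: int, prior: GammaPrior | float) -> float:
    """Prior probability that the two pairs with the most similar divergence
    times codiverge: 1 minus the prior probability that all ``n`` pairs
    diverge independently.  The appropriate prior when a pair of comparisons
    is singled out from the posterior rather than a priori."""
    if n < 2:
        raise ValueError("need at least two comparisons")
    if isinstance(prior, (int, float)):
        return 1.0 - prob_num_events_given_alpha(n, n, float(prior))
    return 1.0 - prob_num_events_marginal(n, n, prior)


@dataclass
class ModelChoiceSummary:
    labels: list[str]
    posterior_num_events: np.ndarray  # P(k), k = 1..n
    prior_num_events: np.ndarray | None
    bayes_factors: np.ndarray | None  # per k, vs all other k
    bf_is_bound: np.ndarray | None  # True where a pseudo-sample bound was used
    codivergence_matrix: np.ndarray  # pairwise P(same event)
    time_summaries: pd.DataFrame  # per comparison: mean, ci_low, ci_high
    n_samples: int

    def num_events_table(self) -> pd.DataFrame:
        n = len(self.posterior_num_events)
        tab = pd.DataFrame({"k": np.arange(1, n + 1), "posterior": self.posterior_num_events})
        if self.prior_num_events is not None:
            tab["prior"] = self.prior_num_events
            tab["bayes_factor"] = self.bayes_factors
            tab["bf_is_bound"] = self.bf_is_bound
        return tab


def _pseudo_bound(count: float, total: int) -> tuple[float, bool]:
    # one-pseudo-sample correction for probabilities estimated as 0 or 1
    if count == 0:
        return 1.0 / (total + 1.0), True
    if count == total:
        return total / (total + 1.0), True
    return count / total, False


def summarize_traces(
    traces: list[Trace],
    prior_num_events: np.ndarray | None = None,
    burn_in: int | None = None,
    ci_mass: float = 0.95,
) -> ModelChoiceSummary:
    """Pool retained samples across chains and compute the model-choice
    summary.  Bayes factors compare each number of events against all other
    numbers of events; degenerate posterior probabilities are replaced by
    one-pseudo-sample bounds and flagged."""
    if not traces:
        raise ValueError("no traces to summarize")
    labels = traces[0].labels
    n = len(labels)
    pooled = pd.concat([t.retained(burn_in) for t in traces], ignore_index=True)
    if pooled.empty:
        raise ValueError("no retained samples after burn-in")
    total = len(pooled)

    k_counts = np.bincount(pooled["k"].to_numpy(dtype=int), minlength=n + 1)[1 : n + 1]
    post_pk = k_counts / total

    bfs = bound_flags = None
    if prior_num_events is not None:
        prior_pk = np.asarray(prior_num_events, dtype=float)
        bfs = np.empty(n)
        bound_flags = np.zeros(n, dtype=bool)
        for i in range(n):
            p, flagged = _pseudo_bound(int(k_counts[i]), total)
            bound_flags[i] = flagged
            bfs[i] = bayes_factor(p, float(np.clip(prior_pk[i], 1e-300, 1 - 1e-12)))

    events = pooled[[f"{lab}_event" for lab in labels]].to_numpy(dtype=int)
    codiv = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            codiv[i, j] = codiv[j, i] = float(np.mean(events[:, i] == events[:, j]))

    lo, hi = (1.0 - ci_mass) / 2.0, 1.0 - (1.0 - ci_mass) / 2.0
    rows = []
    for lab in labels:
        t = pooled[f"{lab}_time"].to_numpy()
        rows.append(
            {
                "comparison": lab,
                "mean": float(t.mean()),
                "ci_low": float(np.quantile(t, lo)),
                "ci_high": float(np.quantile(t, hi)),
            }
        )
    return ModelChoiceSummary(
        labels=labels,
        posterior_num_events=post_pk,
        prior_num_events=None if prior_num_events is None else np.asarray(prior_num_events),
        bayes_factors=bfs,
        bf_is_bound=bound_flags,
        codivergence_matrix=codiv,
        time_summaries=pd.DataFrame(rows),
        n_samples=total,
    )


def vet_split(data: ComparisonData, seed: int) -> tuple[ComparisonData, ComparisonData]:
    """Randomly split a comparison's loci into two halves treated as separate
    comparisons downstream; a genuine method should infer that the two
    halves codiverged."""
    if data.n_loci < 2:
        raise InputError("need at least two loci to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(data.n_loci)
    half = (data.n_loci + 1) // 2
    halves = []
    for tag, idx in (("_splitA", order[:half]), ("_splitB", order[half:])):
        pm = data.population_map
        new_map = replace(pm, label=pm.label + tag)
        loci = [data.loci[i] for i in sorted(idx)]
        halves.append(ComparisonData.from_binary_loci(pm.label + tag, new_map, loci))
    return halves[0], halves[1]


def nucleotide_diversity(data: ComparisonData) -> dict:
    """Mean per-site pairwise difference within each population (pi1, pi2)
    and between populations (pi_between), from the compressed patterns.
    Values needing more sampled copies than available are None with a
    reason recorded under 'omitted'."""
    n1, r1, n2, r2, w = data.pattern_arrays()
    out: dict = {"comparison": data.label, "omitted": {}}

    for key, nn, rr in (("pi1", n1, r1), ("pi2", n2, r2)):
        mask = nn >= 2
        if not mask.any():
            out[key] = None
            out["omitted"][key] = "fewer than two sampled copies at every site"
            continue
        het = 2.0 * rr[mask] * (nn[mask] - rr[mask]) / (nn[mask] * (nn[mask] - 1.0))
        out[key] = float(np.dot(w[mask], het) / w[mask].sum())

    mask = (n1 >= 1) & (n2 >= 1)
    if not mask.any():
        out["pi_between"] = None
        out["omitted"]["pi_between"] = "no site with copies in both populations"
    else:
        diff = (r1[mask] * (n2[mask] - r2[mask]) + r2[mask] * (n1[mask] - r1[mask])) / (
            n1[mask] * n2[mask]
        )
        out["pi_between"] = float(np.dot(w[mask], diff) / w[mask].sum())
    return out


@dataclass
class ReplicateResult:
    """Truth and posterior summaries for one simulated replicate."""

    true_times: np.ndarray
    true_k: int
    post_mean_times: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    posterior_num_events: np.ndarray
    max_psrf: float = float("nan")


@dataclass
class PerformanceReport:
    rmse: float
    coverage: float
    confusion: pd.DataFrame  # rows true k, columns estimated k
    n_psrf_flagged: int
    n_replicates: int
    n_estimates: int


def performance_report(results: list[ReplicateResult]) -> PerformanceReport:
    """RMSE and credible-interval coverage of divergence-time estimates and
    the confusion of true versus estimated numbers of events.  The estimated
    number of events is the posterior mode (ties toward smaller k)."""
    errs, covered = [], []
    n = len(results[0].posterior_num_events)
    confusion = np.zeros((n, n), dtype=int)
    flagged = 0
    for res in results:
        errs.append(res.post_mean_times - res.true_times)
        covered.append((res.true_times >= res.ci_low) & (res.true_times <= res.ci_high))
        est_k = int(np.argmax(res.posterior_num_events)) + 1  # argmax takes smallest tie
        confusion[res.true_k - 1, est_k - 1] += 1
        if not math.isnan(res.max_psrf) and res.max_psrf > PSRF_HIGHLIGHT:
            flagged += 1
    errs = np.concatenate(errs)
    covered = np.concatenate(covered)
    frame = pd.DataFrame(
        confusion,
        index=pd.Index(range(1, n + 1), name="true_k"),
        columns=pd.Index(range(1, n + 1), name="estimated_k"),
    )
    return PerformanceReport(
        rmse=float(np.sqrt(np.mean(errs**2))),
        coverage=float(covered.mean()),
        confusion=frame,
        n_psrf_flagged=flagged,
        n_replicates=len(results),
        n_estimates=len(errs),
    )


def expected_divergence_gap(rate_per_site_per_year: float, years: float) -> float:
    """Expected divergence-time difference (substitutions/site) accumulated
    over a window of ``years`` at the given mutation rate; the yardstick for
    whether two divergences within one interglacial are distinguishable."""
    if rate_per_site_per_year < 0 or years < 0:
        raise ValueError("rate and years must be non-negative")
    return rate_per_site_per_year * years
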