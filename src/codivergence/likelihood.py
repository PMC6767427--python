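"""Analytic likelihood of biallelic site patterns under a two-population
divergence model.

Each comparison is a two-tipped "species" tree: two descendant populations
with constant mutation-scaled sizes ``theta1`` and ``theta2`` that split from
an ancestral population ``tau`` time units ago (time in expected
substitutions per site; the mutation rate is fixed at 1, so theta = Ne*mu).
The ancestral size is ``root_multiplier`` times the mean of the descendant
sizes.  There is no migration after the divergence.

Characters are two-state with the symmetric (Jukes-Cantor-like) substitution
process: each lineage's state flips at rate 1, stationary frequencies
(1/2, 1/2).  The likelihood of a site pattern integrates analytically over
all gene trees and mutational histories.  The computation used here is a
killed ancestral process, exactly equivalent to partial-likelihood pruning:
backward in time the sampled lineages form a Markov chain on states
``(m, j)`` (m surviving lineages, j of them carrying allele 1) where

* each lineage flips allele at rate 1 (the symmetric mutation process is
  reversible, so its time reversal is the same flip process),
* each pair of same-allele lineages coalesces at rate ``1/(2*theta)``,
* a coalescence of two lineages carrying different alleles is impossible in
  a valid history and kills the path.

The pattern probability is the binomial multiplicity of the pattern times
one half (the stationary weight of the final single lineage) times the
probability the process survives to a single lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import gammaln

__all__ = [
    "PairModel",
    "BranchPartial",
    "COALESCENT_PAIR_RATE",
    "transition_prob_same",
    "propagate_branch",
    "pattern_log_likelihood",
    "comparison_log_likelihood",
    "mc_oracle_log_likelihood",
    "PairLikelihood",
]


def COALESCENT_PAIR_RATE(theta: float) -> float:
    """Rate at which one pair of gene copies coalesces, given theta = Ne*mu.

    The diploid convention 1/(2*theta) on the substitutions timescale is
    isolated here so an alternative scaling is a one-line change; tau and
    theta only enter the model jointly through this rate and the flip rate 1.
    """
    return 1.0 / (2.0 * theta)


@dataclass(frozen=True)
class PairModel:
    """Parameters of one comparison's two-population divergence model."""

    tau: float
    theta1: float
    theta2: float
    root_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.theta1 <= 0 or self.theta2 <= 0:
            raise ValueError("theta1 and theta2 must be positive")
        if self.root_multiplier <= 0:
            raise ValueError("root multiplier must be positive")

    @property
    def theta_root(self) -> float:
        return self.root_multiplier * 0.5 * (self.theta1 + self.theta2)


def transition_prob_same(t: float) -> float:
    """P(state unchanged after time t) = (1 + exp(-2t)) / 2."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return 0.5 * (1.0 + math.exp(-2.0 * t))


# ---------------------------------------------------------------------------
# (m, j) state space


def _num_states(n_max: int) -> int:
    # states (m, j), 0 <= j <= m, 1 <= m <= n_max, plus the empty state (0, 0)
    return (n_max + 1) * (n_max + 2) // 2


def state_index(m: int, j: int) -> int:
    """Flat index of state (m lineages, j of them carrying allele 1)."""
    if not (0 <= j <= m):
        raise ValueError(f"invalid state ({m}, {j})")
    return m * (m + 1) // 2 + j


def build_generator(n_max: int, theta: float) -> np.ndarray:
    """Sub-generator of the killed coalescent-mutation process on (m, j).

    Probability mass leaks through coalescences of opposite-allele pairs,
    so rows sum to <= 0.  The empty state (0, 0) is inert.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    lam = COALESCENT_PAIR_RATE(theta)
    size = _num_states(n_max)
    q = np.zeros((size, size))
    for m in range(1, n_max + 1):
        for j in range(m + 1):
            i = state_index(m, j)
            if m - j > 0:  # a 0-lineage mutates to 1
                q[i, state_index(m, j + 1)] += m - j
            if j > 0:  # a 1-lineage mutates to 0
                q[i, state_index(m, j - 1)] += j
            if m > 1:
                if j >= 2:
                    q[i, state_index(m - 1, j - 1)] += lam * j * (j - 1) / 2.0
                if m - j >= 2:
                    q[i, state_index(m - 1, j)] += lam * (m - j) * (m - j - 1) / 2.0
            q[i, i] = -(m + lam * m * (m - 1) / 2.0)
    return q


def survival_to_root(n_max: int, theta: float) -> np.ndarray:
    """P(coalesce to one lineage without ever merging opposite alleles),
    for every starting state (m, j), on a branch of infinite length.

    Solved exactly level-by-level: for each m the flip coupling in j is
    tridiagonal, with the already-known m-1 level as inhomogeneity.
    """
    lam = COALESCENT_PAIR_RATE(theta)
    size = _num_states(n_max)
    h = np.zeros(size)
    h[state_index(0, 0)] = 1.0  # vacuous
    for j in (0, 1) if n_max >= 1 else ():
        h[state_index(1, j)] = 1.0
    for m in range(2, n_max + 1):
        a = np.zeros((m + 1, m + 1))
        b = np.zeros(m + 1)
        for j in range(m + 1):
            out_rate = m + lam * m * (m - 1) / 2.0
            a[j, j] = out_rate
            if m - j > 0:
                a[j, j + 1] -= m - j
            if j > 0:
                a[j, j - 1] -= j
            if j >= 2:
                b[j] += lam * j * (j - 1) / 2.0 * h[state_index(m - 1, j - 1)]
            if m - j >= 2:
                b[j] += lam * (m - j) * (m - j - 1) / 2.0 * h[state_index(m - 1, j)]
        sol = np.linalg.solve(a, b)
        for j in range(m + 1):
            h[state_index(m, j)] = sol[j]
    return h


class BranchPartial:
    """Probability mass over (m, j) ancestral-lineage states on one branch."""

    __slots__ = ("n_max", "mass")

    def __init__(self, n_max: int, mass: np.ndarray | None = None):
        self.n_max = n_max
        self.mass = np.zeros(_num_states(n_max)) if mass is None else np.asarray(mass, float)
        if self.mass.shape != (_num_states(n_max),):
            raise ValueError("mass vector does not match state-space size")
        if not np.all(np.isfinite(self.mass)) or np.any(self.mass < -1e-12):
            raise ValueError("partial mass must be finite and non-negative")

    @classmethod
    def from_tip_counts(cls, n: int, r: int, n_max: int | None = None) -> "BranchPartial":
        n_max = n if n_max is None else n_max
        p = cls(n_max)
        p.mass[state_index(n, r)] = 1.0
        return p

    def total(self) -> float:
        return float(self.mass.sum())


def propagate_branch(partial: BranchPartial, length: float, theta: float) -> BranchPartial:
    """Evolve a branch partial along a branch of the given length.

    ``length = inf`` (the root branch) returns the fully coalesced
    contribution: surviving mass on the single-lineage states, split evenly
    between alleles per the (1/2, 1/2) stationary distribution.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if length < 0:
        raise ValueError("branch length must be non-negative")
    if math.isinf(length):
        h = survival_to_root(partial.n_max, theta)
        surviving = float(partial.mass @ h) - partial.mass[state_index(0, 0)]
        out = BranchPartial(partial.n_max)
        out.mass[state_index(0, 0)] = partial.mass[state_index(0, 0)]
        out.mass[state_index(1, 0)] = 0.5 * surviving
        out.mass[state_index(1, 1)] = 0.5 * surviving
        return out
    q = build_generator(partial.n_max, theta)
    return BranchPartial(partial.n_max, partial.mass @ expm(q * length))


def _log_binom(n: int, r: int) -> float:
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def pattern_log_likelihood(pattern, model: PairModel) -> float:
    """Log-probability of one site pattern under the pair model.

    ``pattern`` needs attributes n1, r1, n2, r2 (any object or namedtuple).
    Not conditioned on the site being variable.  Includes the binomial
    multiplicity of the allele-count pattern, so probabilities over all
    (r1, r2) for fixed (n1, n2) sum to one.
    """
    n1, r1, n2, r2 = pattern.n1, pattern.r1, pattern.n2, pattern.r2
    if n1 + n2 == 0:
        raise ValueError("pattern has no sampled gene copies")
    like = PairLikelihood(n1_max=n1, n2_max=n2)
    return float(
        like.pattern_log_likelihoods(
            np.array([n1]), np.array([r1]), np.array([n2]), np.array([r2]), model
        )[0]
    )


def comparison_log_likelihood(data, model: PairModel) -> float:
    """Sum of weight * pattern log-likelihood over a comparison's compressed
    pattern table (``data`` is a ComparisonData or anything exposing
    ``pattern_arrays() -> (n1, r1, n2, r2, weight)``)."""
    n1, r1, n2, r2, w = data.pattern_arrays()
    if len(w) == 0:
        raise ValueError("empty pattern table")
    like = PairLikelihood(n1_max=int(n1.max()), n2_max=int(n2.max()))
    lls = like.pattern_log_likelihoods(n1, r1, n2, r2, model)
    return float(np.dot(w, lls))


class PairLikelihood:
    """Cached likelihood evaluator for one comparison.

    Caches eigendecompositions of the per-population generators (keyed by
    theta) and the root-merge matrix (keyed by theta_root), so repeated
    evaluations across MCMC proposals that share parameters are cheap.
    Degenerate (defective) eigensystems fall back to scipy's expm.
    """

    def __init__(self, n1_max: int, n2_max: int, cache_size: int = 64):
        self.n1_max = int(n1_max)
        self.n2_max = int(n2_max)
        self._eig_cache: dict[tuple[int, float], tuple] = {}
        self._root_cache: dict[float, np.ndarray] = {}
        self._cache_size = cache_size
        nm = self.n1_max + self.n2_max
        # merged-state index lookup: (m1, j1) x (m2, j2) -> flat (m1+m2, j1+j2)
        s1, s2 = _num_states(self.n1_max), _num_states(self.n2_max)
        self._merge_idx = np.zeros((s1, s2), dtype=np.intp)
        for m1 in range(self.n1_max + 1):
            for j1 in range(m1 + 1):
                for m2 in range(self.n2_max + 1):
                    for j2 in range(m2 + 1):
                        self._merge_idx[state_index(m1, j1), state_index(m2, j2)] = state_index(
                            m1 + m2, j1 + j2
                        )
        self._merged_size = _num_states(nm)

    def _eig(self, n_max: int, theta: float):
        key = (n_max, theta)
        hit = self._eig_cache.get(key)
        if hit is None:
            q = build_generator(n_max, theta)
            w, v = np.linalg.eig(q)
            try:
                vinv = np.linalg.inv(v)
                err = np.abs(v @ np.diag(w) @ vinv - q).max()
                hit = (w, v, vinv) if err < 1e-9 else (None, q, None)
            except np.linalg.LinAlgError:  # pragma: no cover - defective Q
                hit = (None, q, None)
            if len(self._eig_cache) > self._cache_size:
                self._eig_cache.clear()
            self._eig_cache[key] = hit
        return hit

    def _transition(self, n_max: int, theta: float, t: float) -> np.ndarray:
        w, v, vinv = self._eig(n_max, theta)
        if w is None:  # fallback: v holds Q
            return expm(v * t)
        e = (v * np.exp(w * t)) @ vinv
        return np.maximum(e.real, 0.0)

    def _root_merge(self, theta_root: float) -> np.ndarray:
        b = self._root_cache.get(theta_root)
        if b is None:
            h = survival_to_root(self.n1_max + self.n2_max, theta_root)
            a = 0.5 * h
            a[state_index(0, 0)] = 0.0  # no data -> handled upstream
            b = a[self._merge_idx]
            if len(self._root_cache) > self._cache_size:
                self._root_cache.clear()
            self._root_cache[theta_root] = b
        return b

    def pattern_log_likelihoods(
        self,
        n1: np.ndarray,
        r1: np.ndarray,
        n2: np.ndarray,
        r2: np.ndarray,
        model: PairModel,
    ) -> np.ndarray:
        """Vector of log-probabilities for count patterns (n1, r1, n2, r2)."""
        if np.any(n1 + n2 == 0):
            raise ValueError("pattern with zero sampled copies in both populations")
        e1 = self._transition(self.n1_max, model.theta1, model.tau)
        e2 = self._transition(self.n2_max, model.theta2, model.tau)
        b = self._root_merge(model.theta_root)
        idx1 = n1 * (n1 + 1) // 2 + r1
        idx2 = n2 * (n2 + 1) // 2 + r2
        v1 = e1[idx1]  # rows: measures after the descendant branches
        v2 = e2[idx2]
        probs = np.einsum("pi,ij,pj->p", v1, b, v2)
        logmult = _log_binom(n1, r1) + _log_binom(n2, r2)
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(probs, 0.0)) + logmult


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


def mc_oracle_log_likelihood(
    pattern,
    model: PairModel,
    replicates: int = 5000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Independent check of the analytic likelihood: simulate structured-
    coalescent gene trees with msprime and average Felsenstein-pruning
    probabilities of the pattern over trees.

    Returns (mean probability, Monte-Carlo standard error), on the same
    count-pattern scale as :func:`pattern_log_likelihood` (multiplicity
    included).
    """
    import msprime

    if replicates < 1000:
        raise ValueError("use at least 1000 replicates")
    n1, r1, n2, r2 = pattern.n1, pattern.r1, pattern.n2, pattern.r2
    if n1 + n2 == 0:
        raise ValueError("pattern has no sampled gene copies")
    # ploidy 1: pair coalescence rate 1/N per generation; we need 1/(2 theta)
    demography = msprime.Demography()
    demography.add_population(name="p1", initial_size=1.0 / COALESCENT_PAIR_RATE(model.theta1))
    demography.add_population(name="p2", initial_size=1.0 / COALESCENT_PAIR_RATE(model.theta2))
    demography.add_population(name="anc", initial_size=1.0 / COALESCENT_PAIR_RATE(model.theta_root))
    # msprime cannot sample from a population that is already merged at t=0
    demography.add_population_split(
        time=max(model.tau, 1e-12), derived=["p1", "p2"], ancestral="anc"
    )
    reps = msprime.sim_ancestry(
        samples={"p1": n1, "p2": n2},
        demography=demography,
        ploidy=1,
        num_replicates=replicates,
        random_seed=None if seed is None else max(1, seed % (2**31)),
    )
    tip_states = np.concatenate([np.r_[np.ones(r1), np.zeros(n1 - r1)],
                                 np.r_[np.ones(r2), np.zeros(n2 - r2)]]).astype(int)
    vals = np.empty(replicates)
    for i, ts in enumerate(reps):
        vals[i] = _pruning_probability(ts.first(), tip_states)
    mult = math.exp(_log_binom(n1, r1) + _log_binom(n2, r2))
    mean = float(vals.mean()) * mult
    se = float(vals.std(ddof=1) / math.sqrt(replicates)) * mult
    return mean, se


def _pruning_probability(tree, tip_states: np.ndarray) -> float:
    """Felsenstein pruning on one gene tree under the rate-1 flip process."""
    partial: dict[int, np.ndarray] = {}
    for u in tree.nodes(order="postorder"):
        children = tree.children(u)
        if not children:
            s = tip_states[u]
            partial[u] = np.array([1.0 - s, float(s)])
            continue
        acc = np.ones(2)
        for c in children:
            t = tree.branch_length(c)
            p_same = 0.5 * (1.0 + math.exp(-2.0 * t))
            m = np.array([[p_same, 1.0 - p_same], [1.0 - p_same, p_same]])
            acc = acc * (m @ partial[c])
        partial[u] = acc
    root = tree.root
    return float(0.5 * partial[root].sum())
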