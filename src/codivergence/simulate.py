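"""Template-matched coalescent simulation of biallelic datasets.

A :class:`SimulationTemplate` is the exact sampling skeleton of a set of
comparisons: the number of loci per comparison, the number of sites per
locus, and the number of gene copies sampled per population at every site
(the empirical missing-data pattern).  Simulated replicates draw the
divergence model and every parameter from the priors, then generate data
that reproduce the template dimensions exactly.

All sites of a locus evolve along a single structured-coalescent gene tree
(loci are unlinked, no intralocus recombination).  The gene tree for a locus
is simulated for the union of copies observed anywhere in the locus, and
per-site missingness is realized by masking the absent copies.  Binary
characters evolve along the tree under the symmetric rate-1 flip process
with a stationary root state.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import MISSING, ComparisonData, InputError, Locus, PopulationMap
from .dpp import Partition, sample_partition
from .likelihood import COALESCENT_PAIR_RATE
from .priors import PriorSet

__all__ = [
    "SimulationTemplate",
    "SimulatedReplicate",
    "extract_template",
    "simulate_replicate",
    "snp_filter",
    "replicate_seed",
]


@dataclass
class SimulationTemplate:
    """Per-comparison loci x sites x per-site gene-copy counts."""

    labels: list[str]
    # per comparison: list of (n_sites, 2) int arrays of per-site copy counts
    copy_counts: list[list[np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.copy_counts):
            raise InputError("labels and copy-count blocks differ in length")
        for loci in self.copy_counts:
            if not loci:
                raise InputError("every comparison needs at least one locus")
            for counts in loci:
                if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 1:
                    raise InputError("per-locus counts must be (n_sites, 2)")
                if np.any(counts < 0) or not np.any(counts.sum(axis=1) > 0):
                    raise InputError("a locus must sample at least one gene copy somewhere")

    def n_loci(self, comparison: int) -> int:
        return len(self.copy_counts[comparison])

    def sample_sizes(self, comparison: int) -> tuple[int, int]:
        """Union gene-copy count per population across the comparison."""
        m = np.array([c.max(axis=0) for c in self.copy_counts[comparison]]).max(axis=0)
        return int(m[0]), int(m[1])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "copy_counts": [[c.tolist() for c in loci] for loci in self.copy_counts],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTemplate":
        payload = json.loads(Path(path).read_text())
        return cls(
            labels=list(payload["labels"]),
            copy_counts=[
                [np.asarray(c, dtype=int) for c in loci] for loci in payload["copy_counts"]
            ],
        )

    @classmethod
    def uniform(
        cls, n_comparisons: int, n_loci: int, n_sites: int, copies: tuple[int, int]
    ) -> "SimulationTemplate":
        """Fully sampled template with identical dimensions everywhere."""
        block = np.tile(np.array(copies, dtype=int), (n_sites, 1))
        return cls(
            labels=[f"comparison_{i}" for i in range(n_comparisons)],
            copy_counts=[[block.copy() for _ in range(n_loci)] for _ in range(n_comparisons)],
        )


@dataclass
class SimulatedReplicate:
    """Truth (recorded before any analysis) plus the generated data."""

    partition: Partition
    event_times: np.ndarray  # per event
    thetas: np.ndarray  # (n_comparisons, 2)
    root_multipliers: np.ndarray
    alpha: float
    data: list[ComparisonData]
    seed: int

    @property
    def comparison_times(self) -> np.ndarray:
        return self.event_times[np.asarray(self.partition.assignment)]

    @property
    def k(self) -> int:
        return self.partition.k


def extract_template(datasets: list[ComparisonData]) -> SimulationTemplate:
    labels, blocks = [], []
    for data in datasets:
        pop_index = data.population_index
        loci_counts = []
        for locus in data.loci:
            present = locus.states != MISSING
            counts = np.stack(
                [present[pop_index == 0].sum(axis=0), present[pop_index == 1].sum(axis=0)],
                axis=1,
            ).astype(int)
            loci_counts.append(counts)
        labels.append(data.label)
        blocks.append(loci_counts)
    return SimulationTemplate(labels=labels, copy_counts=blocks)


def replicate_seed(master_seed: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed below 2^31."""
    return int(np.random.SeedSequence([master_seed, replicate_index]).generate_state(1)[0] % 2**31)


def simulate_replicate(
    template: SimulationTemplate,
    priors: PriorSet,
    seed: int,
    snp_only: bool = False,
) -> SimulatedReplicate:
    """Draw a divergence model from the priors and simulate a dataset that
    matches the template exactly; ``snp_only`` retains at most one variable
    site per locus."""
    rng = np.random.default_rng(seed)
    n_comp = len(template.labels)
    fixed = priors.fixed_alpha()
    alpha = fixed if fixed is not None else float(priors.concentration.rvs(1, rng)[0])
    partition = sample_partition(n_comp, alpha, rng)
    event_times = priors.tau.rvs(partition.k, rng)
    thetas = priors.theta.rvs(2 * n_comp, rng).reshape(n_comp, 2)
    mults = priors.root_multiplier.rvs(n_comp, rng)

    datasets = []
    for c in range(n_comp):
        tau = float(event_times[partition.assignment[c]])
        t1, t2 = float(thetas[c, 0]), float(thetas[c, 1])
        t_root = float(mults[c]) * 0.5 * (t1 + t2)
        n1, n2 = template.sample_sizes(c)
        pop_map = _synthetic_pop_map(template.labels[c], n1, n2)
        loci = _simulate_loci(
            template.copy_counts[c], tau, t1, t2, t_root, n1, n2, rng
        )
        data = ComparisonData.from_binary_loci(template.labels[c], pop_map, loci)
        if snp_only:
            data = snp_filter(data)
        datasets.append(data)
    return SimulatedReplicate(
        partition=partition,
        event_times=np.asarray(event_times, dtype=float),
        thetas=thetas,
        root_multipliers=mults,
        alpha=alpha,
        data=datasets,
        seed=seed,
    )


def _synthetic_pop_map(label: str, n1: int, n2: int) -> PopulationMap:
    assignment = {f"{label}_a{i:03d}": "pop1" for i in range(n1)}
    assignment.update({f"{label}_b{i:03d}": "pop2" for i in range(n2)})
    return PopulationMap(label=label, population_labels=("pop1", "pop2"), assignment=assignment)


def _simulate_loci(copy_counts, tau, theta1, theta2, theta_root, n1, n2, rng):
    import msprime

    demography = msprime.Demography()
    demography.add_population(name="p1", initial_size=1.0 / COALESCENT_PAIR_RATE(theta1))
    demography.add_population(name="p2", initial_size=1.0 / COALESCENT_PAIR_RATE(theta2))
    demography.add_population(name="anc", initial_size=1.0 / COALESCENT_PAIR_RATE(theta_root))
    demography.add_population_split(
        time=max(tau, 1e-12), derived=["p1", "p2"], ancestral="anc"
    )
    tree_reps = msprime.sim_ancestry(
        samples={"p1": n1, "p2": n2},
        demography=demography,
        ploidy=1,
        num_replicates=len(copy_counts),
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    loci = []
    for i, ts in enumerate(tree_reps):
        counts = copy_counts[i]
        n_sites = counts.shape[0]
        states = _evolve_binary(ts.first(), n1 + n2, n_sites, rng)
        # mask per-site absent copies (trailing copies within each population)
        for pop, offset, total in ((0, 0, n1), (1, n1, n2)):
            col = counts[:, pop]
            if np.any(col < total):
                mask = np.arange(total)[:, None] >= col[None, :]
                states[offset : offset + total][mask] = MISSING
        loci.append(Locus(locus_id=f"locus_{i:05d}", states=states))
    return loci


def _evolve_binary(tree, n_tips: int, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Evolve n_sites independent binary characters along one gene tree."""
    node_states: dict[int, np.ndarray] = {}
    root = tree.root
    node_states[root] = rng.integers(0, 2, size=n_sites, dtype=np.int8)
    for u in tree.nodes(order="preorder"):
        if u == root:
            continue
        t = tree.branch_length(u)
        p_flip = 0.5 * (1.0 - math.exp(-2.0 * t))
        flips = rng.random(n_sites) < p_flip
        node_states[u] = np.where(flips, 1 - node_states[tree.parent(u)], node_states[tree.parent(u)]).astype(np.int8)
    return np.stack([node_states[tip] for tip in range(n_tips)])


def snp_filter(data: ComparisonData) -> ComparisonData:
    """Keep at most one variable site per locus (the first, in locus order);
    invariant loci contribute nothing."""
    kept: list[Locus] = []
    for locus in data.loci:
        for site in range(locus.n_sites):
            col = locus.states[:, site]
            observed = col[col != MISSING]
            if observed.size and observed.min() != observed.max():
                kept.append(Locus(locus_id=locus.locus_id, states=col[:, None]))
                break
    if not kept:
        warnings.warn(f"comparison {data.label!r}: no variable sites; SNP filter left no data")
        return ComparisonData(label=data.label, population_map=data.population_map, loci=[])
    return ComparisonData.from_binary_loci(data.label, data.population_map, kept)
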