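"""Reading, recoding and compressing multilocus alignments.

Input is either a directory of per-locus FASTA files or a NEXUS file with
charset-style locus boundaries, plus a population map assigning each
sequence (gene copy) to one of the two populations of a comparison.
Nucleotide columns are recoded to two states -- state 0 is the first
non-missing nucleotide scanning the column top-to-bottom in input order,
state 1 any other nucleotide.  Columns with three or more nucleotides
("polyallelic") are either removed or recoded to binary, mirroring the two
strategies compared in the source analyses.  Missing bases (gap, N, ?)
reduce the per-site sampled gene-copy count.

Retained sites are compressed to weighted site patterns
(n1, r1, n2, r2, weight) which are the sufficient data for the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MappingError",
    "InputError",
    "PopulationMap",
    "Locus",
    "SitePattern",
    "RemovalSignal",
    "ComparisonData",
    "recode_biallelic",
    "read_comparison",
    "summarize_dataset",
    "write_comparison_fasta",
    "MISSING_SYMBOLS",
]

MISSING_SYMBOLS = frozenset("-?.Nn")
MISSING = -1  # internal missing-state code


class MappingError(ValueError):
    """A sequence identifier could not be reconciled with the population map."""


class InputError(ValueError):
    """An alignment source was empty or malformed."""


@dataclass(frozen=True)
class PopulationMap:
    label: str
    population_labels: tuple[str, str]
    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.population_labels)) != 2:
            raise MappingError("a comparison needs exactly two distinct population labels")
        pops = set(self.assignment.values())
        if not pops.issubset(set(self.population_labels)):
            raise MappingError(f"unknown population label(s): {pops - set(self.population_labels)}")
        for p in self.population_labels:
            if p not in pops:
                raise MappingError(f"population {p!r} has no sequences")

    def population_index(self, seq_id: str) -> int:
        try:
            return self.population_labels.index(self.assignment[seq_id])
        except KeyError:
            raise MappingError(f"sequence id {seq_id!r} is not in the population map") from None

    @property
    def sequence_ids(self) -> list[str]:
        # stable order: population 0 sequences first, then population 1
        return sorted(self.assignment, key=lambda s: (self.population_index(s), s))


@dataclass
class Locus:
    """One locus: recoded binary states per sequence (rows follow the
    comparison's sequence order), -1 marking missing bases."""

    locus_id: str
    states: np.ndarray  # (n_sequences, n_sites) int8, values {-1, 0, 1}

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[1] < 1:
            raise InputError(f"locus {self.locus_id!r} must have at least one site")

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class SitePattern:
    n1: int
    r1: int
    n2: int
    r2: int
    weight: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.r1 <= self.n1 and 0 <= self.r2 <= self.n2):
            raise InputError("allele counts exceed sampled copies")
        if self.n1 + self.n2 < 1:
            raise InputError("pattern has no sampled copies")
        if self.weight < 1:
            raise InputError("pattern weight must be at least 1")


@dataclass(frozen=True)
class RemovalSignal:
    reason: str  # "polyallelic" or "all_missing"


def recode_biallelic(
    column: Sequence[str],
    population_index: Sequence[int],
    mode: str = "recode",
) -> SitePattern | RemovalSignal:
    """Recode one nucleotide column to a biallelic site pattern.

    State 0 is the first non-missing nucleotide in input order.  With three
    or more distinct nucleotides ``mode="remove"`` signals removal while
    ``mode="recode"`` merges every non-first nucleotide into state 1; the two
    modes agree whenever the column has at most two nucleotides.
    """
    states, n_alleles = _recode_column(column, mode)
    if n_alleles == 0:
        return RemovalSignal("all_missing")
    if states is None:
        return RemovalSignal("polyallelic")
    pattern = _column_to_pattern(states, np.asarray(population_index))
    if pattern is None:  # zero copies in both populations
        return RemovalSignal("all_missing")
    return pattern


def _recode_column(column: Sequence[str], mode: str) -> tuple[np.ndarray | None, int]:
    if mode not in ("remove", "recode"):
        raise InputError(f"unknown polyallelic mode {mode!r}")
    states = np.full(len(column), MISSING, dtype=np.int8)
    first: str | None = None
    alleles: set[str] = set()
    for i, sym in enumerate(column):
        s = sym.upper()
        if sym in MISSING_SYMBOLS or s == "N":
            continue
        alleles.add(s)
        if first is None:
            first = s
        states[i] = 0 if s == first else 1
    if first is None:
        return None, 0
    if len(alleles) > 2 and mode == "remove":
        return None, len(alleles)
    return states, len(alleles)


def _column_to_pattern(states: np.ndarray, pop_index: np.ndarray) -> SitePattern | None:
    present = states != MISSING
    n1 = int(np.sum(present & (pop_index == 0)))
    n2 = int(np.sum(present & (pop_index == 1)))
    if n1 + n2 == 0:
        return None
    # canonicalize: first non-missing copy carries state 0 (holds by
    # construction for recoded data; enforced here for simulated states)
    first = int(np.argmax(present))
    vals = states.copy()
    if vals[first] == 1:
        vals[present] = 1 - vals[present]
    r1 = int(np.sum((vals == 1) & (pop_index == 0)))
    r2 = int(np.sum((vals == 1) & (pop_index == 1)))
    return SitePattern(n1=n1, r1=r1, n2=n2, r2=r2)


@dataclass
class ComparisonData:
    """One population pair's loci, compressed patterns and bookkeeping."""

    label: str
    population_map: PopulationMap
    loci: list[Locus]
    patterns: dict[tuple[int, int, int, int], int] = field(default_factory=dict)
    n_sites: int = 0
    n_variable: int = 0
    n_polyallelic: int = 0
    n_dropped_empty: int = 0

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sequence_ids(self) -> list[str]:
        return self.population_map.sequence_ids

    @property
    def population_index(self) -> np.ndarray:
        pm = self.population_map
        return np.array([pm.population_index(s) for s in self.sequence_ids])

    @property
    def sample_sizes(self) -> tuple[int, int]:
        idx = self.population_index
        return int(np.sum(idx == 0)), int(np.sum(idx == 1))

    def pattern_arrays(self) -> tuple[np.ndarray, ...]:
        keys = sorted(self.patterns)
        n1, r1, n2, r2 = (np.array([k[i] for k in keys], dtype=int) for i in range(4))
        w = np.array([self.patterns[k] for k in keys], dtype=float)
        return n1, r1, n2, r2, w

    @classmethod
    def from_binary_loci(
        cls,
        label: str,
        population_map: PopulationMap,
        loci: Iterable[Locus],
        n_polyallelic: int = 0,
    ) -> "ComparisonData":
        data = cls(label=label, population_map=population_map, loci=list(loci),
                   n_polyallelic=n_polyallelic)
        if not data.loci:
            raise InputError(f"comparison {label!r} has no loci")
        pop_index = data.population_index
        pop0, pop1 = pop_index == 0, pop_index == 1
        for locus in data.loci:
            states = locus.states
            if states.shape[0] != len(pop_index):
                raise MappingError(
                    f"locus {locus.locus_id!r} has {states.shape[0]} rows for "
                    f"{len(pop_index)} mapped sequences"
                )
            present = states != MISSING
            n1 = present[pop0].sum(axis=0)
            n2 = present[pop1].sum(axis=0)
            keep = n1 + n2 > 0
            data.n_dropped_empty += int((~keep).sum())
            if not keep.any():
                continue
            # canonicalize each column: first non-missing copy carries state 0
            first_row = np.argmax(present, axis=0)
            flip = states[first_row, np.arange(states.shape[1])] == 1
            vals = np.where(flip[None, :], 1 - states, states)
            ones = (vals == 1) & present
            r1 = ones[pop0].sum(axis=0)
            r2 = ones[pop1].sum(axis=0)
            cols = np.stack([n1, r1, n2, r2], axis=1)[keep]
            data.n_sites += int(keep.sum())
            r_tot, n_tot = cols[:, 1] + cols[:, 3], cols[:, 0] + cols[:, 2]
            data.n_variable += int(((r_tot > 0) & (r_tot < n_tot)).sum())
            uniq, counts = np.unique(cols, axis=0, return_counts=True)
            for key, cnt in zip(map(tuple, uniq.astype(int)), counts):
                data.patterns[key] = data.patterns.get(key, 0) + int(cnt)
        return data


def read_comparison(
    source: str | Path,
    population_map: PopulationMap,
    polyallelic_mode: str = "recode",
) -> ComparisonData:
    """Load a comparison from per-locus FASTA (directory) or NEXUS (file)."""
    source = Path(source)
    if source.is_dir():
        raw_loci = list(_read_fasta_dir(source))
    elif source.suffix.lower() in (".nex", ".nexus"):
        raw_loci = list(_read_nexus(source))
    else:
        raise InputError(f"cannot read alignment source {source}")
    if not raw_loci:
        raise InputError(f"no loci found in {source}")

    seq_ids = population_map.sequence_ids
    seen: set[str] = set()
    loci: list[Locus] = []
    n_polyallelic = 0
    n_dropped_empty = 0
    for locus_id, sequences in raw_loci:
        for sid in sequences:
            if sid not in population_map.assignment:
                raise MappingError(f"sequence id {sid!r} in locus {locus_id!r} is not mapped")
        seen.update(sequences)
        length = len(next(iter(sequences.values())))
        if any(len(s) != length for s in sequences.values()):
            raise InputError(f"locus {locus_id!r} sequences have unequal lengths")
        columns = []
        for site in range(length):
            col = [sequences.get(sid, "N" * length)[site] for sid in seq_ids]
            states, n_alleles = _recode_column(col, polyallelic_mode)
            if n_alleles >= 3:
                n_polyallelic += 1
                if states is None:
                    continue
            if states is None:  # entirely missing column
                n_dropped_empty += 1
                continue
            columns.append(states)
        if columns:
            loci.append(Locus(locus_id=locus_id, states=np.array(columns).T))
    missing_ids = set(seq_ids) - seen
    if missing_ids:
        raise MappingError(f"mapped identifiers absent from the alignment: {sorted(missing_ids)}")
    data = ComparisonData.from_binary_loci(
        population_map.label, population_map, loci, n_polyallelic=n_polyallelic
    )
    data.n_dropped_empty += n_dropped_empty
    return data


def _read_fasta_dir(path: Path):
    from Bio import SeqIO

    for fasta in sorted(path.glob("*.fasta")) + sorted(path.glob("*.fa")):
        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
        if sequences:
            yield fasta.stem, sequences


def _read_nexus(path: Path):
    import dendropy

    matrix = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
    full = {taxon.label: str(matrix[taxon]) for taxon in matrix.taxon_namespace}
    subsets = {
        name: subset
        for name, subset in matrix.character_subsets.items()
    }
    if not subsets:
        yield path.stem, full
        return
    for name in sorted(subsets):
        positions = sorted(subsets[name].character_indices)
        yield name, {sid: "".join(seq[i] for i in positions) for sid, seq in full.items()}


def summarize_dataset(data: ComparisonData) -> dict:
    """Dataset summary record mirroring the loci/sites/variable/polyallelic
    table columns, plus per-population sample sizes."""
    s1, s2 = data.sample_sizes
    return {
        "comparison": data.label,
        "n_loci": data.n_loci,
        "n_sites": data.n_sites,
        "n_variable": data.n_variable,
        "n_polyallelic": data.n_polyallelic,
        "sample_size_1": s1,
        "sample_size_2": s2,
    }


_WRITE_SYMBOLS = {0: "A", 1: "C", MISSING: "N"}


def write_comparison_fasta(data: ComparisonData, out_dir: str | Path) -> list[Path]:
    """Serialize to per-locus FASTA, writing each column with its first
    observed allele as 'A' so a round trip reproduces the pattern table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_ids = data.sequence_ids
    paths = []
    for locus in data.loci:
        states = locus.states.copy()
        for col in states.T:
            present = col != MISSING
            if present.any() and col[np.argmax(present)] == 1:
                col[present] = 1 - col[present]
        path = out_dir / f"{locus.locus_id}.fasta"
        with open(path, "w") as fh:
            for row, sid in enumerate(seq_ids):
                fh.write(f">{sid}\n")
                fh.write("".join(_WRITE_SYMBOLS[int(v)] for v in states[row]) + "\n")
        paths.append(path)
    return paths
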