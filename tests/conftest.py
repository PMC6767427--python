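import numpy as np
import pytest

from codivergence.data_io import ComparisonData, Locus, PopulationMap
from codivergence.dpp import GammaPrior
from codivergence.priors import ExponentialPrior, PriorSet


@pytest.fixture(scope="session")
def study_priors() -> PriorSet:
    """The simulation-study prior set: alpha ~ Gamma(1.5, 3.13),
    tau ~ Exponential(mean 0.005), theta ~ Gamma(4, mean 0.004),
    root multiplier ~ Gamma(100, mean 1)."""
    return PriorSet(
        tau=ExponentialPrior(0.005),
        theta=GammaPrior.from_shape_mean(4.0, 0.004),
        root_multiplier=GammaPrior.from_shape_mean(100.0, 1.0),
        concentration=GammaPrior(1.5, 3.13),
    )


@pytest.fixture()
def toy_pop_map() -> PopulationMap:
    return PopulationMap(
        label="toy",
        population_labels=("island1", "island2"),
        assignment={"a1": "island1", "a2": "island1", "b1": "island2", "b2": "island2"},
    )


@pytest.fixture()
def toy_fasta_dir(tmp_path, toy_pop_map):
    """Two loci (3 and 2 sites), 2+2 samples, no polymorphism."""
    d = tmp_path / "toy_loci"
    d.mkdir()
    (d / "locus1.fasta").write_text(">a1\nAAA\n>a2\nAAA\n>b1\nAAA\n>b2\nAAA\n")
    (d / "locus2.fasta").write_text(">a1\nGG\n>a2\nGG\n>b1\nGG\n>b2\nGG\n")
    return d


def make_binary_comparison(label, columns, n1, n2):
    """Build a one-locus ComparisonData from explicit binary columns
    (lists over the n1+n2 gene copies; None marks missing)."""
    states = np.array(
        [[-1 if v is None else v for v in col] for col in columns], dtype=np.int8
    ).T
    assignment = {f"x{i}": "p1" for i in range(n1)}
    assignment.update({f"y{i}": "p2" for i in range(n2)})
    pm = PopulationMap(label=label, population_labels=("p1", "p2"), assignment=assignment)
    locus = Locus(locus_id="locus0", states=states)
    return ComparisonData.from_binary_loci(label, pm, [locus])
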