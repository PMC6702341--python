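import numpy as np
import pytest

from phylogeoabc.seq_data import LocusAlignment, PopulationMap
from phylogeoabc.synthetic import make_worked_examples


@pytest.fixture(scope="session")
def worked_examples():
    return make_worked_examples()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_alignment(rng, n=10, length=50, alphabet="ACGT", name="toy"):
    mat = rng.choice(list(alphabet), size=(n, length))
    seqs = tuple((f"s{i}", "".join(row)) for i, row in enumerate(mat))
    return LocusAlignment(name, seqs)


@pytest.fixture()
def three_group_popmap():
    """Six samples split 2/2/2 over three groups."""
    return PopulationMap({
        "s0": ("A", "a1"), "s1": ("A", "a1"),
        "s2": ("B", "b1"), "s3": ("B", "b1"),
        "s4": ("C", "c1"), "s5": ("C", "c1"),
    })
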