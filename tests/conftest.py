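import numpy as np
import pytest

from karyoz.karyotype import MarkerGenome
from karyoz.trees import RootedTree

EIGHT_TIP_NEWICK = (
    "((((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1):1,OUT:3);"
)


@pytest.fixture
def eight_tip_tree() -> RootedTree:
    return RootedTree.from_newick(EIGHT_TIP_NEWICK)


@pytest.fixture
def toy_genome() -> MarkerGenome:
    lengths = {m: 1_000_000 for m in "abcdefgh"}
    return MarkerGenome(
        {
            "chr1": [("a", 1), ("b", 1), ("c", 1)],
            "chr2": [("d", 1), ("e", 1)],
            "chr3": [("f", 1), ("g", 1), ("h", 1)],
        },
        lengths,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
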