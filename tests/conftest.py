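import numpy as np
import pytest

from mitorearr.gene_order import GeneLabel, GeneOrder, ancestral_arrangement
from mitorearr.genes import CANONICAL_GENES


def random_gene_order(rng: np.random.Generator, taxon: str = "rnd") -> GeneOrder:
    names = list(CANONICAL_GENES)
    rng.shuffle(names)
    signs = rng.integers(0, 2, size=len(names)) * 2 - 1
    return GeneOrder(
        taxon, tuple(GeneLabel(n, int(s)) for n, s in zip(names, signs))
    )


def random_signed_circle(rng: np.random.Generator, n: int) -> tuple[int, ...]:
    perm = rng.permutation(n) + 1
    signs = rng.integers(0, 2, size=n) * 2 - 1
    return tuple(int(p * s) for p, s in zip(perm, signs))


@pytest.fixture
def ancestor():
    return ancestral_arrangement()


@pytest.fixture
def rng():
    return np.random.default_rng(20240322)
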