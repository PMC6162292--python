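import numpy as np
import pytest

from teqtl import GenotypeSplit, SimDesign, simulate_trait


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def balanced_genotypes():
    """Deterministic 40-strain balanced genotype vector."""
    return np.tile([0, 1], 20)


@pytest.fixture
def linked_trait(balanced_genotypes):
    """A trait with a clear eQTL at the balanced marker."""
    design = SimDesign(n_strains=40, effect=("linear_up", "peak"))
    return simulate_trait(design, balanced_genotypes, seed=1)


@pytest.fixture
def null_trait(balanced_genotypes):
    """A trait whose two genotype groups share one pattern (no eQTL)."""
    design = SimDesign(n_strains=40, effect=("peak", "peak"))
    return simulate_trait(design, balanced_genotypes, seed=2)


@pytest.fixture
def split(balanced_genotypes):
    return GenotypeSplit.from_genotypes(balanced_genotypes)
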