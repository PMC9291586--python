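import numpy as np
import pytest

from sdturnover.genome import Locus, gamete_index


def make_gamete(**focal):
    """Gamete index with focal alleles at the named loci, e.g. XY_SD=1."""
    alleles = [0] * 7
    for name, value in focal.items():
        alleles[int(Locus[name])] = value
    return gamete_index(alleles)


@pytest.fixture
def g():
    return make_gamete


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
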