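import numpy as np
import pytest

from selsig.sfs import HaplotypeAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_alignment():
    """4 ingroup haplotypes, 2 polarizable segregating sites (derived counts
    1 and 3) on a 12-base gene; outgroup carries the ancestral alleles."""
    anc = "ATGGCTGCTAAA"
    h1 = "ATGGCTGCTAAA"
    h2 = "ATGGCAGCTAAA"  # derived A at pos 5 (count 1)
    h3 = "ATGGCTGTTAAA"  # derived T at pos 7
    h4 = "ATGGCTGTTAAA"
    h5 = "ATGGCTGTTAAA"
    # derived counts: site 5 -> 1, site 7 -> 3
    return HaplotypeAlignment(
        gene_id="g1",
        haplotypes={"a": h2, "b": h3, "c": h4, "d": h5},
        outgroup=anc,
    )
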