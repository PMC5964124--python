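import pytest

from allelescreen import build_allele_templates, build_index
from allelescreen.simulate import make_haplotype_locus, make_panel


@pytest.fixture(scope="session")
def small_panel():
    """Five biallelic SNPs with random flanks (deterministic seed)."""
    return make_panel(seed=101, n_biallelic=5, n_triallelic=0, n_quadallelic=0)


@pytest.fixture(scope="session")
def small_library(small_panel):
    templates = [t for e in small_panel for t in build_allele_templates(e)]
    return build_index(templates)


@pytest.fixture(scope="session")
def haplotype_amplicons():
    """Three staggered amplicons sharing a 3-SNP cluster spanning 68 bp."""
    return make_haplotype_locus(seed=55)
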