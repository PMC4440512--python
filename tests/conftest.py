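import pytest

from alumeth.synthetic import GenomeDesign, generate_genome


@pytest.fixture(scope="session")
def planted_genome():
    """Default toy genome with a designed Alu fragment share of 0.30."""
    return generate_genome(GenomeDesign(seed=1))


@pytest.fixture(scope="session")
def plain_genome():
    """Small Alu-free genome used as a methylome substrate."""
    genome, _repeats, _genes, _truth = generate_genome(
        GenomeDesign(seed=9, n_chroms=1, chrom_length=30_000,
                     alu_fragment_share=None, n_alu_insertions=0))
    return genome
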