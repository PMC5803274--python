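import pytest

from dsbrna import synthdata


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale simulated study: 3 x 1 Mb, 40 motifs, 12 cut."""
    genome, truth = synthdata.simulate_genome(seed=20)
    return genome, truth


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast geometry for read-level pipeline tests."""
    genome, truth = synthdata.simulate_genome(
        n_chrom=2, chrom_length=120_000, n_motifs=8, n_cut=4,
        min_separation=11_000, margin=6_000, seed=7)
    return genome, truth
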