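import pytest

from medipmap.cgi_scan import scan_genome
from medipmap.genome_model import build_feature_partition, chrom_sizes
from medipmap.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A scaled-down four-group dataset used by cross-module tests."""
    return SyntheticConfig(
        seed=42,
        chrom_lengths={"chr1": 200_000, "chr2": 120_000},
        n_cgi=12,
        n_genes=14,
        n_background_domains=8,
        n_dmg=8,
        library_size=20_000,
    )


@pytest.fixture(scope="session")
def dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def partition(dataset):
    return build_feature_partition(dataset.transcripts, chrom_sizes(dataset.genome))


@pytest.fixture(scope="session")
def islands(dataset):
    return scan_genome(dataset.genome)
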