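import numpy as np
import pytest

from promotif.synthetic import PlantedDatasetSpec, generate_planted_dataset, generate_toy_genome


@pytest.fixture(scope="session")
def toy_genome():
    """Two 50 kb contigs, GC 0.4 / 0.6, 10% soft-masked."""
    return generate_toy_genome(
        n_contigs=2, contig_length=50_000, gc_profile=[0.4, 0.6],
        mask_fraction=0.10, seed=7,
    )


@pytest.fixture(scope="session")
def small_planted():
    """A small planted dataset (40+40 records, 600 bp) for fast pipeline tests."""
    spec = PlantedDatasetSpec(
        n_pos=40, n_neg=40, length=600, upstream=450, downstream=150,
        plant_rate_pos=0.9, plant_rate_neg=0.05, seed=11,
    )
    records, planted, truth = generate_planted_dataset(spec)
    return spec, records, planted, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
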