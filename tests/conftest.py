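import numpy as np
import pytest

from nucadapt.genetics import synonymous_families


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cds(rng: np.random.Generator, n_codons: int = 300) -> str:
    """Random CDS of sense codons (no stops), uniform over the code."""
    sense = sorted(c for fam in synonymous_families().values() for c in fam)
    idx = rng.integers(0, len(sense), n_codons)
    return "".join(sense[i] for i in idx)


@pytest.fixture
def make_cds():
    return random_cds


@pytest.fixture(scope="session")
def small_collection():
    """A small deterministic synthetic collection shared across tests."""
    from nucadapt.synth import SyntheticSpec, synth_collection

    spec = SyntheticSpec(
        n_genomes=10,
        genes_per_genome=20,
        gene_length_codons_mean=120.0,
        gene_length_codons_sd=15.0,
        ncdna_segments=4,
        ncdna_length=400,
        trna_count=6,
        rrna_count=2,
        rrna_length=600,
        windows_per_genome=10,
    )
    return spec, synth_collection(spec, seed=99)
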