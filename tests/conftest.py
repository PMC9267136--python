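import numpy as np
import pytest

from splicework.cohort import cohort_models, reference_cohort
from splicework.transcript import TranscriptModel


@pytest.fixture(scope="session")
def models():
    return cohort_models()


@pytest.fixture(scope="session")
def cohort():
    return reference_cohort()


@pytest.fixture
def two_exon_model():
    """Exon 1 = genomic bases 101-200 (1-based), exon 2 = 301-400, + strand:
    c.1..100 map to 101..200, the intron is 100 nt."""
    return TranscriptModel(
        "toy", "TOY", "chr1", "+", [(100, 200), (300, 400)]
    )


def random_model(rng: np.random.Generator, max_total: int = 1000) -> TranscriptModel:
    """Small random transcript model for enumeration oracles."""
    n_exons = int(rng.integers(1, 7))
    exon_sizes = rng.integers(3, 60, size=n_exons).tolist()
    while sum(exon_sizes) > max_total:
        exon_sizes = exon_sizes[:-1]
    n_exons = len(exon_sizes)
    intron_sizes = rng.integers(1, 80, size=max(0, n_exons - 1)).tolist()
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel.from_exon_sizes(
        "rand", "RAND", "chrR", strand, exon_sizes, intron_sizes,
        genomic_start=int(rng.integers(50, 5000)),
    )
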