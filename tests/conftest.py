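import numpy as np
import pytest

from episcape import GenotypeMatrix, MarkerInfo, PairExposureTable, Phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_genotypes(dosages, marker_ids=None, sample_ids=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    marker_ids = marker_ids or [f"m{j}" for j in range(m)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    markers = [MarkerInfo(mid, 1, j + 1) for j, mid in enumerate(marker_ids)]
    return GenotypeMatrix(dosages, markers, sample_ids)


def make_table(cases, controls, coding="dominant"):
    return PairExposureTable(
        np.asarray(cases), np.asarray(controls), ("mA", "mB"), (coding, coding)
    )


def random_table(rng, low=1, high=60):
    """A random all-positive 2x2x2 exposure table."""
    return make_table(
        rng.integers(low, high, size=4), rng.integers(low, high, size=4)
    )


@pytest.fixture
def genotypes_factory():
    return make_genotypes


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def pheno_factory():
    def make(status):
        return Phenotype(np.asarray(status, dtype=np.int8))

    return make
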