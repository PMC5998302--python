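import numpy as np
import pytest

from srcca import (
    MosaicConfig,
    core_signature,
    generate_mosaic,
    mosaic_log_tpm,
    subtype_candidates,
)
from srcca.expression_io import ExpressionMatrix
from srcca.panels import default_panels


@pytest.fixture(scope="session")
def mosaic42():
    """Default synthetic mosaic at seed 42: (counts, truth)."""
    return generate_mosaic(MosaicConfig(), seed=42)


@pytest.fixture(scope="session")
def log_tpm42(mosaic42):
    counts, _ = mosaic42
    return mosaic_log_tpm(counts, seed=42)


@pytest.fixture(scope="session")
def core42(log_tpm42):
    return core_signature(log_tpm42)


@pytest.fixture(scope="session")
def ds42(log_tpm42):
    return subtype_candidates(log_tpm42)


@pytest.fixture(scope="session")
def panels():
    return default_panels()


@pytest.fixture()
def random_matrix():
    """Seeded random counts matrix factory."""

    def make(n_genes=8, n_cells=5, seed=0, unit="counts"):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 50, size=(n_genes, n_cells)).astype(float)
        return ExpressionMatrix(values,
                                [f"G{i}" for i in range(n_genes)],
                                [f"C{j}" for j in range(n_cells)], unit)

    return make
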