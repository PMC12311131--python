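import numpy as np
import pandas as pd
import pytest

from scresist import CountMatrix, NormalizedMatrix, RunConfig, SimLineSpec, simulate_line
from scresist.qc import lognormalize


#: config matched to the synthetic data scale (1000-gene panels)
@pytest.fixture
def sim_config():
    return RunConfig(min_genes=100, max_genes=1200, top_k_variable=1000)


@pytest.fixture
def line_dataset():
    """One simulated paired sensitive/resistant line at default settings."""
    return simulate_line(SimLineSpec(), seed=11)


@pytest.fixture
def small_norm():
    """Small deterministic normalized matrix (20 genes x 30 cells)."""
    rng = np.random.default_rng(5)
    counts = rng.poisson(5.0, size=(20, 30))
    counts[0] += 1  # guard against zero-total cells
    cm = CountMatrix(
        [f"G{i:02d}" for i in range(20)],
        [f"C{i:02d}" for i in range(30)],
        counts,
    )
    return lognormalize(cm)


def random_count_matrix(rng, n_genes=40, n_cells=25, mean=3.0, with_mito=True):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    if with_mito and n_genes >= 4:
        genes[0] = "MT-A"
        genes[1] = "MT-B"
        genes[2] = "RPL1"
        genes[3] = "RPS2"
    counts = rng.poisson(mean, size=(n_genes, n_cells))
    counts[:, 0] += 1  # no zero-total cell
    return CountMatrix(genes, [f"C{i:03d}" for i in range(n_cells)], counts)
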