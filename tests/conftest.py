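import numpy as np
import pandas as pd
import pytest

from dmrpipe.synthetic import CountSimConfig, generate_genome, simulate_window_counts
from dmrpipe.windows import GenomeWindows


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome({"chr1": 100_000, "chr2": 60_000}, seed=101)


@pytest.fixture(scope="session")
def small_matrix(small_genome):
    cfg = CountSimConfig(mean_library_size=50_000, n_true_dmrs=5, seed=102)
    matrix, truth = simulate_window_counts(small_genome, cfg)
    return matrix, truth


@pytest.fixture
def grid_windows():
    """One chromosome, 20 windows of 100 bp."""
    return GenomeWindows(100, ("chr1",), (2000,))


def results_frame(p_values, windows=None, lfc=None):
    """Build a minimal per-window test-result frame on a 100-bp grid."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    df = pd.DataFrame(
        {
            "window_index": np.arange(n),
            "p_value": p,
            "q_value": np.minimum(p * n, 1.0),
            "log2_fc": lfc if lfc is not None else np.zeros(n),
        }
    )
    return df
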