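import numpy as np
import pandas as pd
import pytest

from refstab.io import LONG_COLUMNS, CqTable


def make_table(mat, genes=None, samples=None, conditions=None, bio_reps=None,
               max_cycles=40.0) -> CqTable:
    """Build an aggregated CqTable from a samples x genes array (NaN = missing)."""
    mat = np.asarray(mat, dtype=float)
    n_s, n_g = mat.shape
    genes = genes or [f"g{j}" for j in range(n_g)]
    samples = samples or [f"s{i}" for i in range(n_s)]
    conditions = conditions or ["c"] * n_s
    bio_reps = bio_reps or list(range(1, n_s + 1))
    rows = [
        (samples[i], genes[j], conditions[i], bio_reps[i], 1, mat[i, j])
        for i in range(n_s) for j in range(n_g)
    ]
    return CqTable(pd.DataFrame(rows, columns=LONG_COLUMNS), max_cycles=max_cycles)


@pytest.fixture
def small_table() -> CqTable:
    """4 samples x 3 genes, no missing values."""
    rng = np.random.default_rng(123)
    return make_table(rng.uniform(22, 30, size=(4, 3)))


@pytest.fixture
def panel_table() -> CqTable:
    """Aggregated 12-sample x 9-gene panel from the generator defaults."""
    from refstab.io import aggregate_technical_replicates
    from refstab.simulate import SimulationConfig, simulate_cq

    table, _ = simulate_cq(SimulationConfig(seed=20))
    return aggregate_technical_replicates(table)
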