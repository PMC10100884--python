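import numpy as np
import pandas as pd
import pytest

from plankton_assembly.io_tables import AsvTable
from plankton_assembly.synthetic_data import (
    NeutralSimConfig,
    bundle_env_columns,
    simulate_bundle,
    simulate_neutral_table,
)


def make_table(counts, sample_ids=None, asv_ids=None) -> AsvTable:
    counts = np.asarray(counts)
    n, s = counts.shape
    return AsvTable(
        pd.DataFrame(
            counts,
            index=sample_ids or [f"S{i + 1}" for i in range(n)],
            columns=asv_ids or [f"A{j + 1}" for j in range(s)],
        )
    )


@pytest.fixture
def toy_table() -> AsvTable:
    return make_table([[3, 0, 1], [1, 5, 0], [2, 2, 4]])


@pytest.fixture(scope="session")
def neutral_table() -> AsvTable:
    """One mid-immigration neutral community, reused by read-only tests."""
    cfg = NeutralSimConfig(S=300, n_samples=30, depth=5000, m=0.3, seed=11)
    return simulate_neutral_table(cfg)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Synthetic two-region bundle on disk plus its env column names."""
    out = tmp_path_factory.mktemp("bundle")
    paths = simulate_bundle(out, seed=5)
    return {"paths": paths, "env_columns": bundle_env_columns()}
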