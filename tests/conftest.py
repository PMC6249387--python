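import numpy as np
import pandas as pd
import pytest

from scidseq import (
    AntibodyTag,
    CountMatrix,
    Panel,
    PlateLayout,
    SimConfig,
    Well,
    simulate_truth,
    truth_count_matrix,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact design for fast read-level tests."""
    return SimConfig(
        n_cell_wells=16,
        n_empty_wells=6,
        panel_size=24,
        mean_depth=400,
        error_rate=0.0,
        duplication_rate=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_raw(small_truth) -> CountMatrix:
    return truth_count_matrix(small_truth)


@pytest.fixture(scope="session")
def default_truth():
    """One default-design experiment (84 cells, 48 empty, 69 antibodies)."""
    return simulate_truth(SimConfig(seed=5))


def toy_panel(barcodes, **tag_kwargs) -> Panel:
    return Panel(
        [
            AntibodyTag(antibody_name=f"Ab{i}", barcode=bc, **tag_kwargs)
            for i, bc in enumerate(barcodes)
        ]
    )


def toy_matrix(values: np.ndarray, state: str = "raw", gate=None) -> CountMatrix:
    """CountMatrix around a plain array; all wells are cell wells."""
    n, m = values.shape
    wells = [f"C{i}" for i in range(n)]
    names = [f"Ab{j}" for j in range(m)]
    df = pd.DataFrame(values, index=pd.Index(wells, name="well_id"), columns=names)
    row_meta = pd.DataFrame(
        {
            "well_type": "cell",
            "gate_label": gate if gate is not None else "none",
            "total_umis": df.sum(axis=1),
        },
        index=df.index,
    )
    col_meta = pd.DataFrame(index=pd.Index(names, name="antibody_name"))
    col_meta["pathway_group"] = ""
    return CountMatrix(values=df, row_meta=row_meta, col_meta=col_meta, state=state)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
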