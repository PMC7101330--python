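import numpy as np
import pandas as pd
import pytest

from chimeraseq import (
    DeconvolutionParams,
    SimulationConfig,
    simulate_chimera,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_cells_human=40,
        n_cells_mouse=40,
        doublet_rate=0.05,
        n_ortholog_genes=120,
        n_human_only_genes=15,
        n_mouse_only_genes=15,
        molecules_per_cell=60.0,
        reads_per_molecule=2.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_chimera(small_config)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """No doublets, no misassignment: species are perfectly separable."""
    return SimulationConfig(
        n_cells_human=30,
        n_cells_mouse=30,
        doublet_rate=0.0,
        misassignment_rate=0.0,
        n_ortholog_genes=80,
        n_human_only_genes=10,
        n_mouse_only_genes=10,
        molecules_per_cell=40.0,
        reads_per_molecule=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return simulate_chimera(clean_config)


@pytest.fixture
def default_params() -> DeconvolutionParams:
    return DeconvolutionParams()


def make_reads(rows) -> pd.DataFrame:
    """Build a read table from (read_id, barcode, umi, gh, sh, gm, sm) rows."""
    df = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "barcode",
            "umi",
            "gene_human",
            "score_human",
            "gene_mouse",
            "score_mouse",
        ],
    )
    df["score_human"] = df["score_human"].astype(float)
    df["score_mouse"] = df["score_mouse"].astype(float)
    return df


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
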