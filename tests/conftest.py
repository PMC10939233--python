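import numpy as np
import pandas as pd
import pytest

from proxsim import SimulationConfig, simulate_population

FIG3_COMPLEXES = ["1:1", "1:2", "2:1", "2:2"]


def fig3_config(seed: int = 0, n_cells: int = 100) -> SimulationConfig:
    """Three-protein scenario with a 2x2 complex block among proteins 1 and 2
    and a nearly absent protein 3 (monomer means 20 / 15 / 2 UMIs per cell)."""
    return SimulationConfig(
        protein_names=["1", "2", "3"],
        probe_a_means=[20, 15, 2],
        probe_b_means=[20, 15, 2],
        complex_means=[[30, 15, 0], [15, 25, 0], [0, 0, 0]],
        n_cells=n_cells,
        seed=seed,
    )


def null_config(seed: int = 0, abundance=(1000, 1000, 100),
                n_cells: int = 100) -> SimulationConfig:
    """No-complex control population: every PLA count is proximity noise."""
    return SimulationConfig(
        protein_names=["1", "2", "3"],
        probe_a_means=list(abundance),
        probe_b_means=list(abundance),
        complex_means=np.zeros((3, 3)),
        n_cells=n_cells,
        seed=seed,
    )


@pytest.fixture(scope="session")
def fig3_sim():
    return simulate_population(fig3_config(seed=0))


@pytest.fixture(scope="session")
def null_sim():
    return simulate_population(null_config(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rank1_counts(n_cells: int = 80, excess: float = 8.0, seed: int = 7
                 ) -> pd.DataFrame:
    """Synthetic 3-protein PLA table: independent (rank-1) background of 50
    UMIs per product plus a single enrichment of ``excess`` at product 1:2."""
    from proxsim import pla_product_ids

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_cells):
        M = np.full((3, 3), 50.0)
        M[0, 1] += excess
        M += rng.normal(0, 1.0, (3, 3))
        rows.append(np.round(M).clip(0).ravel())
    return pd.DataFrame(rows, columns=pla_product_ids(["1", "2", "3"]),
                        index=[f"c{t}" for t in range(n_cells)])
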