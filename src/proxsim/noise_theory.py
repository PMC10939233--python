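"""Closed-form model of proximity noise on a spherical cell surface.

Two antibody probes placed uniformly at random on a sphere of radius ``R``
ligate when their chord (3-D Euclidean) distance is at most ``d``.  The chord
length ``L`` between two uniform random points has density ``L / (2 R**2)`` on
``[0, 2R]``, so the ligation probability is ``d**2 / (4 R**2)``.  If protein i
carries ``A_i`` probe-A molecules and protein j carries ``B_j`` probe-B
molecules, and every probe may ligate arbitrarily often, the random-ligation
count of PLA product i:j is Binomial(``A_i * B_j``, ``d**2 / (4 R**2)``) with
mean ``d**2 / (4 R**2) * A_i * B_j``.  Because a physical probe is consumed by
its first ligation, this mean is an upper bound for the simulated counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NoiseModelParams",
    "ligation_probability",
    "expected_random_count",
    "noise_scaling_curve",
]


@dataclass(frozen=True)
class NoiseModelParams:
    """Geometry of the spherical-cell noise model.

    Parameters
    ----------
    radius
        Cell radius R, in simulation length units (5000 units = 5 um by
        convention).
    ligation_distance
        Maximum chord distance d at which an A/B probe pair ligates, in the
        same units (50 units = 50 nm by convention).
    """

    radius: float = 5000.0
    ligation_distance: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.ligation_distance < self.radius:
            raise ValueError(
                f"require 0 < ligation_distance < radius, got "
                f"d={self.ligation_distance}, R={self.radius}"
            )


def ligation_probability(d: float, R: float) -> float:
    """Probability that two uniform random points on a sphere of radius ``R``
    lie within chord distance ``d`` of each other.

    Returns ``d**2 / (4 R**2)``, the CDF of the chord-length law ``L/(2R**2)``
    evaluated at ``d``.  At ``d = 2R`` (the sphere's diameter) this reaches 1.
    """
    if R <= 0:
        raise ValueError(f"radius must be positive, got {R}")
    if not 0 < d <= 2 * R:
        raise ValueError(f"require 0 < d <= 2R, got d={d}, R={R}")
    return d * d / (4.0 * R * R)


def expected_random_count(A: float, B: float, d: float, R: float) -> float:
    """Expected random-ligation count of one PLA product.

    ``E[X] = d**2/(4 R**2) * A * B`` for ``A`` probe-A and ``B`` probe-B
    molecules of the two target proteins.  This binomial approximation lets
    every probe ligate repeatedly, so it upper-bounds the single-use
    simulator's mean count.
    """
    if A < 0 or B < 0:
        raise ValueError(f"probe counts must be non-negative, got A={A}, B={B}")
    return ligation_probability(d, R) * A * B


def noise_scaling_curve(
    abundance_grid,
    d_grid,
    R: float = 5000.0,
    n_cells: int = 500,
    nb_dispersion: float = 1.5,
    variance_mode: str = "none",
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Monte-Carlo mean no-complex PLA count over an abundance x distance grid.

    For every combination of abundance ``a`` (used for both probe A and probe
    B of a single protein) and ligation distance ``d``, simulates ``n_cells``
    cells with no complexes and records the mean and standard error of the
    homotypic PLA count, next to the binomial expectation.

    Returns
    -------
    table
        One row per grid point with columns ``abundance``, ``distance``,
        ``mean_count``, ``se_count``, ``expected_count``.
    slopes
        ``{"abundance": s_a, "distance": s_d}`` -- log-log regression slopes
        of the simulated mean versus abundance (at each distance, averaged)
        and versus distance (at each abundance, averaged).  Both are 2 under
        the quadratic noise law.
    """
    from .sphere_sim import SimulationConfig, simulate_population

    abundance_grid = np.asarray(abundance_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if abundance_grid.size == 0 or d_grid.size == 0:
        raise ValueError("grids must be non-empty")

    ss = np.random.SeedSequence(seed)
    rows = []
    for a in abundance_grid:
        for d in d_grid:
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            config = SimulationConfig(
                protein_names=["p"],
                probe_a_means=[a],
                probe_b_means=[a],
                complex_means=[[0.0]],
                radius=R,
                ligation_distance=d,
                nb_dispersion=nb_dispersion,
                variance_mode=variance_mode,
                n_cells=n_cells,
                seed=sub_seed,
            )
            sim = simulate_population(config)
            counts = sim.pla["p:p"].to_numpy(dtype=float)
            rows.append(
                {
                    "abundance": a,
                    "distance": d,
                    "mean_count": counts.mean(),
                    "se_count": counts.std(ddof=1) / np.sqrt(len(counts)),
                    "expected_count": expected_random_count(a, a, d, R),
                }
            )
    table = pd.DataFrame(rows)

    def _loglog_slope(df: pd.DataFrame, x: str) -> float:
        ok = df["mean_count"] > 0
        if ok.sum() < 2:
            return np.nan
        return np.polyfit(np.log(df.loc[ok, x]), np.log(df.loc[ok, "mean_count"]), 1)[0]

    slope_a = np.nanmean(
        [_loglog_slope(g, "abundance") for _, g in table.groupby("distance")]
    )
    slope_d = np.nanmean(
        [_loglog_slope(g, "distance") for _, g in table.groupby("abundance")]
    )
    return table, {"abundance": float(slope_a), "distance": float(slope_d)}
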