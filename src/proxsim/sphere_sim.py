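"""Geometric single-cell simulator of Prox-seq PLA product counts.

Each cell is a sphere of radius ``R``.  Probe-A and probe-B molecules that
bind non-interacting ("monomeric") protein copies are placed as independent
uniform random points on the sphere surface; each protein complex i:j places
one probe-A point (labelled i) and one probe-B point (labelled j) at the same
coordinates.  Every A/B pair within the ligation distance ``d`` is a candidate
PLA product; candidates are visited in uniformly random order and matched
greedily, each probe ligating at most once.  Unmatched probes are reported as
non-proximal ("free oligo") counts, the quantity measured experimentally by
the free-oligo assay modification.

Per-cell molecule numbers are either the configured means (``variance_mode
= "none"``) or negative-binomial draws with dispersion ``n_NB`` (mean ``mu``,
variance ``mu + mu**2 / n_NB``), with probe-B counts tied proportionally to
the probe-A draw of the same protein.  Optionally every probe carries an
independent Bernoulli nonspecific-binding flag, which classifies each PLA
product as both-specific, one-specific or nonspecific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SimulationConfig",
    "CellRealization",
    "SimulationResult",
    "sample_sphere_points",
    "sample_nb_count",
    "realize_cell",
    "ligate",
    "simulate_population",
    "pla_product_ids",
]

CATEGORY_NAMES = ("both_specific", "one_specific", "nonspecific")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Full parameterization of one simulated cell population.

    Parameters
    ----------
    protein_names
        Panel identifiers; may not contain ``":"`` (reserved as the PLA
        product id separator).
    probe_a_means, probe_b_means
        Mean per-cell counts of non-interacting probe A / probe B per protein
        (UMIs per cell).
    complex_means
        ``n x n`` matrix of mean complex counts ``c[i, j]`` for the ordered
        pair (probe-A target i, probe-B target j); homodimers on the diagonal.
    nb_dispersion
        Negative-binomial dispersion ``n_NB`` (> 0); 1.5 matches the
        overdispersion of experimental Jurkat/Raji Prox-seq data.
    radius, ligation_distance
        Sphere radius R and ligation threshold d, same length units
        (defaults 5000 and 50, i.e. 5 um and 50 nm).
    nonspecific_prob
        Per-protein probability that a bound probe is nonspecific; scalar or
        length-n sequence.
    n_cells
        Number of cells to simulate.
    seed
        Seed for the population-level :class:`numpy.random.SeedSequence`;
        per-cell substreams are spawned from it, so increasing ``n_cells``
        leaves earlier cells unchanged.
    variance_mode
        ``"negative_binomial"`` (default) or ``"none"`` (counts fixed at the
        rounded means).
    """

    protein_names: list[str]
    probe_a_means: np.ndarray
    probe_b_means: np.ndarray
    complex_means: np.ndarray
    nb_dispersion: float = 1.5
    radius: float = 5000.0
    ligation_distance: float = 50.0
    nonspecific_prob: np.ndarray = 0.0
    n_cells: int = 100
    seed: int | None = 0
    variance_mode: str = "negative_binomial"

    def __post_init__(self) -> None:
        n = len(self.protein_names)
        if n == 0:
            raise ValueError("protein panel is empty")
        for name in self.protein_names:
            if ":" in str(name):
                raise ValueError(f"protein name may not contain ':': {name!r}")
        if len(set(self.protein_names)) != n:
            raise ValueError("protein names must be unique")
        self.probe_a_means = np.asarray(self.probe_a_means, dtype=float)
        self.probe_b_means = np.asarray(self.probe_b_means, dtype=float)
        self.complex_means = np.asarray(self.complex_means, dtype=float)
        self.nonspecific_prob = np.broadcast_to(
            np.asarray(self.nonspecific_prob, dtype=float), (n,)
        ).copy()
        if self.probe_a_means.shape != (n,) or self.probe_b_means.shape != (n,):
            raise ValueError("probe mean vectors must have one entry per protein")
        if self.complex_means.shape != (n, n):
            raise ValueError(f"complex_means must be {n}x{n}")
        if (
            self.probe_a_means.min(initial=0) < 0
            or self.probe_b_means.min(initial=0) < 0
            or self.complex_means.min(initial=0) < 0
        ):
            raise ValueError("all mean counts must be non-negative")
        bad = (self.probe_b_means > 0) & (self.probe_a_means == 0)
        if bad.any():
            raise ValueError(
                "probe_b_means > 0 requires probe_a_means > 0 for the same "
                f"protein (B/A coupling undefined): {np.flatnonzero(bad)}"
            )
        if not 0 < self.ligation_distance < self.radius:
            raise ValueError("require 0 < ligation_distance < radius")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if ((self.nonspecific_prob < 0) | (self.nonspecific_prob > 1)).any():
            raise ValueError("nonspecific_prob must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.variance_mode not in ("none", "negative_binomial"):
            raise ValueError(
                f"variance_mode must be 'none' or 'negative_binomial', "
                f"got {self.variance_mode!r}"
            )

    @property
    def n_proteins(self) -> int:
        return len(self.protein_names)


def pla_product_ids(protein_names) -> list[str]:
    """All n**2 ordered PLA product ids "i:j" in row-major pair order."""
    return [f"{a}:{b}" for a in protein_names for b in protein_names]


# ---------------------------------------------------------------------------
# elementary sampling
# ---------------------------------------------------------------------------

def sample_sphere_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` points uniformly on the sphere of the given radius.

    Uses the area-preserving parameterization x = R sqrt(1-u^2) cos(theta),
    y = R sqrt(1-u^2) sin(theta), z = R u with u ~ U[-1, 1) and
    theta ~ U[0, 2 pi), so every point lies exactly at distance R from the
    origin.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    u = rng.uniform(-1.0, 1.0, size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    s = np.sqrt(1.0 - u * u)
    return radius * np.column_stack((s * np.cos(theta), s * np.sin(theta), u))


def sample_nb_count(mean: float, n_nb: float, rng: np.random.Generator) -> int:
    """Draw one negative-binomial count with the given mean and dispersion.

    The draw counts failures before ``n_nb`` successes with success
    probability ``p = (1 + mean/n_nb)**-1``, so E = mean and
    Var = mean + mean**2 / n_nb.  A zero mean returns 0 deterministically.
    """
    if mean < 0:
        raise ValueError(f"mean must be non-negative, got {mean}")
    if n_nb <= 0:
        raise ValueError(f"n_nb must be positive, got {n_nb}")
    if mean == 0:
        return 0
    p = 1.0 / (1.0 + mean / n_nb)
    return int(rng.negative_binomial(n_nb, p))


# ---------------------------------------------------------------------------
# single-cell realization
# ---------------------------------------------------------------------------

@dataclass
class CellRealization:
    """One cell's probe point cloud before ligation.

    ``a_points``/``b_points`` are (N, 3) coordinates on the sphere;
    ``a_labels``/``b_labels`` give each point's target-protein index and
    ``a_nonspecific``/``b_nonspecific`` its Bernoulli nonspecific flag.
    ``a_pair_id``/``b_pair_id`` link the two probes of a complex (-1 for
    monomer-bound probes): the k-th complex point appears once in each probe
    set with the same id and identical coordinates.
    """

    a_points: np.ndarray
    a_labels: np.ndarray
    a_nonspecific: np.ndarray
    a_pair_id: np.ndarray
    b_points: np.ndarray
    b_labels: np.ndarray
    b_nonspecific: np.ndarray
    b_pair_id: np.ndarray
    drawn_probe_counts: tuple[np.ndarray, np.ndarray] = field(default=None)
    true_complex_counts: np.ndarray = field(default=None)


def realize_cell(config: SimulationConfig, rng: np.random.Generator) -> CellRealization:
    """Draw one cell's molecule counts and place all probes on the sphere.

    Non-interacting probe-A counts are NB draws (or the rounded means);
    probe-B counts follow ``B_i^(t) = round((B_i / A_i) * A_i^(t))`` so the
    two probes of one protein covary.  Complex counts are independent NB
    draws; each complex contributes a coincident A/B point pair.
    """
    n = config.n_proteins
    nb = config.nb_dispersion
    use_nb = config.variance_mode == "negative_binomial"

    a_counts = np.zeros(n, dtype=int)
    b_counts = np.zeros(n, dtype=int)
    for i in range(n):
        if use_nb:
            a_counts[i] = sample_nb_count(config.probe_a_means[i], nb, rng)
        else:
            a_counts[i] = int(round(config.probe_a_means[i]))
        if config.probe_a_means[i] > 0:
            ratio = config.probe_b_means[i] / config.probe_a_means[i]
            b_counts[i] = int(round(ratio * a_counts[i])) if use_nb else int(
                round(config.probe_b_means[i])
            )
        else:
            b_counts[i] = 0

    c_counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            mu = config.complex_means[i, j]
            if use_nb:
                c_counts[i, j] = sample_nb_count(mu, nb, rng)
            else:
                c_counts[i, j] = int(round(mu))

    # monomer-bound probes: independent uniform placements
    a_pts = [sample_sphere_points(int(a_counts.sum()), config.radius, rng)]
    a_lab = [np.repeat(np.arange(n), a_counts)]
    b_pts = [sample_sphere_points(int(b_counts.sum()), config.radius, rng)]
    b_lab = [np.repeat(np.arange(n), b_counts)]

    # complex-bound probes: one coincident A/B point pair per complex
    total_c = int(c_counts.sum())
    c_pts = sample_sphere_points(total_c, config.radius, rng)
    pair_ids = np.arange(total_c)
    ij = np.repeat(
        np.arange(n * n).reshape(n, n).ravel(), c_counts.ravel()
    )
    a_pts.append(c_pts)
    a_lab.append(ij // n)
    b_pts.append(c_pts)
    b_lab.append(ij % n)

    a_points = np.vstack(a_pts)
    a_labels = np.concatenate(a_lab)
    b_points = np.vstack(b_pts)
    b_labels = np.concatenate(b_lab)
    a_pair = np.concatenate([np.full(len(a_lab[0]), -1), pair_ids])
    b_pair = np.concatenate([np.full(len(b_lab[0]), -1), pair_ids])

    p_ns = config.nonspecific_prob
    a_flags = rng.random(len(a_labels)) < p_ns[a_labels]
    b_flags = rng.random(len(b_labels)) < p_ns[b_labels]

    return CellRealization(
        a_points=a_points,
        a_labels=a_labels,
        a_nonspecific=a_flags,
        a_pair_id=a_pair,
        b_points=b_points,
        b_labels=b_labels,
        b_nonspecific=b_flags,
        b_pair_id=b_pair,
        drawn_probe_counts=(a_counts, b_counts),
        true_complex_counts=c_counts,
    )


# ---------------------------------------------------------------------------
# ligation
# ---------------------------------------------------------------------------

def _candidate_pairs_kdtree(a_points, b_points, d) -> np.ndarray:
    """(N, 2) candidate (A-index, B-index) pairs within distance d, in
    lexicographic order."""
    if len(a_points) == 0 or len(b_points) == 0:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(b_points)
    neighbours = tree.query_ball_point(a_points, r=d)
    pairs = [
        (ai, bi) for ai, nbrs in enumerate(neighbours) for bi in sorted(nbrs)
    ]
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def _candidate_pairs_brute(a_points, b_points, d) -> np.ndarray:
    """Brute-force O(N_A * N_B) candidate pairs; reference for the KD-tree
    path, identical output (lexicographic order)."""
    if len(a_points) == 0 or len(b_points) == 0:
        return np.empty((0, 2), dtype=np.int64)
    d2 = float(d) * float(d)
    pairs = []
    for ai, p in enumerate(a_points):
        diff = b_points - p
        hit = np.flatnonzero(np.einsum("ij,ij->i", diff, diff) <= d2)
        pairs.extend((ai, bi) for bi in hit)
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def ligate(
    cell: CellRealization,
    d: float,
    rng: np.random.Generator,
    n_proteins: int | None = None,
    method: str = "kdtree",
):
    """Match A/B probe pairs within distance ``d`` and tally PLA products.

    All candidate pairs at chord distance <= d are listed, shuffled uniformly
    with the cell's RNG stream and accepted greedily, skipping any probe that
    has already ligated (single-use matching).  Returns per-pair count
    matrices:

    - ``X`` -- (n, n) PLA counts by (A-target, B-target);
    - ``categories`` -- dict of (n, n) tallies splitting X by the two probes'
      nonspecific flags (both_specific / one_specific / nonspecific);
    - ``complex_ligations`` -- (n, n) matched pairs that are a complex's own
      coincident A/B couple (competition losses are X's complex fraction
      minus this);
    - ``aprime``, ``bprime`` -- per-protein unmatched (non-proximal) probe
      counts, so matched_A(i) + aprime[i] equals the number of A-points of
      protein i.
    """
    if d <= 0:
        raise ValueError(f"ligation distance must be positive, got {d}")
    n = int(n_proteins if n_proteins is not None else
            max(cell.a_labels.max(initial=-1), cell.b_labels.max(initial=-1)) + 1)

    if method == "kdtree":
        pairs = _candidate_pairs_kdtree(cell.a_points, cell.b_points, d)
    elif method == "brute":
        pairs = _candidate_pairs_brute(cell.a_points, cell.b_points, d)
    else:
        raise ValueError(f"unknown method {method!r}")

    order = rng.permutation(len(pairs))
    a_used = np.zeros(len(cell.a_points), dtype=bool)
    b_used = np.zeros(len(cell.b_points), dtype=bool)

    X = np.zeros((n, n), dtype=int)
    categories = {name: np.zeros((n, n), dtype=int) for name in CATEGORY_NAMES}
    complex_lig = np.zeros((n, n), dtype=int)

    for k in order:
        ai, bi = pairs[k]
        if a_used[ai] or b_used[bi]:
            continue
        a_used[ai] = True
        b_used[bi] = True
        i = cell.a_labels[ai]
        j = cell.b_labels[bi]
        X[i, j] += 1
        n_ns = int(cell.a_nonspecific[ai]) + int(cell.b_nonspecific[bi])
        categories[CATEGORY_NAMES[n_ns]][i, j] += 1
        if cell.a_pair_id[ai] >= 0 and cell.a_pair_id[ai] == cell.b_pair_id[bi]:
            complex_lig[i, j] += 1

    aprime = np.bincount(cell.a_labels[~a_used], minlength=n)
    bprime = np.bincount(cell.b_labels[~b_used], minlength=n)
    return X, categories, complex_lig, aprime, bprime


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Simulated population: observed counts plus ground truth.

    ``pla`` is the cells x PLA-products UMI matrix (columns "i:j"),
    ``nonproximal`` the cells x free-oligo matrix (columns
    "<protein>:free_oligo_B" for unligated probe A and
    "free_oligo_A:<protein>" for unligated probe B), ``truth`` the drawn
    per-cell complex counts and ``complex_ligations`` the subset of PLA
    counts that came from a complex's own probe pair.  ``categories`` splits
    ``pla`` by binding specificity.
    """

    pla: pd.DataFrame
    nonproximal: pd.DataFrame
    truth: pd.DataFrame
    complex_ligations: pd.DataFrame
    categories: dict[str, pd.DataFrame]
    config: SimulationConfig


def simulate_population(config: SimulationConfig) -> SimulationResult:
    """Simulate ``config.n_cells`` independent cells.

    Each cell runs on its own RNG substream spawned from the population seed,
    so results are reproducible and extending ``n_cells`` does not perturb
    earlier cells.
    """
    n = config.n_proteins
    names = config.protein_names
    product_ids = pla_product_ids(names)
    cell_ids = [f"cell{t}" for t in range(config.n_cells)]

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_cells)

    X_all = np.zeros((config.n_cells, n * n), dtype=int)
    truth_all = np.zeros((config.n_cells, n * n), dtype=int)
    clig_all = np.zeros((config.n_cells, n * n), dtype=int)
    ap_all = np.zeros((config.n_cells, n), dtype=int)
    bp_all = np.zeros((config.n_cells, n), dtype=int)
    cat_all = {
        name: np.zeros((config.n_cells, n * n), dtype=int)
        for name in CATEGORY_NAMES
    }

    for t in range(config.n_cells):
        rng = np.random.default_rng(children[t])
        cell = realize_cell(config, rng)
        X, cats, clig, aprime, bprime = ligate(
            cell, config.ligation_distance, rng, n_proteins=n
        )
        X_all[t] = X.ravel()
        truth_all[t] = cell.true_complex_counts.ravel()
        clig_all[t] = clig.ravel()
        ap_all[t] = aprime
        bp_all[t] = bprime
        for name in CATEGORY_NAMES:
            cat_all[name][t] = cats[name].ravel()

    nonprox_cols = [f"{p}:free_oligo_B" for p in names] + [
        f"free_oligo_A:{p}" for p in names
    ]
    return SimulationResult(
        pla=pd.DataFrame(X_all, index=cell_ids, columns=product_ids),
        nonproximal=pd.DataFrame(
            np.hstack([ap_all, bp_all]), index=cell_ids, columns=nonprox_cols
        ),
        truth=pd.DataFrame(truth_all, index=cell_ids, columns=product_ids),
        complex_ligations=pd.DataFrame(
            clig_all, index=cell_ids, columns=product_ids
        ),
        categories={
            name: pd.DataFrame(cat_all[name], index=cell_ids, columns=product_ids)
            for name in CATEGORY_NAMES
        },
        config=config,
    )
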