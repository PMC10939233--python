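"""Protein-complex inference from cells x PLA-product count matrices.

Four procedures are provided, all operating on a square panel of PLA products
"i:j" (probe-A target i, probe-B target j):

- the **iterative method**: per cell, repeatedly subtract the expected
  random-ligation count (built from observed margins minus current complex
  estimates) from the observed count, with a population-level one-sided
  t-test + Benjamini-Hochberg gate zeroing products whose mean estimate is
  not credibly above a threshold, and a symmetry rule tying j:i to i:j;
- the **LR method**: per product, weighted least squares of the observed
  count on the product of non-proximal ("free oligo") probe counts
  ``A'_i * B'_j`` across cells, calling a complex when the intercept exceeds
  a cutoff, and quantifying it as observed minus slope * A'B';
- the **ensemble method**: the iterative method initialized at the LR
  method's per-cell complex estimates;
- a per-cell one-sided **Fisher's exact test** of PLA product enrichment on
  the 2x2 table of margin counts, BH-corrected within each cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .sphere_sim import pla_product_ids

__all__ = [
    "IterativeSettings",
    "LRSettings",
    "ComplexPrediction",
    "FisherResult",
    "protein_abundance",
    "expected_pla_count",
    "iterative_predict",
    "lr_predict",
    "ensemble_predict",
    "fisher_detect",
    "bh_adjust",
    "split_nonproximal",
]


# ---------------------------------------------------------------------------
# settings and results
# ---------------------------------------------------------------------------

@dataclass
class IterativeSettings:
    """Tuning knobs of the iterative method.

    ``tolerance`` is the convergence threshold on the largest change of any
    product's mean estimate between iterations (UMIs); ``sym_weight`` is the
    fraction of Y[i, j] assigned to the symmetric partner j:i when only i:j
    passes the test; ``t_test_mean_threshold`` is the alternative-hypothesis
    mean (UMIs) of the one-sided one-sample t-test.
    """

    max_iterations: int = 100
    tolerance: float = 0.01
    sym_weight: float = 1.0
    alpha: float = 0.05
    t_test_mean_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")


@dataclass
class LRSettings:
    """Tuning knobs of the LR method.

    ``beta_cutoff`` is the intercept threshold of the one-sided test (1 for
    simulated data; 10 is appropriate for experimental data).
    ``interaction_scale`` rescales the regressor A'B' for conditioning when
    its median exceeds ``auto_scale_ratio`` times the median response; the
    reported slope and complex counts are invariant to it.  Cells with
    A'B' = 0 carry an undefined weight and are dropped from that product's
    fit; a product losing more than ``max_dropped_fraction`` of its cells is
    flagged unreliable and left undetected.
    """

    beta_cutoff: float = 1.0
    alpha: float = 0.05
    interaction_scale: float = 1e6
    auto_scale_ratio: float = 1e3
    max_dropped_fraction: float = 0.5
    min_cells: int = 3

    def __post_init__(self) -> None:
        if self.beta_cutoff < 0:
            raise ValueError("beta_cutoff must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ComplexPrediction:
    """Per-cell complex count estimates plus per-complex calls.

    ``counts`` is cells x complexes (non-negative after finalization);
    ``detected`` flags complexes with a population-level call; undetected
    complexes have counts identically 0.  ``pvalues_adj`` holds the final
    BH-adjusted p-values of the population test (NaN where no test was run).
    For the LR family ``beta0``/``beta1`` carry the fitted regression
    coefficients per product.
    """

    counts: pd.DataFrame
    detected: pd.Series
    pvalues_adj: pd.Series
    method: str
    iterations: int = 0
    converged: bool = True
    beta0: pd.Series | None = None
    beta1: pd.Series | None = None
    flags: dict = field(default_factory=dict)


@dataclass
class FisherResult:
    """Per-cell enrichment calls from the one-sided Fisher's exact test."""

    pvalues_adj: pd.DataFrame
    calls: pd.DataFrame
    positive_fraction: pd.Series
    alpha: float


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _panel(X: pd.DataFrame) -> list[str]:
    """Protein names from a square "i:j" product panel, in first-seen order."""
    names: list[str] = []
    for col in X.columns:
        parts = str(col).split(":")
        if len(parts) != 2:
            raise ValueError(f"PLA product id must be 'i:j', got {col!r}")
        for p in parts:
            if p not in names:
                names.append(p)
    return names


def _to_cube(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Reshape cells x products to (cells, n, n), filling absent products
    with zeros."""
    names = _panel(X)
    n = len(names)
    full = pla_product_ids(names)
    cube = pd.DataFrame(0.0, index=X.index, columns=full)
    cube[X.columns] = X.to_numpy(dtype=float)
    return cube.to_numpy().reshape(len(X), n, n), names


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN treated as 1."""
    p = np.asarray(pvalues, dtype=float).copy()
    p[np.isnan(p)] = 1.0
    return multipletests(p, method="fdr_bh")[1]


def split_nonproximal(nonproximal: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a free-oligo count table into A' and B' tables keyed by protein.

    Columns "<p>:free_oligo_B" hold the unligated probe-A count A'_p and
    columns "free_oligo_A:<p>" the unligated probe-B count B'_p.
    """
    aprime, bprime = {}, {}
    for col in nonproximal.columns:
        parts = str(col).split(":")
        if len(parts) != 2:
            raise ValueError(f"free-oligo id must contain one ':', got {col!r}")
        left, right = parts
        if right == "free_oligo_B":
            aprime[left] = nonproximal[col]
        elif left == "free_oligo_A":
            bprime[right] = nonproximal[col]
        else:
            raise ValueError(
                f"column {col!r} is neither '<p>:free_oligo_B' nor "
                "'free_oligo_A:<p>'"
            )
    return pd.DataFrame(aprime), pd.DataFrame(bprime)


# ---------------------------------------------------------------------------
# protein abundance and expected counts
# ---------------------------------------------------------------------------

def protein_abundance(X: pd.DataFrame) -> pd.DataFrame:
    """Per-cell protein counts estimated from PLA products.

    ``Protein_i = sum_l X[i, l] + sum_k X[k, i]``; the homodimer product i:i
    appears in both sums and is therefore counted twice, matching the two
    molecules a homodimer contributes.
    """
    cube, names = _to_cube(X)
    totals = cube.sum(axis=2) + cube.sum(axis=1)
    return pd.DataFrame(totals, index=X.index, columns=names)


def expected_pla_count(X: pd.DataFrame) -> pd.DataFrame:
    """Expected random count ``E[i, j] = rowsum_i * colsum_j / total`` per cell.

    Margins of E equal the margins of X (the estimate redistributes each
    cell's total under independence of the A- and B-side margins).  Cells
    with an all-zero row are returned as all-zero E.
    """
    cube, names = _to_cube(X)
    row = cube.sum(axis=2)
    col = cube.sum(axis=1)
    tot = cube.sum(axis=(1, 2))
    safe = np.where(tot > 0, tot, 1.0)
    E = row[:, :, None] * col[:, None, :] / safe[:, None, None]
    E[tot == 0] = 0.0
    return pd.DataFrame(
        E.reshape(len(X), -1), index=X.index, columns=pla_product_ids(names)
    )


# ---------------------------------------------------------------------------
# iterative method
# ---------------------------------------------------------------------------

def _population_test(
    Y: np.ndarray, threshold: float, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided one-sample t-test per product (H1: mean > threshold) with a
    BH correction across the product panel; returns (passed, adjusted p)."""
    n_cells, n, _ = Y.shape
    flat = Y.reshape(n_cells, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_1samp(flat, popmean=threshold, axis=0,
                                alternative="greater")
        p = np.asarray(res.pvalue, dtype=float)
    # zero-variance products: decisive if strictly above/below the threshold
    sd = flat.std(axis=0)
    exact = sd == 0
    p[exact & (flat.mean(axis=0) > threshold)] = 0.0
    p[exact & (flat.mean(axis=0) <= threshold)] = 1.0
    p_adj = bh_adjust(p)
    return (p_adj <= alpha).reshape(n, n), p_adj.reshape(n, n)


def iterative_predict(
    X: pd.DataFrame,
    settings: IterativeSettings | None = None,
    init: pd.DataFrame | np.ndarray | None = None,
) -> ComplexPrediction:
    """Iterative background-subtraction estimate of complex counts.

    Starting from ``Y = 0`` (or ``init``), each iteration recomputes, per
    cell,

        ``Y[i,j] <- X[i,j] - (rowX_i - rowY_i) (colX_j - colY_j)
                              / (totX - totY)``

    i.e. the observed count minus the random-ligation expectation of the
    non-complex remainder.  After each sweep a one-sided t-test across cells
    (H1: mean Y[i,j] > threshold) with BH correction zeroes non-significant
    products population-wide, and the symmetry rule sets
    ``Y[j,i] = sym_weight * Y[i,j]`` for partners that failed while their
    mirror passed.  Iteration stops when no product's mean estimate moves by
    more than ``tolerance``.  Negative per-cell values are kept during
    iteration (they inform the population test) and clipped to zero only in
    the returned counts.
    """
    settings = settings or IterativeSettings()
    cube, names = _to_cube(X)
    n_cells, n, _ = cube.shape
    if n_cells < 2:
        raise ValueError("iterative method needs at least 2 cells")
    ids = pla_product_ids(names)

    if init is None:
        Y = np.zeros_like(cube)
    elif isinstance(init, pd.DataFrame):
        Y, _ = _to_cube(init.reindex(index=X.index))
    else:
        Y = np.array(init, dtype=float).reshape(cube.shape)

    rowX = cube.sum(axis=2)
    colX = cube.sum(axis=1)
    totX = cube.sum(axis=(1, 2))

    passed = np.zeros((n, n), dtype=bool)
    sym_filled = np.zeros((n, n), dtype=bool)
    p_adj = np.full((n, n), np.nan)
    degenerate_cells = 0
    converged = False
    iterations = 0

    for iterations in range(1, settings.max_iterations + 1):
        rowY = Y.sum(axis=2)
        colY = Y.sum(axis=1)
        totY = Y.sum(axis=(1, 2))
        denom = totX - totY
        ok = denom > 0
        degenerate_cells = int((~ok).sum())
        safe = np.where(ok, denom, 1.0)
        Y_new = cube - (
            (rowX - rowY)[:, :, None] * (colX - colY)[:, None, :]
            / safe[:, None, None]
        )
        Y_new[~ok] = Y[~ok]  # degenerate denominator: freeze that cell

        passed, p_adj = _population_test(
            Y_new, settings.t_test_mean_threshold, settings.alpha
        )
        Y_new[:, ~passed] = 0.0
        sym_filled = (~passed) & passed.T
        if sym_filled.any():
            Y_t = np.transpose(Y_new, (0, 2, 1))
            Y_new[:, sym_filled] = settings.sym_weight * Y_t[:, sym_filled]

        delta = np.abs(Y_new.mean(axis=0) - Y.mean(axis=0)).max()
        Y = Y_new
        if delta < settings.tolerance:
            converged = True
            break

    active = passed | sym_filled
    counts = np.clip(Y, 0.0, None)
    counts[:, ~active] = 0.0
    return ComplexPrediction(
        counts=pd.DataFrame(counts.reshape(n_cells, -1), index=X.index,
                            columns=ids),
        detected=pd.Series(active.ravel(), index=ids),
        pvalues_adj=pd.Series(p_adj.ravel(), index=ids),
        method="iterative",
        iterations=iterations,
        converged=converged,
        flags={"degenerate_cells": degenerate_cells},
    )


# ---------------------------------------------------------------------------
# LR method
# ---------------------------------------------------------------------------

def lr_predict(
    X: pd.DataFrame,
    nonproximal: pd.DataFrame,
    settings: LRSettings | None = None,
) -> ComplexPrediction:
    """Weighted-least-squares complex estimate from free-oligo counts.

    For each product i:j, regresses the observed count on
    ``A'_i * B'_j`` across cells with weights ``1 / (A'_i B'_j)``
    (heteroscedastic counts), tests the intercept one-sided against
    ``beta_cutoff``, BH-corrects across products, and for significant
    products returns ``Y = max(0, X - beta1 * A'B')`` per cell.
    """
    settings = settings or LRSettings()
    cube, names = _to_cube(X)
    n_cells, n, _ = cube.shape
    if n_cells < 3:
        raise ValueError("LR method needs at least 3 cells")
    ids = pla_product_ids(names)
    aprime, bprime = split_nonproximal(nonproximal)
    missing = [p for p in names if p not in aprime.columns or p not in bprime.columns]
    if missing:
        raise ValueError(f"non-proximal counts missing for proteins: {missing}")
    ap = aprime[names].reindex(X.index).to_numpy(dtype=float)
    bp = bprime[names].reindex(X.index).to_numpy(dtype=float)

    beta0 = np.full((n, n), np.nan)
    beta1 = np.full((n, n), np.nan)
    pvals = np.full((n, n), np.nan)
    fitted = np.zeros((n, n), dtype=bool)
    unreliable: list[str] = []
    negative_slope: list[str] = []

    for i in range(n):
        for j in range(n):
            x = ap[:, i] * bp[:, j]
            y = cube[:, i, j]
            keep = x > 0
            if keep.mean() < 1.0 - settings.max_dropped_fraction:
                unreliable.append(f"{names[i]}:{names[j]}")
                continue
            if keep.sum() < settings.min_cells:
                unreliable.append(f"{names[i]}:{names[j]}")
                continue
            xk, yk = x[keep], y[keep]
            med_y = np.median(yk)
            scale = (
                1.0 / settings.interaction_scale
                if np.median(xk) > settings.auto_scale_ratio * max(med_y, 1.0)
                else 1.0
            )
            exog = sm.add_constant(xk * scale)
            fit = sm.WLS(yk, exog, weights=1.0 / xk).fit()
            b0 = float(fit.params[0])
            b1 = float(fit.params[1]) * scale
            se0 = float(fit.bse[0])
            if not np.isfinite(se0) or se0 == 0:
                p = 0.0 if b0 > settings.beta_cutoff else 1.0
            else:
                t = (b0 - settings.beta_cutoff) / se0
                p = float(stats.t.sf(t, fit.df_resid))
            beta0[i, j] = b0
            beta1[i, j] = b1
            pvals[i, j] = p
            fitted[i, j] = True
            if b1 < 0:
                negative_slope.append(f"{names[i]}:{names[j]}")

    p_adj = np.full((n, n), np.nan)
    if fitted.any():
        p_adj[fitted] = bh_adjust(pvals[fitted])
    detected = fitted & (p_adj <= settings.alpha)

    counts = np.zeros_like(cube)
    for i, jj in zip(*np.nonzero(detected)):
        counts[:, i, jj] = np.clip(
            cube[:, i, jj] - beta1[i, jj] * ap[:, i] * bp[:, jj], 0.0, None
        )

    return ComplexPrediction(
        counts=pd.DataFrame(counts.reshape(n_cells, -1), index=X.index,
                            columns=ids),
        detected=pd.Series(detected.ravel(), index=ids),
        pvalues_adj=pd.Series(p_adj.ravel(), index=ids),
        method="lr",
        beta0=pd.Series(beta0.ravel(), index=ids),
        beta1=pd.Series(beta1.ravel(), index=ids),
        flags={"unreliable": unreliable, "negative_slope": negative_slope},
    )


# ---------------------------------------------------------------------------
# ensemble method
# ---------------------------------------------------------------------------

def ensemble_predict(
    X: pd.DataFrame,
    nonproximal: pd.DataFrame,
    lr_settings: LRSettings | None = None,
    it_settings: IterativeSettings | None = None,
) -> ComplexPrediction:
    """LR-initialized iterative estimate.

    Runs the LR method first and hands its per-cell complex matrix to the
    iterative method as the initial guess, steering the iteration toward a
    sensible region of the solution space.  If the LR output is identically
    zero this reduces to the plain iterative method.
    """
    lr = lr_predict(X, nonproximal, lr_settings)
    result = iterative_predict(X, it_settings, init=lr.counts)
    result.method = "ensemble"
    result.beta0 = lr.beta0
    result.beta1 = lr.beta1
    result.flags["lr_flags"] = lr.flags
    return result


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_detect(X: pd.DataFrame, alpha: float = 0.05) -> FisherResult:
    """Per-cell one-sided Fisher's exact test of PLA product enrichment.

    For each cell and product i:j, tests whether X[i, j] is enriched in the
    2x2 table (X[i,j]; other products of probe-A i; other products of
    probe-B j; everything else) against the hypergeometric null; the
    one-sided p-value is ``hypergeom.sf(X[i,j] - 1, total, rowsum_i,
    colsum_j)``.  P-values are BH-corrected across the product panel within
    each cell; degenerate margins give p = 1.  The population summary is the
    fraction of cells called positive per product.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    cube, names = _to_cube(X)
    n_cells, n, _ = cube.shape
    ids = pla_product_ids(names)
    cube = cube.astype(np.int64)

    row = cube.sum(axis=2)
    col = cube.sum(axis=1)
    tot = cube.sum(axis=(1, 2))

    M = np.broadcast_to(tot[:, None, None], cube.shape)
    K = np.broadcast_to(row[:, :, None], cube.shape)
    N = np.broadcast_to(col[:, None, :], cube.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.hypergeom.sf(cube - 1, M, K, N)
    p = np.where((tot[:, None, None] == 0) | (K == 0) | (N == 0), 1.0, p)
    p = np.clip(p, 0.0, 1.0)

    flat = p.reshape(n_cells, -1)
    p_adj = np.vstack([bh_adjust(flat[t]) for t in range(n_cells)])
    calls = p_adj < alpha
    return FisherResult(
        pvalues_adj=pd.DataFrame(p_adj, index=X.index, columns=ids),
        calls=pd.DataFrame(calls, index=X.index, columns=ids),
        positive_fraction=pd.Series(calls.mean(axis=0), index=ids),
        alpha=alpha,
    )
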