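# Methods

## The measurement being modelled

Prox-seq quantifies surface proteins and protein complexes on single cells
with pairs of DNA-barcoded antibodies.  A probe A and a probe B that end up
within the ligation distance of each other produce a proximity ligation
assay (PLA) product, identified as `i:j` by the two targeted proteins and
counted in unique molecular identifiers (UMIs).  Two probes bound to the two
members of a protein complex are always proximal; but any two probes can
also meet by chance, producing *proximity noise* that scales with the
product of the two proteins' abundances.  Separating complex-derived from
noise-derived PLA counts is the central analysis problem, and the reason a
generative simulator is useful: it provides ground truth that no experiment
can.

## Geometric simulator

Each cell is a sphere of radius `R` (default 5000 units = 5 µm).  Probes are
point particles:

1. For every protein `i`, the non-interacting probe-A count `A_i(t)` for
   cell `t` is drawn and that many points are placed uniformly on the
   sphere via `x = R√(1−u²)cosθ, y = R√(1−u²)sinθ, z = Ru` with
   `u ~ U[−1,1)` and `θ ~ U[0,2π)`.  Probe-B points follow the same
   placement.
2. For every ordered pair `i:j`, the complex count `c_ij(t)` is drawn and
   each complex contributes one probe-A point (label `i`) and one probe-B
   point (label `j`) at *identical* coordinates.
3. All A/B pairs with chord distance ≤ `d` (default 50 units = 50 nm) are
   candidate ligations.  The candidate list is shuffled uniformly and
   accepted greedily; a probe ligates at most once.  Accepted pairs are
   tallied into the PLA count matrix `X` by their protein labels; unmatched
   probes are the non-proximal ("free oligo") counts `A′_i`, `B′_j` that the
   modified assay measures.

Count draws are either the rounded configured means (`variance_mode:
"none"`) or negative-binomial with dispersion `n_NB` (mean `µ`, variance
`µ + µ²/n_NB`; default `n_NB = 1.5`, the average of per-product fits to
experimental Jurkat/Raji data).  Probe-B counts are tied to the probe-A draw
of the same protein, `B_i(t) = round((B_i/A_i)·A_i(t))`, so the two panels
of one protein covary as they do in cells.  Complex draws are independent of
the monomer draws; abundances of real proteins and their complexes are
likely correlated, which the model deliberately does not impose.

Optionally every probe carries an independent Bernoulli(`p_ns`) nonspecific
flag for its antibody; a PLA product is then classified both-specific /
one-specific / nonspecific from its two probes' flags.  Nonspecific binding
does not alter spatial placement — only provenance book-keeping.

### Closed-form noise model

The chord length `L` between two uniform points on the sphere has density
`L/(2R²)`, so `P(L ≤ d) = d²/(4R²)`.  If each probe could ligate repeatedly,
the noise count of product `i:j` would be `Binomial(A_i·B_j, d²/4R²)` with
mean `E[X_ij] = d²/(4R²)·A_i·B_j`.  Because the simulator (like, roughly,
the chemistry) consumes a probe on ligation, this mean is an upper bound on
the simulated noise; the bound is tight at low abundance.  Mean noise grows
quadratically in abundance and in ligation distance, which the
`noise_scaling_curve` diagnostic verifies by log–log regression (slope 2).

Note one subtlety: the bound is conditional on the realized probe counts.
Under NB variance the A/B coupling makes `E[A(t)·B(t)] > A·B`, so the
*unconditional* homotypic noise mean may exceed `d²/(4R²)·A·B`; the bound
statement is therefore checked in `variance_mode: "none"`.

### Randomness

One `numpy` `SeedSequence` per population; per-cell generators are spawned
substreams, so runs are bit-reproducible and enlarging `n_cells` leaves
earlier cells unchanged.  The KD-tree candidate search is required to
reproduce the brute-force O(N_A·N_B) pair list exactly (both are
implemented; equality is tested), so the spatial index is purely an
optimization.

## Inference methods

All methods consume the cells × products matrix `X` over a square panel.

**Protein abundance.** `Protein_i = Σ_l X_il + Σ_k X_ki`; the homodimer
product `i:i` is counted twice, once per molecule.

**Expected counts.** `E_ij = (Σ_l X_il)(Σ_k X_kj) / ΣΣX` per cell — the
random-ligation expectation given the margins; it preserves row and column
sums.

**Iterative method.** Per cell,

    Y_ij ← X_ij − (ΣX_il − ΣY_il)(ΣX_kj − ΣY_kj) / (ΣΣX − ΣΣY),

starting from `Y = 0`.  After each sweep a one-sided one-sample t-test
across cells (H₁: mean `Y_ij` > 1 UMI) with Benjamini–Hochberg correction
over the panel zeroes non-significant products population-wide, and the
symmetry rule sets `Y_ji = sym_weight · Y_ij` (default 1) for a partner that
failed while its mirror passed.  Iteration stops when no product's mean
moves by more than the tolerance (0.01 UMI) or after 100 sweeps.  Negative
per-cell values are kept during iteration — they carry information for the
population test — and clipped to zero only on output.  Cells whose residual
denominator `ΣΣX − ΣΣY` is non-positive are frozen for that sweep and
counted in a flag.

A structural caveat worth knowing: when the complex signal is confined to a
fully-connected block between two proteins and everything else is near
zero, the first-sweep residual of that 2×2 block is `±det/T` — positive on
one diagonal and negative on the other — so from a zero start the method
can only ever attribute signal to one of the two diagonals; it converges to
a partial fixed point whose residual has exactly independent margins, and
the remaining pair stays at mean ≈ 0.  This is the initialization
sensitivity that motivates the ensemble.

**LR method.** For each product, weighted least squares of `X_ij` on
`A′_i·B′_j` across cells with weights `1/(A′_iB′_j)` (counts are strongly
heteroscedastic in the noise level).  Cells with `A′_iB′_j = 0` have
undefined weight and are dropped; a product losing more than half its cells
is flagged unreliable and left undetected.  When the regressor's median
exceeds 10³× the response's the regressor is rescaled by 10⁻⁶ for
conditioning (slope and output are invariant).  A complex is called when the
intercept exceeds `β_cutoff` (default 1 UMI for simulated data; 10 is the
appropriate experimental setting) in a one-sided t-test, BH-corrected across
products; for called products `Y_ij = max(0, X_ij − β₁A′_iB′_j)` per cell.
If free-oligo counts were perfect proxies for non-interacting probe counts,
`β₁ = d²/4R²`; in practice `A′ < A` and the fitted slope is biased slightly
high (we observe ≈ +10% at abundance 1000).  Negative fitted slopes are
permitted but flagged — they occur when noise is negligible and the
regression is essentially unidentified, the regime where the LR method is
known to be unstable.

**Ensemble.** The LR method's per-cell complex matrix is passed to the
iterative method as its initial guess.  Starting near the LR solution
places the iteration in the attraction basin of a sensible fixed point,
which is exactly what the zero start cannot guarantee (see the caveat
above).  If LR calls nothing, the ensemble reduces to the plain iterative
method.

**Fisher's exact test.** Per cell and product, the 2×2 table
`(X_ij; Σ_{l≠j}X_il; Σ_{k≠i}X_kj; rest)` is tested one-sided for enrichment
(`p = hypergeom.sf(X_ij − 1, total, rowsum, colsum)`), BH-corrected across
the panel *within each cell*; degenerate margins give p = 1.  The
population summary is the fraction of positive cells per product, reported
without a hard detection cutoff (the diagnostics in this package use ≥ 5%
of cells where a set-valued answer is needed).

## Prediction score

    score = w₁·ΣPearson − w₂·ΣMean_deviation − w₃·ΣFPrate,
    (w₁, w₂, w₃) = (0.5, 0.4, 0.1).

One Pearson coefficient per true complex (true mean count > 0) between true
and predicted counts across cells, summed; a zero-variance prediction
contributes 0 and is flagged.  `Mean_deviation = |mean_pred −
mean_true|/mean_true` per true complex, summed.  `FPrate` is the fraction
of cells with a positive prediction, summed over products whose true count
is identically zero.  Single-cell correlation is weighted highest because a
prediction can match bulk means while being useless per cell; false
positives get the smallest weight because all methods assign only trace
counts to them.

## Randomized benchmark scenarios

Eight scenario cells: four classes × two signal-to-noise regimes, with 100
random replicates per cell at full scale (reduced-replicate sweeps are used
in routine checks; the class structure is unchanged).  Classes (3-protein
panel): *only-heterodimer* (`c_12, c_21 > 0`), *only-homodimer*
(`c_11, c_22 > 0`), *one-overabundant-protein* (protein 3's monomer mean
10× the others, heterodimer pair present), *multiple-dimers* (five
simultaneous complexes).  Monomer and homodimer means are drawn uniform on
[0.5, 2]× their base; heterodimer means triangular (min 0.5×, mode 1×, max
2×) — ranges chosen to reproduce the qualitative shapes of the reference
samplers, configurable in `ScenarioSpec`.  After drawing, complex means are
rescaled so total complex abundance is exactly 10× total monomer abundance
(high SNR) or 0.1× (low SNR); the low regime also raises the monomer scale
10-fold (base 1000 vs 100 UMIs) so proximity noise genuinely dominates.

Per configuration the benchmark simulates, runs each method and scores it
against the drawn ground truth.  Method robustness is summarized by the
median and the variance of the scores pooled across the whole sweep — the
distribution a violin plot of all runs would show — and, for finer
inspection, `summarize_benchmark` reports medians and variances per
scenario cell.

## Calibration diagnostics

`ppc_statistics` compares an observed and a replicated table per feature by
coefficient of variation and by the Mann–Whitney U statistic scaled to
[0, 1] (`U/(n₁n₂)`; 0.5 = indistinguishable, ties mid-ranked).
`fit_nb_dispersion` maximizes the NB likelihood per feature over
`log n_NB` with the mean fixed at the sample mean; under-dispersed features
(variance ≤ mean) are censored at `n_NB = 10⁴` (the Poisson limit) and
constant features flagged degenerate.

## What the simulator does and does not capture

Captured: quadratic abundance/distance scaling of noise, single-use probe
competition, NB overdispersion and the induced positive correlation between
PLA and free-oligo counts, nonspecific-binding provenance classes.  Not
captured: probe diffusion and steric effects, protein size, higher-order
complexes, correlated monomer/complex abundances, read-level UMI
collapsing, the mRNA modality, heterogeneous cell populations (all
predictors assume a homogeneous population; cluster first).  Passing tests
therefore demonstrate correctness of the methods *under the geometric
model*, not fidelity to any particular experimental dataset.

## Problem sizes used in routine checks

The shipped test-suite and the acceptance script run reduced but
statistically adequate sizes, chosen once: Monte-Carlo geometry at 10⁶
pairs; the scaling grid {250, 500, 1000}×{25, 50, 100} at 500 cells per
point; null-safety at 20 seeded repeats of 100 cells; the randomized
benchmark at 10 (tests) or 5 (acceptance script) replicates per scenario
cell of 100 cells each.  The full 100-replicate sweep is available through
`ScenarioSpec(replicates=100)` or `proxsim benchmark --reps 100`.
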