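# Methods

## Model and assumptions

`greynet` treats GRN inference as two stacked questions. First, *which
trajectories move together?* — answered by grey relational analysis
(GRA), a shape-similarity measure designed for systems with partially
unknown structure, computed over adaptive windows so that associations
may strengthen and fade over time. Second, *which of those associations
are temporally directed?* — answered by Granger-style feature selection
in a lagged multivariate regression: a regulator is a gene whose past
improves the prediction of the target beyond everything else's past.
The method assumes regularly sampled time series without missing values
(missing data are rejected, not imputed), at least three timepoints per
replicate series, and regulation that manifests within `d` sampling
intervals.

## Stage 1: dynamic grey association

For a target gene the pipeline (per replicate block):

1. normalises every gene's series,
2. takes first differences of the target,
3. tiles the difference axis with windows whose lengths follow the
   entropy-ratio recurrence `L_{i+1} = round(E_i / E_{i-1} * L_i)`
   clamped to `[L_min, L_max]`, where `E_i` is the Shannon entropy
   (bits) of the softmax of the absolute differences inside window *i*,
4. computes the grey relational grade of every other gene inside each
   window (extrema pooled across all comparative genes and in-window
   positions), and
5. averages grades over windows (unweighted) and then over blocks.

Decisions taken where the procedure is genuinely open:

* **Normalisation** (default per-gene z-score per block) precedes the
  residuals; raw expression scales would make residual pooling across
  genes meaningless, and GRA practice always normalises. `minmax` and
  `none` are available. Under z-scoring the association matrix is
  invariant to per-gene affine rescaling (tested to 1e-10).
* **Bootstrap of the recurrence.** The entropy recurrence is circular
  (the current window's length would need its own entropy). Entropies
  are therefore computed on *completed* windows only, and the
  pre-history entropy is set to `log2(L_init)` — a maximum-entropy
  prior meaning "no adjustment until evidence".
* **Windows sample values, schedule lives on differences.** A window
  `(s, L)` on the difference axis samples the normalised expression
  values at timepoints `s+1 .. s+L` (the endpoints of the differences
  it contains).
* **Stride** equals window length (consecutive, non-overlapping tiling);
  trailing points shorter than `L_min` form a final short window when at
  least two remain, and a lone trailing point joins the previous window.
* **Degenerate cases.** A window where all residuals are zero scores
  ξ ≡ 1 (the limit of the coefficient as residuals vanish); a zero
  previous entropy keeps the window length unchanged instead of
  dividing by zero.
* **Defaults.** ρ = 0.5 (the conventional distinguished coefficient,
  exposed as `--rho`), `L_init = max(3, round((n−1)/5))`, `L_min = 2`,
  `L_max = n−1`, rounding half-to-even. Extrema pooling is per-window
  by default; `--pool-extrema global` pools across all windows of a
  target.

## Stage 2: Granger regression

The lagged design for target *y* stacks, per replicate block and per
usable timepoint *t*, the response `y[t]` against columns
`regulator_k[t−l]` for lags `l = 1..d` (default `d = 2`); rows never
span block boundaries. Autoregressive self-lags are included in the
design — standard Granger practice, so regulator importances are judged
*beyond* the target's own history — but excluded from edge scores
(`--no-self-lags` disables them).

The tree-ensemble split criteria (variance reduction, gradient-statistic
gain) are exactly the documented objectives of scikit-learn's
`RandomForestRegressor` and xgboost's `XGBRegressor`; the package
delegates those fits and consumes impurity importances / total gain,
averaged over `n_repeats` (default 10) reseeded fits. Lasso/ridge fits
standardize predictor columns and use |coefficient| as importance; the
penalty defaults to 5-fold cross-validation over a logarithmic grid
(`10^-4 .. 10`) unless `--lambda` is given. Constant responses or
columns yield zero importances, never errors.

Per-target weight columns are rescaled to sum to one (standard for
importance-based GRN rankers) so high-variance targets cannot dominate
the global ranking. The combination with the association matrix is an
element-wise **product** — monotone in both factors, zero-preserving,
ranking-semantics-preserving; `regression_only` and `dga_only` modes
reproduce the ablation arms, and `--dga-topk K` offers association-based
candidate pre-filtering as an alternative coupling. Directions for a
binary network come from the support rule (weight above threshold one
way but not the other → directed edge; both ways → mutual edge); with
lasso and threshold 0 this is exactly the support-based reading.

## Evaluation

AUROC uses the Mann–Whitney formulation with midrank tie handling;
AUPRC is step-wise average precision (no trapezoidal interpolation).
Gold pairs absent from a ranking are appended below all ranked pairs as
lowest-confidence predictions (configurable). The trial comparison is
the *signed-rank* (paired) Wilcoxon test — the ablation compares the
same trials with and without the association factor — exact null for
n ≤ 25, continuity-corrected normal approximation beyond. MCC and
accuracy at a user-chosen cutoff are provided as secondary helpers.

## Synthetic data

The generator emulates the shape of the public in-silico benchmark:
directed networks of 10–100 genes without self-loops (Erdős–Rényi by
default, an out-hub topology optionally), edge strengths uniform on
±[0.5, 1.0], and replicate series of 21 timepoints. Dynamics:

* **var1** (primary): `x_t = A x_{t−1} + ε`, `ε ~ N(0, noise_sd²)`,
  with `A` the transposed strength matrix plus a self-decay diagonal
  (0.5), rescaled to spectral radius 0.9 — strong but stationary
  signal; with noise_sd = 0.1 the lag-1 signal-to-noise is ≈ 5.
  Granger-style inference is provably consistent here, so the causal
  half of the pipeline *must* recover the support. If a sampled network
  is nilpotent (a DAG with no self-loops has spectral radius 0), the
  self-decay diagonal guarantees a nonzero radius to rescale.
* **hill_ode**: saturating Hill kinetics
  `dx_i/dt = Σ_parents β·hill(x_p) − γ·x_i` (activation uses the
  increasing Hill curve, repression its complement; h = 2, K = 1,
  γ = 0.5, constitutive leak 0.1), integrated by fixed-step RK4 with
  observation noise — a nonlinear surface for the tree regressors.

Trajectories are shifted by a single global offset to positive,
expression-like values (irrelevant under z-score normalisation).

What the generator does **not** emulate: mRNA/protein separation,
perturbation or knockout designs, kinetic-model fidelity of
GeneNetWeaver, measurement-platform artefacts, or unevenly spaced
sampling. Passing tests on this data therefore demonstrate correct
mechanics and causal recovery under idealised dynamics, not performance
on any particular experimental compendium.

## Problem sizes and numerical choices

The test and acceptance studies use 10-gene, density-0.15 networks with
5 replicate blocks of 21 timepoints (the size-10 benchmark shape) over
20 simulation seeds, and a 5-gene sparse VAR(1) with 200 timepoints for
exact support recovery (coupling ±0.6, self-decay 0.2, lasso penalty
0.3, support threshold 1e-8 — a regime where the lasso's exact-zero
sparsity coincides with the true parent sets across seeds). Oracle
comparisons run at ≤5 genes and ≤12 timepoints against literal
loop-based recomputations, at tolerance 1e-10. All randomness flows
from explicit integer seeds; reruns are byte-identical.

## Known limitations

* The entropy-adaptive schedule reacts only to the *target* gene's
  differences; regulator-specific timing is handled downstream by lags.
* On strongly autocorrelated data the lasso can admit correlated
  false positives at small penalties (shrinkage bias); cross-validated
  penalties rank well but do not guarantee exact support.
* The with/without-association comparison is dataset-dependent: on
  linear VAR(1) synthetic data the regression arm alone is often already
  near-ceiling, so the association factor does not measurably improve
  AUROC there; the ablation harness reports the paired comparison
  rather than asserting a direction.
* Single-cell data (dropout, pseudotime) are out of scope.
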