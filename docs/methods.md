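# Methods

## Generative model

Counts are simulated hierarchically. For gene *i*, cell *j*, plate *k*,
group *g*:

- base expression `μ_i ~ LogNormal(mean_log_mu, sd_log_mu²)` on the
  natural-log scale; for spiked DE genes the group-2 (or group-1) mean is
  multiplied by `2^de_log2fc`,
- plate effects `δ_ikg ~ LogNormal(−σ_p²/2, σ_p²)` i.i.d. per gene ×
  plate, so `E[δ] = 1` exactly,
- cell factors `θ_jkg ~ LogNormal(−σ_t²/2, σ_t²)` i.i.d. per cell,
  independent of δ,
- conditional on δ and θ, `Y_ijkg ~ NB(mean = δ·θ·μ, dispersion = φ_i)`,
  sampled as a gamma–Poisson mixture, independent across genes and cells,
- optional zero inflation: each count is independently replaced by 0 with
  a constant dropout probability.

A single `numpy` PCG64 stream seeded from `SimulationConfig.seed` is
consumed in a fixed order (cells per plate, DE spike-in, base means,
dispersions, plate effects, cell factors, counts, dropout), so a config is
a complete, bit-reproducible description of a dataset.

### Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 10,000 | genes simulated (benchmarks use 5,000; tests less) |
| `n_groups` × `plates_per_group` | 2 × 3 | confounded one-way design |
| `cells_per_plate_range` | [50, 100] | uniform draw per plate |
| `mean_log_mu`, `sd_log_mu` | ln 5, 1.5 | base expression spanning ~0.1–500 expected counts |
| `nb_dispersion` | 0.3 (median) | typical scRNA-seq overdispersion; per-gene `φ = 0.3·LogNormal(0, 0.5²)` |
| `sigma_plate` | 0.5 | sd of log δ; a per-gene plate CV of ~53% |
| `sigma_theta` | 0.3 | sd of log θ (library-size variability) |
| `de_fraction`, `de_log2fc` | 0 / 0.1, 1 | spike-in for power runs |

The base-expression, dispersion-spread and effect-size values are this
package's declared study conditions — chosen once to reproduce the
qualitative regime of plate-confounded scRNA-seq (order-of-magnitude error
inflation, restoration by summation) rather than to match any particular
dataset; all are exposed in `SimulationConfig`.

Scenario variants modify one knob each: `no_plate_effect` (σ_p = 0),
`half_plate_effect` (σ_p = 0.25; "halving the magnitude" is interpreted on
the log-scale sd, the natural strength parameter), `variable_libsizes`
(σ_t doubled to 0.6), `variable_cell_numbers` (cells/plate widened to
[20, 130]), `more_plates` (6 per group), `zinb` (dropout probability 0.2,
constant and mean-independent — the simplest zero-inflation mechanism;
mean-dependent dropout is not modelled).

### What the simulator does and does not emulate

It reproduces the *dependence structure* that matters for the statistical
claim: gene-specific multiplicative plate effects confounded with groups,
cell-specific scaling removable by normalization, NB counts. It does not
emulate gene–gene correlation, mean-dependent dropout, batch structure
above plates, cell subpopulations, or empirically calibrated mean/
dispersion relationships from a specific protocol. Passing benchmarks
therefore demonstrate the plate-effect mechanism and its remedy, not
performance on any particular real dataset.

## Pseudobulk and filtering

`sum_by_plate` sums counts over the cells of each plate (exact integer
conservation; plate order = first appearance). Low-abundance genes are
filtered on the **single-cell** matrix (mean count across cells < 1
dropped; a mean of exactly 1 survives), and the same kept-gene set is used
for the summed analysis so the two modes test identical genes.
`residual_df(n, p) = n − p` and refuses saturated designs — the quantity
at the heart of the problem: 298 claimed d.f. for 300 cells vs 4 real d.f.
for 6 plates.

## Normalization

Single-cell analyses use library sizes as effective library sizes (in the
generative model θ is a pure scaling, and the library size is its
sufficient estimate). Summed analyses use median-of-ratios size factors
(per-sample median of count/geometric-mean ratios over genes positive in
all samples), rescaled to geometric mean 1 and multiplied by the geometric
mean of the library sizes so CPM values stay on a familiar scale. Log-CPM
uses `log2((count + 0.5)/(L + 1) · 1e6)`.

## Moderated linear-model engine

Per gene, OLS on log-CPMs gives residual quarter-root variances; a LOWESS
(span 0.5, 3 robustness iterations) of sqrt residual sd against average
log2 count forms the mean–variance trend; each observation's fitted
log-count is mapped through the trend and the inverse fourth power becomes
its precision weight (boundary-clamped outside the fitted range). Weighted
least squares is solved per gene by batched normal equations. Residual
variances are squeezed by fitting a scaled inverse-chi-squared prior
(d0, s0²) via moment matching of log s² against the log-F distribution
(digamma/trigamma inversion, Newton on the trigamma inverse); when the
observed spread of log-variances does not exceed the chi-squared sampling
spread the prior is degenerate (d0 = ∞) and all posteriors equal s0².
Moderated t-statistics use d0 + residual d.f. (normal when d0 = ∞);
p-values are two-sided throughout, and BH step-up is the multiple-testing
adjustment wherever an FDR threshold is quoted.

## NB GLM engine

GLMs with log link and per-sample offsets (log effective library sizes)
are fitted by Fisher scoring with vectorized per-gene step-halving;
convergence at relative deviance change < 1e−8 or 100 iterations;
coefficients clamped to [−30, 30], which parks all-zero genes at the lower
bound with zero deviance. Deviance uses the saturated-model convention
with 0·log 0 = 0; dispersions below 1e−8 switch to the Poisson limit. The
hot elementwise loops (means/deviances, working weights, log-likelihoods)
are numba-compiled; linear algebra stays in NumPy.

Dispersion is estimated by maximizing the Cox–Reid adjusted profile
likelihood — the profile log-likelihood at the φ-specific MLE of β minus
½ log det of the Fisher information — over φ ∈ [1e−8, 10]: a 21-point
log-spaced grid pass brackets the optimum, then golden-section search
refines to 1e−4 relative tolerance (ties collapse toward the lower end, so
underdispersed genes land on the bound). Two estimators share that grid
pass:

- **gene-wise (tagwise)**: each gene maximizes its own APL; consumed by
  the LRT, which tests the deviance difference of nested fits against
  chi-squared at fixed per-gene φ with no information sharing. With fewer
  than 10 residual d.f. the LRT emits a `LowReplicationWarning` — per-gene
  dispersions cannot be stably estimated from, say, six plate sums, which
  is why the quasi-likelihood engine is preferred there.
- **trended**: genes are grouped into equal-occupancy average-log-CPM bins
  (up to 10), each bin maximizes the *summed* APL of its genes, and log
  dispersion is interpolated across bin centres. Pooling the likelihoods
  avoids the downward bias of smoothing noisy gene-wise maxima at few
  residual d.f. (smoothing log-MLEs from 4-d.f. fits underestimated the
  trend by ~18% in our checks against the reference implementation). A
  plain LOWESS smoother of gene-wise estimates remains available as
  `trend_dispersions` for exploratory use.

The quasi-likelihood F-test consumes the **trended** dispersion: the
gene's quasi-dispersion is its residual deviance over the residual d.f.,
the quasi-dispersions are squeezed with the same log-F moment matching as
the linear engine's variances (yielding a prior d.f. d0), and the
coefficient is tested with F = (deviance difference / 1) / squeezed
quasi-dispersion on (1, residual d.f. + d0) degrees of freedom. Feeding
the QL test gene-wise MLE dispersions instead would drive every
quasi-dispersion to ≈1 and collapse the F-test into an overconfident LRT,
which is why the engine pairing (LRT ↔ tagwise, QL ↔ trended) is fixed in
the benchmark harness. Robust (winsorized) EB estimation is not
implemented; squeezing is non-robust.

## Evaluation harness

`run_benchmark` iterates scenario × engine × mode cells: simulate, filter,
(optionally) sum, normalize, test, score. Per-iteration seeds derive from
the root seed via `SeedSequence([seed, scenario_index, iteration])`, so any
cell is independently reproducible. Observed error rates (proportion of
null genes with p < α) are aggregated as geometric means with the standard
error computed on log rates; a zero rate is replaced by half a reciprocal
gene count before logging (continuity correction). Observed FDR (fraction
of BH-rejections that are truly null; defined 0 when nothing is rejected)
and TPR at fixed FPR are averaged arithmetically. ROC curves sweep unique
p-values with ties grouped, endpoints (0,0)/(1,1) appended, and are
interpolated linearly when read at a fixed FPR.

Benchmark problem sizes: 5,000 genes × 10 iterations for the headline
numbers (`scripts/acceptance.py`, `tests/test_acceptance.py`), 1,000–2,000
genes for examples and the no-plate-effect calibration suite — sizes
chosen to keep Monte-Carlo error well below the effect sizes being
demonstrated (the error-rate contrast is ~60×).

## Numerical and design choices

- One-way designs are treatment-coded (intercept + indicator), contrast =
  the group-2 coefficient; NB log2FC = β/ln 2.
- Nestedness of LRT designs is verified by projection; identical model
  spaces return statistic 0, p = 1.
- `bh_adjust` delegates to statsmodels' `fdr_bh`; the tests re-derive it
  by brute-force step-up.
- Engines are cross-validated against edgeR (coefficients, deviances, LRT
  p-values to ~1e−6; gene-wise dispersions to ~0.1%; trended dispersions
  to a few percent) and limma-voom (p-values within LOWESS-dialect
  differences) on deterministic fixtures in `tests/test_oracle_r.py`.
- All CLI commands are pure functions of (inputs, config, seed).

## Known limitations

- Only two-group one-way contrasts are wired into the harness and CLI
  (the fitting routines accept arbitrary full-rank designs).
- With the default noise levels and a |log2FC| of 1, the summed analysis
  at 3 plates/group has limited absolute power at genome-wide thresholds;
  per-iteration observed FDR is then a ratio of small counts and noisy
  across iterations (the reference implementation behaves identically).
- No robust EB, no TMM or deconvolution normalization, no mixed models,
  no intra-plate correlation modelling; batch structure above plates is
  out of scope.
- The QL F-test is the "legacy"-style deviance/d.f. quasi-dispersion; the
  newer bias-adjusted variant is not implemented.
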