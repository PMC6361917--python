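# Methods

## Model and estimator

`ctpr` estimates SNP effects for K quantitative traits by minimizing a
penalized least-squares objective. Genotypes are standardized so every
SNP column has mean 0 and sum of squares n_k, and phenotypes are
centered, so no intercept appears. The loss is the sum over traits of
(1/2n_k)‖y_k − X_k β_k‖²; traits may be measured on entirely different
cohorts, since they interact only through the penalty.

Two sparsity penalties are supported. The **Lasso** (λ₁Σ|β|) gives a
convex problem and the familiar soft-threshold coordinate update. The
**MCP** integrates a linearly decaying threshold,
λ₁∫₀^|β| (1 − x/(γλ₁))⁺ dx: coefficients below γλ₁ are shrunk, larger
ones are left unbiased. γ defaults to 3.0, the value conventionally
recommended for MCP regression, and is deliberately not tuned (tuning
it triples the grid for little benefit at these scales). The package
requires γ > 1; because the quadratic terms only add curvature
(λ₂·d ≥ 0), the per-coordinate problem is then always strictly convex
even though the full MCP objective is not.

The **cross-trait penalty** is a Laplacian quadratic,
(λ₂/2)[Σ_{k<k'}Σ_j a_kk'j(β_kj − β_k'j)² + Σ_kΣ_mΣ_j a_k(K+m)j(β_kj − ŝ_mj)²],
where ŝ_mj are fixed anchors built from external GWAS summary
statistics. Each unordered trait pair enters once; with that convention
the closed-form updates below are the exact stationarity points of the
objective, which a numerical-differentiation oracle in the test suite
verifies coordinate by coordinate. Adjacency coefficients a default
to 1 (no prior knowledge); per-pair/per-SNP overrides are accepted but
no estimation of adjacencies is implemented.

## Coordinate descent

For coordinate (k', j') with current estimates β̃, write
ζ̃ = (x_{k'j'}·r̃)/n_{k'} for the partial-residual correlation
(r̃ excluding the coefficient's own contribution),
ξ̃ = λ₂(Σ_{k≠k'} a β̃_kj' + Σ_m a ŝ_mj'), b̃ = ζ̃ + ξ̃, and
d = Σ_{k≠k'} a + Σ_m a (the anchor adjacencies belong in d: they add
curvature exactly like trait pairs). Then

* Lasso: β̂ = sgn(b̃)(|b̃| − λ₁)⁺ / (1 + λ₂d);
* MCP: β̂ = sgn(b̃)·γ(|b̃| − λ₁)⁺ / (γ(1 + λ₂d) − 1) when
  |b̃| ≤ γλ₁(1 + λ₂d), else b̃/(1 + λ₂d).

Residuals r_k = y_k − X_kβ_k are maintained incrementally
(r ← r − Δβ·x, O(N) per update, audited against full recomputation to
< 1e-8 over 10⁴ updates). A full cycle visits traits outer, SNPs in
file order inner; the algorithm then iterates on the active set
(nonzero coefficients) until quiet and re-verifies with a full cycle.
Convergence: the largest relative coefficient change over a full cycle,
|Δβ|/max(|β_old|, 1e-6), below `tol` (default 1e-3; the floor makes a
coefficient leaving exact zero register as a large change). Paths run
λ₁ from λ₁ᵐᵃˣ = max_{k,j}|x_kj·y_k|/n_k downward on a log grid
(default 50 points, ratio 0.01 — the usual path convention), each
solution warm-starting the next. For the convex Lasso, warm- and
cold-started solutions agree to 1e-6; for MCP the warm-started path
*defines* the estimator and cold-start comparisons are not meaningful.

## Blocked update schedule

`partition_scheduler` reproduces, deterministically and in one process,
the update-order contract of a distributed fit: P SNPs are split into q
disjoint subgroups (round-robin over genomic order by default, which
spreads nearby — hence correlated — SNPs across subgroups; a contiguous
`chunk` strategy is available), and subgroups are grouped into s
ordered core-groups. Within a core-group every subgroup updates its
coefficients from the residual state frozen at the step start (sibling
updates are invisible until the merge); core-groups execute in order,
so later ones see earlier ones' fresh coefficients. With s = q, and
with q = 1, the schedule degenerates to sequential coordinate descent
and the implementation is bitwise identical to it, because both paths
share the per-coordinate arithmetic — the tests assert exact equality.
Smaller s trades convergence reliability for parallel width; the
default is s = q (exact). The contract is the update order, not the
transport: no actual message passing is performed.

## Tuning

(λ₁, λ₂) are selected by n-fold cross-validation (default 5) on the
primary trait only, minimizing the mean held-out MSE. Secondary-trait
data are used in full except for individuals who also carry the primary
phenotype: they inherit the primary sample's fold, so a held-out
individual's secondary phenotype never reaches the training side of its
own fold. A regression test constructs a worst case (secondary ≈
primary on the same individuals) and checks that disabling the rule
measurably deflates CV MSE. All fold-level standardization and
centering use training-fold statistics; validation genotypes are
transformed with the training means/scales. The λ₁ grid is shared
across folds (computed from the full data's λ₁ᵐᵃˣ, the usual CV-path
convention); the default λ₂ grid is {0, 0.01, 0.05, 0.1, 0.5, 1}.
Ties break toward larger λ₁ then larger λ₂ (sparser, smoother). Grid
points with any non-convergent fold fit are excluded from selection
with a warning. The final model is refit on all data at the selected
point, warm-started along the λ₁ path.

## Harmonization of summary statistics

External effects are first allele-aligned to the genotype panel's
counted allele (allele2 of the .bim file): matching records are kept,
swapped-allele records are sign-flipped, strand-ambiguous (A/T, C/G)
SNPs are excluded by default, and absent SNPs anchor at 0. The aligned
vector is then rescaled by the no-intercept least-squares slope of the
primary trait's marginal effects on the secondary effects, making that
slope exactly 1: a proportional rescaling keeps null SNPs at zero and
flips negatively correlated traits (e.g. a BMI-like helper trait for
height) into positive orientation. Covariate adjustment of marginal
effects is out of scope: callers pre-residualize phenotypes on
age/sex/PCs before computing or supplying summary statistics.

## Simulator

`simulate` draws per-SNP MAFs uniformly (default [0.05, 0.5]),
hard-call dosages binomial(2, MAF), and, for the C causal SNPs, effect
vectors β_j ~ N_K(0, D) with d_kk = h²_k/C,
d_lm = ρ_lm√(d_ll d_mm); non-causal effects are exactly 0. Phenotypes
are y = Xβ + ε with ε ~ N(0, 1 − h²_k) on standardized genotypes, so
var(y) = 1 and the genetic variance is h²_k by construction.
`shared_causal_fraction` < 1 draws the shared causals first and gives
each trait disjoint extra causals with independent N(0, d_kk) effects.
SNPs are independent by default; an optional AR(1) latent-Gaussian
block mode adds within-block LD for stress-testing the partition
scheduler. Real panels differ in MAF spectrum, pervasive LD, and
cohort structure, so simulation results here speak to the estimator's
mechanics, not to cohort-specific accuracy.

## Validation experiments and problem sizes

`validation.gain_replicate` runs the full pipeline on one simulated
two-trait study: primary cohort with genotypes, secondary cohort
contributing only marginal summary statistics, harmonization, warm
Lasso/MCP paths with and without the cross-trait penalty, selection by
held-out MSE on a tuning cohort (n = 500 by default), and scoring on an
untouched test cohort. The defaults (n = 2000, P = 1000, C = 50,
h² = 0.45/0.25, ρ = 0.75) describe a well-powered two-trait design. A
held-out tuning cohort stands in for per-replicate cross-validation to
keep replicate cost low; pilot comparisons showed the same selection
direction as 5-fold CV. The replicate-level λ₁ grid uses 12 points at
ratio 0.05 and the multi-trait λ₂ grid is {0.05, 0.2, 0.8}.

Two regimes matter scientifically. In the well-powered default
(n/C = 40 training samples per causal SNP, n > P), single-trait Lasso
already captures ~0.40 of the 0.45 heritable variance, so cross-trait
anchors have essentially no headroom and the measured gain is ~0. The
cross-trait penalty targets the opposite, biobank-like regime — many
causal SNPs relative to sample size (P > n, n/C ≈ 2-3), where
single-trait R² sits far below h². The underpowered configuration
(n = 400, P = 800, C = 160) preserves that structure at desk scale:
single-trait R² ≈ 0.13, and the summary-statistic-anchored model gains
≈ +0.013 absolute (~+10% relative; paired one-sided p ≈ 0.015 over 12
replicates), growing with ρ and λ₂. Both regimes are reported by
`scripts/acceptance.py` and exercised in the test suite.

## Numerical and design notes

* Missing genotypes are mean-imputed before standardization (keeps
  column sums exactly 0); monomorphic or all-missing columns are
  zeroed, flagged, and excluded from updates, their coefficients pinned
  at 0.
* Dosages count allele2 of the .bim file; the counted allele is
  recorded in coefficient output so downstream alignment is
  unambiguous.
* Phenotype/genotype joining is an inner join on sample id with the
  genotype file's order winning; unmatched samples are logged and
  dropped.
* Validation data are always standardized with training statistics
  (stored in the model file) to avoid leakage.
* Update order is deterministic (traits outer, SNPs in file order, or
  the partition order for blocked fits), so identical inputs give
  bitwise-identical outputs.
* Prediction R² of a zero-variance score is defined as 0 with a
  warning.
* The `cli_app` subcommands are thin wrappers; every command writes a
  `.run.json` audit file with the resolved configuration and seeds all
  randomness from a single `--seed`.

## Limitations

Continuous traits only (no binary-trait link); no covariate adjustment
inside the fit (pre-residualize); no VCF/BGEN or dosage input; no MAF
or imputation-quality filtering (assumed done upstream); adjacency
coefficients are taken as given, never estimated; the blocked scheduler
simulates — but does not perform — distributed execution.
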