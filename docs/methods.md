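# Methods

## Model and assumptions

Each gene is analyzed independently. For a gene with L isoforms observed in
J conditions (K_j samples in condition j, N = ΣK_j), the log-scale abundance
Y_jkl of isoform l in sample k of condition j follows the two-factor
split-plot linear mixed model

    Y_jkl = β^G + β_l^I + β_j^C + β_jl^IC + ρ_k(j) + ε_jkl,

with a whole-plot random sample effect ρ_k(j) ~ N(0, σ_ρ²) shared by all L
isoform measurements of a sample, and independent errors ε_jkl ~ N(0, σ_l²)
with isoform-specific variances. Marginally, a sample's length-L vector is
multivariate normal with mean X_jβ and covariance

    Σ = diag(σ_1², …, σ_L²) + σ_ρ²·11ᵀ   (unequal variance),

reducing to compound symmetry when all σ_l² are equal and generalizing to a
fully unstructured Σ (parameterized by its Cholesky factor). Fixed effects
are reference-coded: β_1^C = β_1^I = β_1l^IC = β_j1^IC = 0, giving J·L free
parameters for the full model, L for the isoform-only (Type 1 null) model
and J + L − 1 for the additive (Type 2 null) model.

Assumptions worth keeping in mind: log abundances are Gaussian with a
common covariance across conditions; samples are independent; each sample
has a complete L-vector (missing isoform values are an error, not imputed,
because the whole-plot structure is defined on complete vectors).

## Estimation

Fitting is by maximum likelihood (not REML): the screening tests are
likelihood-ratio tests between nested *fixed-effect* structures, which REML
likelihoods do not support. For fixed variance parameters the fixed effects
have the closed-form GLS solution β̂ = (Σ_jk X_jᵀΣ⁻¹X_j)⁻¹ Σ_jk X_jᵀΣ⁻¹Y_jk,
so the likelihood is profiled and only the variance parameters are
optimized.

Because the design block X_j is identical for every sample within a
condition, the exact profiled log-likelihood and its gradient are computed
from per-condition sufficient statistics (K_j, Σ_k Y_jk, Σ_k Y_jk Y_jkᵀ),
making each evaluation O(L³) independent of N. The gradient with respect to
the variance parameters follows from the envelope theorem (∂ℓ/∂β = 0 at the
GLS optimum): ∂ℓ/∂θ = ½·tr[(Σ⁻¹RΣ⁻¹ − N·Σ⁻¹)·∂Σ/∂θ], with R the residual
cross-product matrix at β̂.

Numerical choices:

* Working parameterization log σ_l² and log(σ_ρ² + f), with floor
  f = 10⁻⁸ × total sample variance, so σ_ρ² ≥ 0 without a hard boundary;
  log-Cholesky for the unstructured form.
* L-BFGS-B, relative log-likelihood tolerance 10⁻¹⁰, gradient tolerance
  10⁻⁷, at most 500 iterations; a bounded Nelder–Mead restart on failure.
* Initialization from the pooled within-condition residual covariance S:
  σ_ρ² ← mean off-diagonal of S (clipped below at f), σ_l² ← max(S_ll − σ_ρ²,
  0.05·S_ll); unstructured from the Cholesky of S plus ridge 10⁻⁶·tr(S)/L.
* The unstructured form is refused when L > 15 or N < L(L+1)/2 + p; with so
  many covariance parameters relative to samples its type I error inflates
  and the fit is poorly identified — use unequal variance instead.
* Non-convergent fits are returned with `converged=False`; their screening
  p-values are set to missing and excluded (with a logged count) from the
  BH denominator M.

Degenerate inputs: a gene needs L ≥ 2 isoforms (a single isoform admits no
splicing contrast) and every condition present in the data contributes at
least one complete sample vector; zero-variance isoforms in the simple
t-test path yield statistic 0 and p = 1 when group means are equal.

## Testing and OFDR control

Screening p-values come from χ² references with df = (J−1)·L (Type 1) or
(J−1)(L−1) (Type 2). Confirmatory per-isoform tests are Wald contrasts
(Cβ̂)ᵀ(C·Var(β̂)·Cᵀ)⁻¹(Cβ̂) on the full-model fit with a χ²_{J−1} reference,
or Welch t-tests (pooled-variance one-way ANOVA for J > 2). The Wald test
uses the plug-in covariance without small-sample degrees-of-freedom
correction and is anticonservative at small N (see the small-sample note
below).

The two-step decision rule: BH at level α over the M screening p-values;
for each of the R passing genes, control the FWER of its L confirmatory
tests at level Rα/M by Bonferroni, Holm, or Hochberg. The BH and FWER
procedures are implemented in-package with the standard tie-safe
adjusted-value formulations (the test suite cross-checks every decision
against statsmodels' independent implementations). Confirmatory p-values
are computed for all genes up front but consumed only for passing genes —
the decisions are identical and the pipeline simpler. When screening and
confirmation share the same data the independence condition behind the
OFDR proof does not hold exactly; the simulation engine is the empirical
check that control survives in practice.

Fold changes are reported as exp(d) for an estimated log-difference d ≥ 0
and −exp(−d) for d < 0, so the sign carries direction and the magnitude is
always ≥ 1. Log transform defaults to ln(a + 1) on FPKM/TPM (offset
configurable); fold changes are exp of log differences, consistent with the
natural log.

## Simulation engine

The generator emulates a two-condition isoform abundance study seeded by a
*template* gene: a full-model and a reduced-model parameter set (fixed
effects plus unequal-variance covariance). Per dataset of M genes, m0
null-hypothesis genes (NHGs) are drawn from the reduced model (identical
parameters for all NHGs); the remaining genes split evenly into *full*
false-null genes (every isoform differential) and *partial* false-null
genes, whose trailing isoforms l = ⌊(L+1)/2⌋+1…L are forced exactly null by
setting β_2l^IC = −β_2^C. Condition and interaction effects of false-null
genes are drawn independently and uniformly from intervals around the
template estimates b: [0, b] (small), [b/2, 3b/2] (medium), [b, 2b] (large),
mirrored for b < 0; baseline and isoform effects are copied unchanged.
Truth is recorded from the realized parameters: an isoform is truly
differential iff its realized mean difference is nonzero (continuous draws
make accidental zeros measure-zero; partial-gene zeros are exact by
construction).

Metrics per replicate: OFDR contribution V/R (defined as 0 when R = 0, the
standard FDR convention), power(I) = truly-differential isoforms rejected /
all truly-differential isoforms, and power(II) = false-null genes that pass
screening with *every* isoform decision correct (differential isoforms
rejected and null isoforms not rejected — the strict reading) / all
false-null genes. The simple-BH comparator runs Welch t-tests on all M×L
isoforms with one joint BH correction; a gene is "discovered" when any of
its isoforms is rejected.

Randomness: a master seed spawns one child stream per replicate through
`numpy.random.SeedSequence`, so runs are bit-for-bit reproducible and
replicates are independent.

### Template fixtures

Three built-in synthetic parameter sets (L = 5, 7, 11) stand in for
templates fitted to real tumor RNA-seq genes, whose source data is
external; users can regenerate templates from their own data with
`estimate_template`. Magnitudes were chosen once to be typical of log-FPKM
fits: baselines 1.5–3 on the log scale, isoform effects spanning roughly an
order of magnitude of relative abundance, condition effects 0.35–0.6
(≈1.4–1.8-fold), interactions ±0.3–0.6 with alternating signs (isoform
switches), error variances 0.3–1.1 growing for minor isoforms, and a
sample random-effect variance of 0.10–0.15. The L = 7 set carries the
weakest signals of the three.

What the generator does *not* emulate: abundance-dependent technical noise
and zero inflation, non-Gaussian heavy tails, between-gene parameter
heterogeneity among NHGs (an option to jitter is deliberately omitted;
identical reduced-model parameters for all NHGs), library-size or batch
effects, and correlation between genes. Passing simulations therefore
demonstrate the statistical behavior of the procedure under its own model,
not robustness to real-data artifacts.

## Study scales used by the shipped experiments

The packaged acceptance experiment uses M = 200 genes, the 7-isoform
template, n = 200 samples per condition, medium effects, α = 0.05 and
20 replicates per m0 ∈ {100, 180, 200} — a deliberately reduced scale that
keeps the full generate→fit→test→score loop cheap while leaving
Monte-Carlo standard errors around 0.004–0.01 (mixed m0) to ≈0.05 (all-null
m0, where V/R per replicate is almost Bernoulli). The calibration checks
use 200 genes for parameter recovery and 500 genes for the null-uniformity
KS test, both at n = 200; the small-sample check repeats the all-null run
at n = 50, where the χ² LRT reference is known to be anticonservative and
the realized OFDR may drift slightly above nominal (asserted only to stay
below 0.10).

## Known limitations

* No Kenward–Roger/Satterthwaite corrections or parametric-bootstrap LRT:
  at small N both the screening LRT and the Wald confirmation are somewhat
  anticonservative.
* No shrinkage of variance parameters across genes; very low replication
  per condition will fit poorly.
* The OFDR guarantee is proved under screening/confirmation independence,
  which shared data violates; control is verified empirically here.
* Normalization between samples is out of scope — abundances are taken as
  given.
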