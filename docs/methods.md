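# Methods

## The model family

All prediction models are variance-component mixed models over plot-level
records `y_ijk` (site *i*, line *j*, replicate *k*):

    y = μ·1 + Σ_t u_t + ε,   u_t ~ N(0, σ²_t K_t),   ε ~ N(0, σ²_ε I)

where each named term *t* contributes an observation-level positive
semidefinite kernel:

| term | kernel | meaning |
|------|--------|---------|
| `E`  | Z_E Z_E′ | IID site main effects |
| `L`  | Z_L Z_L′ | IID line main effects (baseline without markers) |
| `W`  | Z_E Ω Z_E′, Ω = W_s W_s′/Q | environmental-covariable regression; Ω measures similarity of site climates |
| `G`  | Z_L G Z_L′, G = X_c X_c′/p | genomic main effects (marker regression in kernel form) |
| `A`  | Z_L A Z_L′ | pedigree additive effects (tabular-method A) |
| `GE` | (Z_L G Z_L′) ∘ (Z_E Z_E′) | genomic × site reaction-norm interaction (Hadamard product) |
| `AE` | (Z_L A Z_L′) ∘ (Z_E Z_E′) | pedigree × site interaction |

The eight model names (`L+E`, `L+E+W`, `E+W+G`, `E+W+G+GE`, `E+W+A`,
`E+W+A+AE`, `E+W+G+A`, `E+W+G+A+GE+AE`) select subsets of these terms.

Kernel conventions. `G` column-centers the marker matrix and divides by the
marker count *p*; an uncentered mode and a VanRaden-2008 denominator
(2 Σ p_q(1−p_q), dosage scale) are selectable. Markers default to the
presence/absence {0,1} dialect of DArTseq-style panels, with {0,1,2} dosage
selectable. `Ω` standardizes covariable columns (population SD) and divides
by Q so its diagonal averages 1 and σ²_w is comparable to the other
components; raw-scale covariables are selectable, with an error on constant
columns. Whether covariables should be standardized before forming Ω is
genuinely open in this model family; standardization is the default because
it makes the variance scale interpretable. An optional minor-allele-frequency
filter in the marker reader is off by default. All kernels are stored dense
at observation level (O(n_obs²) memory, fine up to a few thousand plots);
internally each kernel carries a low-rank factor F with K = F F′ (and a
block-label for within-site interactions), from which the dense matrix is
materialised on demand.

## Fitting: eigenbasis Gibbs sampler

Each u_t is represented in the eigenbasis of its kernel restricted to the
training records: a thin SVD of F[train] gives K[train,train] = (U S)(U S)′,
so u_t = U S α_t with α_t ~ N(0, σ²_t I) and (U S)′(U S) = S² diagonal. The
whole coordinate block α_t then has an independent conjugate-normal
conditional and is updated in one vectorised draw; variances get scaled
inverse-χ² updates; μ has a flat prior. Eigenpairs with λ < 1e−10·λ_max are
dropped (PAV-coded G is rank-deficient). Within-site interaction kernels are
block-diagonal over sites and are decomposed block by block.

Priors: df = 5 for every variance; scales set so each term's prior mode
equals (training phenotypic variance × R²_t)/mean-diag(K_t), with residual
R² = 0.5 and the rest split equally among terms — the de-facto default of
this model family. Defaults: 12 000 iterations, 2 000 burn-in, thinning 5;
the cross-validation sweeps in `analysis/` and the acceptance script use
1 500–3 000 iterations because only posterior-mean predictions and variance
means are consumed and those stabilise quickly in the eigenbasis.
Variances (and μ) can be fixed, which turns the sampler into a draw from the
standard GBLUP conditional — the closed-form check in the tests.

Prediction uses the exact conditional mean of the (possibly singular) joint
Gaussian: u_test = K[test,train] K[train,train]⁺ u_train = (F[test] V) α_t
per draw. Two structural consequences, both tested: a line with a zero
relationship row receives only μ + site terms; and a site absent from
training receives exactly zero `GE`/`AE` contribution, so information reaches
an untested environment only through `W`, `g` and `a`. A consequence of
predicting with posterior means: a model whose prediction carries no
line-discriminating information (e.g. `L+E+W` for lines never observed)
yields *constant* within-site predictions; the Pearson correlation is then
undefined and is scored as 0 (no discriminating ability) rather than left
missing. Sites with fewer than 3 test records are reported missing.

## Stage-one phenotypic analysis

Per site: `y ~ check-group + (1|line) + (1|block)` by REML (statsmodels
variance components); checks are fixed groups and carry no line random
effect. Broad-sense heritability is line-mean based, H² = σ²_L/(σ²_L +
σ²_ε/r̄), with r̄ the mean replication of accessions in the p-rep design
(≈1.23 under the default 81/15/4 split).

Across sites: a factor-analytic model with sites fixed (plus site × check
cells), blocks-in-sites random, and genotype-within-site effects α with
Var(α) = (ΛΛ′ + Ψ) ⊗ G (2 factors, site-specific variances Ψ, genotype
relationship G). Estimation is EM/ECM on the restricted likelihood: G is
whitened through its eigendecomposition, the E-step solves the mixed-model
equations jointly for (β, δ, α̃) with a flat prior on β, and the M-step
updates σ²_δ and σ²_ε in closed form and (Λ, Ψ) by a few inner
factor-analysis EM steps on the expected genetic covariance — a
generalised-EM step, so the restricted log-likelihood is non-decreasing
(asserted; if a Ψ variance floor — a Heywood boundary — would break the
guarantee, the fit stops at the last accepted iterate). Convergence: |Δℓ| <
1e−5 after at least 10 iterations; non-convergence returns the best iterate
with a warning. Σ = ΛΛ′ + Ψ gives the genetic variance/correlation table
(variances on the diagonal); a two-site one-factor fit per site pair is the
saturated pairwise alternative, since it is genuinely unstated whether such
tables derive from the joint FA fit or from pairwise analyses. The biplot
rotates Λ to principal axes (SVD); the cosine between site vectors
approximates (and, because Ψ is excluded, slightly exceeds) the genetic
correlation, and vector length tracks the site's genetic variance, i.e. its
discriminating power.

## Prediction problems

* **CV1**: all records of a random 20% of accession lines masked everywhere
  (predicting never-observed lines); every record of a line shares a fold.
* **CV2**: a random 20% of accession plot records masked (sparse testing).
* **pairwise**: fit on exactly two sites' records with the test site masked.
* **leave-one-site-out**: all sites' records in the kernels, the held-out
  site's responses masked; its covariable row remains in W.

Accuracy is the within-site Pearson correlation between observed and
predicted test records (raw plot values by default; a line-mean mode is
provided), averaged with SD over replicates (50 random partitions by default
for CV1/CV2; the transfer schemes are deterministic single runs). Checks are
design infrastructure: never in test sets, never in accuracy computations.

## The synthetic-trial generator

The generator emulates the study conditions of a multi-site spring-wheat
panel: 803 accessions (tests and analyses run scaled down, 100–300 lines),
5 sites, a DArTseq-scale PAV panel, 5 growth-phase temperature summaries,
3 checks, and a p-rep augmented design with 81% of accessions once, 15%
twice, 4% three times per site and 6% of plots as checks (deterministic
rounding, so realized proportions are exact to one entry; replicates of an
entry land in distinct blocks). Phenotypes are drawn from the full
reaction-norm decomposition itself — each term from its stated multivariate
normal — so the fitted models are correctly specified and every recovery
test has an exact estimand. Zero-variance terms are identically zero.

Variance defaults are stated on the phenotypic scale and converted to kernel
units through each kernel's mean diagonal (PAV-coded G has mean diagonal
≈0.18, so its kernel-scale parameter is ≈5× the phenotypic target);
`SimTruth` records the kernel-unit values the models estimate alongside the
targets. Defaults — E 1.0, W 0.5, G 1.0, A 0.4, GE 0.35, AE 0.15, block 0.2,
residual 1.0 t² ha⁻², μ = 6 t ha⁻¹ — give per-site genetic variance ≈1.9,
H² ≈ 0.55–0.65 and an implied between-site genetic correlation ≈0.74, inside
the 0.4–0.85 range multi-site wheat yield trials show.

The pedigree is a two-generation genealogy from few founders (elite-nursery
relatedness: full sibs, half sibs, cousins). Markers are by default drawn
independently of the pedigree, so the G- and A-indexed effects are separable
and recovery of their variance split is well-posed; a `markers_from_pedigree`
gene-drop mode produces the more realistic family-structured panel, at the
price of making G ≈ A + Mendelian noise with no well-defined G/A split.
What the generator does **not** emulate: linkage disequilibrium and marker
redundancy, spatial field trend, check-specific G×E, missing data, or any
selection history — so passing tests demonstrate correctness of the
machinery under the assumed covariance structure, not robustness to the
model misspecification real trials carry.

## Known information limits (kept visible, not papered over)

Two recovery checks sit beyond what the stated design can identify, and the
corresponding tests are left failing by design rather than loosened:

* σ²_E and σ²_W are variances of effects realized at only 5 sites; the
  realized variance of 5 draws has ≈63% sampling SD, so no estimator hits a
  ±30% band in 8/10 replicates.
* the GE/AE (and to a lesser degree G/A) split: both interaction kernels are
  diagonal-dominated at line×site level, so their sum is recovered to a few
  percent while the split is prior-sensitive; refitting with a nearly flat
  prior moves the estimates little, confirming a likelihood (not prior)
  limit.

## Numerical choices

Seed handling: every operation is a pure function of its arguments including
the seed; the pipeline spawns per-stage seeds from one master seed via CRC32
of the stage name (all below 2³¹). PSD assertions tolerate eigenvalues down
to −1e−8·λ_max; kernel-set validation runs the full eigencheck automatically
only at desk scale (≤250 observations) and on demand otherwise. Yield is
t ha⁻¹ throughout; days and cm traits ride the same machinery unchanged.
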