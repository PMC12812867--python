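# Methods

## Scope and model overview

`mtmepred` predicts quantitative phenotypes from genome-wide SNP dosages,
NIR spectra, or a user-supplied relationship matrix, in four analysis
modes: uni- or multi-trait (UT/MT) crossed with uni- or multi-environment
(UE/ME). The predictive core is a fixed-architecture feed-forward network;
a closed-form GBLUP solver provides an algebraic oracle and baseline.

## Quality control

Markers are filtered in a fixed precedence: (1) monomorphic markers (all
observed calls identical), (2) call rate below 0.90, (3) minor allele
frequency below 0.05, where MAF = min(p, 1−p) and p = mean(dosage)/2 over
observed calls. Both thresholds are inclusive — a marker exactly at 0.90
call rate or 0.05 MAF is retained, because the filters remove values
strictly *below* the cut. Each removal is attributed to exactly one cause,
so QC counts always reconcile with the input/output dimensions. Remaining
missing dosages are mean-imputed per marker *after* filtering; imputed
values are fractional and used only as covariates and in G. For
multi-environment analyses, individuals lacking a complete record in any
requested environment are excluded (complete-case alignment) before
covariate assembly.

## Relationship matrices

- **Genomic:** `G = WW′ / (2 Σ pₖ(1−pₖ))` with `W = M − 2P`, allele
  frequencies estimated from the data itself. Because the columns of `W`
  are centred at the estimated frequencies, `G·1 = 0`: G is always
  singular by one dimension, which is why a jitter step precedes any
  Cholesky factorisation.
- **Phenomic:** `H = SS′/w` on column-standardised spectra (zero mean,
  unit variance with the population denominator n), zero-variance bands
  dropped with a warning. With this convention diag(H) averages exactly 1.
  Standardising per band rather than merely centring was a deliberate
  choice: it makes H scale-free across instruments and structurally
  parallel to G.
- **ensure_pd** adds diagonal jitter starting at 1e-6 and doubling until
  the Cholesky succeeds, erroring if the accumulated jitter would exceed
  1e-2 (such a matrix is not a plausible relationship matrix). Off-diagonal
  entries are never modified.
- **Cholesky convention:** `Q` is upper-triangular with `Qᵗ Q = G`. The
  feature matrix handed to models is `Z_G Qᵗ`, whose Gram matrix is
  `Z_G G Z_Gᵗ`.

## Covariate assembly

Records are ordered individual-major with environments in the
user-supplied order; the same ordering binds X and Y. For ME data the
design matrices are one-hot incidences for environment (Z_E), genotype
(Z_G) and their interaction (Z_GE, columns environment-major), and

```
X = [Z_E,  Z_G Qᵗ,  Z_GE (I_e ⊗ Qᵗ)]        (relationship input)
X = [Z_E,  Z_G R,   Z_GE (I_e ⊗ R)]          (raw input)
```

The interaction transform `I_e ⊗ Qᵗ` is the unique conformable completion
of the construction consistent with an interaction covariance of the form
σ² (I_e ⊗ G) under environment-major column ordering; this identity is
verified to 1e-8 in the tests. The Cholesky factor is computed once
globally (not per environment). Z_E keeps all environment columns
(one-hot without a dropped level): the network has no intercept
identifiability concern. Column standardisation is *not* applied here —
X stays exact linear algebra; scaling happens inside network training.

For UE data with a relationship input, X is simply `Qᵗ` (one record per
individual, Z_G = I), so `X Xᵗ = G`.

Note an intentional asymmetry for kernel-equivalent models: the individual
ordering chosen when factorising G rotates the Cholesky basis, so X itself
is order-dependent, but every Gram matrix — and therefore every
kernel/ridge prediction — is order-invariant. Tests assert the invariant
at the prediction level, not on raw X entries.

## The network

Architecture (fixed, by design not user-modifiable):

- three fully connected hidden layers, each of `round(2/3 · n_inputs)`
  units (half-up rounding, clamped at 1);
- the configured activation after each hidden layer, inverted dropout at
  rate 0.30 after each hidden layer during training;
- linear output layer with one unit per trait.

Training: X columns and Y columns are standardised with training-set
statistics (zero-variance columns map to 0); minibatch backpropagation for
exactly `epochs` epochs (no early stopping, no internal validation split —
the epoch count is a grid dimension and must mean what it says); the loss
(mean squared or mean absolute error, averaged over batch and outputs) is
multiplied by `loss_weight`, applied uniformly to every output head. For a
single trait the loss weight only rescales the gradient (it moves the
effective step size, not the optimum); under Adam even that effect is
nearly neutralised by the second-moment normalisation. The `metric` field
is monitoring-only and provably never changes predictions — grid seeds are
derived from the training-relevant fields only, so metric-only variants
train bit-identically.

Optimizers use fixed conventional step sizes: Adam (lr 1e-3, β₁ 0.9,
β₂ 0.999, ε 1e-8) and SGD with momentum 0.9 at lr 1e-2. Weights are
Glorot-uniform initialised. All randomness — initialisation, shuffling,
dropout masks — flows from `config.seed` through one NumPy generator, so
training is bit-reproducible; dropout is disabled at inference, so
prediction is deterministic. A non-finite loss aborts with the epoch
number. The implementation is a small self-contained NumPy network
(forward/backward passes are a few dense matmuls); at the problem sizes
this package targets, that is fast and keeps the fitted model fully
inspectable.

## Hyperparameter grid and summary

The default grid crosses activations {relu, tanh, sigmoid}, optimizers
{adam, sgd}, epochs {50, 100, 200}, batch sizes {32, 64}, losses {MSE,
MAE}, metrics {mse, mae}, and loss weights {1.0, 0.01} — 288 combinations.
Every level list is user-overridable. Each combination × repetition is
scored on a seeded 80/20 split shared across combinations within a
repetition, so combinations are compared on identical partitions; results
are independent of the worker count because every task's seed is a pure
function of (base seed, repetition, training-relevant config). Failed
combinations are recorded as missing, reported, and excluded from the
ANOVA. Tuning uses 5 repetitions by default; the 50-cycle protocol is
reserved for final evaluation.

`resume_hyperparameters` tests each hyperparameter *marginally*: a one-way
ANOVA of prediction ability on its levels pooled over all other factors,
repetitions and traits, then Tukey HSD at α = 0.05 with an
insert-and-absorb compact-letter display (start from one group with all
levels; for each significant pair split the offending group in two; drop
groups absorbed by supersets; letter surviving groups from the
best-performing level down — this canonical ordering makes letters
invariant to level input order). A full factorial ANOVA is intentionally
out of scope: the marginal view matches the per-factor bar charts the
summary produces. Ranking of combinations is total and deterministic:
mean prediction ability descending, then mean MSE ascending, then the
configuration string.

## Cross-validation and model comparison

The evaluation protocol draws `cycles` (default 50) independent random
splits into disjoint 80% training / 20% testing subsets. Splitting is at
the **individual** level: in ME data all environment records of an
individual travel together, otherwise the same genotype would appear on
both sides and leak. Membership is a pure function of the sorted
individual ids and (base seed, cycle) — shuffling input rows changes
nothing. Scores are the Pearson prediction ability and MSE per cycle and
trait; cycles with training failures or undefined correlations (constant
predictions) are recorded as missing and the effective cycle count is
reported alongside the means. `compare_models` refuses to compare runs
with different split seeds or cycle counts, then applies the same
ANOVA + Tukey machinery per trait. Tukey HSD already controls the
family-wise error within a trait; no further correction is applied across
traits.

## GBLUP oracle

The univariate mixed model y = 1μ + Z_env β + Z_g g + Z_ge g_ge + ε with
g ~ N(0, σ²_g G), g_ge ~ N(0, σ²_ge (I_e ⊗ G)), solved from Henderson's
equations at *supplied* variance ratios λ = σ²_ε/σ²_g (and λ_ge). No REML:
the solver exists for algebraic verification and as a noise-floor/ceiling
baseline, not for variance-component inference. The environment block is
made identifiable by constraining the first level to zero. Fixed and
random effects are solved jointly in one system; the normal-equation
residual is recorded in the fit.

Key identity (used throughout): ridge regression with an unpenalised
intercept on the features `Z_G Qᵗ` with penalty λ‖a‖² equals the MME
solution with `ĝ = Qᵗ â`, because substituting g = Qᵗa turns λ gᵗG⁻¹g into
λ aᵗa. The identity also holds on row subsets via the kernel form
`G_test,train (G_train,train + λI)⁻¹`, which is why the cross-validated
"GBLUP" model is implemented as ridge on the prepared Cholesky features —
it is the same estimator, and the equivalence itself is a tested claim.

## Synthetic data generator

The generator emulates the statistical structure the models assume:

- **Genotypes:** dosages Binomial(2, pₖ), pₖ uniform in `maf_range`
  (default 0.05–0.5), half the markers mirrored to 1−p. No linkage
  disequilibrium, no pedigree structure.
- **Traits:** additive only. Marker effects are drawn jointly across
  traits with the requested genetic correlation; shared breeding values
  g = W·effects are rescaled to unit variance per trait. G×E is an
  independent additive deviation per environment (fresh marker effects,
  compound symmetry across environments — consistent with a σ²(G ⊗ I)
  interaction covariance), scaled to `gxe_variance_fraction` (default 0.2)
  of the additive variance. Environment main effects are N(0, 1²) in trait
  units. Residual variance is set from the *realized* genetic variance so
  each trait's per-environment heritability hits its target (0.6 by
  default) up to sampling error; h² = 0 produces pure noise around the
  environment means, h² = 1 is exactly noiseless. Realized heritabilities
  are recorded in the truth block.
- **Spectra:** 512 bands (the resolution of a common field NIR
  spectrometer) = smooth baseline + genetic signal + noise. The genetic
  part projects up to 200 latent additive scores (computed from the
  centred genotypes) through lightly smoothed random wavelength loadings,
  weighted by `spectra_signal_fraction` (default 0.8); the remainder is
  independent noise weighted by √(1−f²). The latent dimension matters:
  with too few components, the spectra-derived H estimates G so noisily
  that phenomic relatedness is lost even at high signal fractions. At
  f = 0 the spectra carry no genetic information at all.

All randomness flows from one seed through named substreams (genotypes,
effects, env, residual, spectra), so each layer regenerates independently.

What passing tests on these data do **not** show: robustness to linkage
disequilibrium, population structure, dominance/epistasis, non-Gaussian
residuals, genotype-environment correlation (as opposed to interaction),
or real NIR artefacts (scatter, baseline drift, water bands). Results on
simulated data are statements about the machinery, not about expected
accuracy on any real crop dataset.

## Problem sizes and numerical choices

Default test and acceptance runs use desk-scale problems — around 60–300
individuals, 100–600 markers, and networks trained 5–200 epochs — chosen
so the full verification suite exercises every code path, including the
50-cycle protocol, at interactive speed. Tolerances: symmetry 1e-8 on
read, Cholesky reconstruction 1e-8, covariance-preservation 1e-8, ANOVA
agreement 1e-10, save/load prediction round-trip 1e-6. Ties in ranking
break deterministically; degenerate inputs (all-constant vectors,
single-level factors, all-markers-filtered, non-PD matrices beyond the
jitter cap) raise explicit errors rather than propagating NaNs.

## Known limitations

- One relationship matrix per analysis; no additive+dominance+epistasis
  decomposition, no pedigree A-matrix, no single-step blending of pedigree
  and genomic information.
- The GBLUP solver takes variance ratios as given (no REML/MCMC) and does
  not extrapolate to individuals absent from G.
- VCF support covers biallelic SNPs only; multiallelic records are skipped
  with a warning.
- The network architecture is intentionally rigid; users wanting other
  depths/widths are outside this package's scope.
- Grid search is exhaustive by design — no random/Bayesian/successive-
  halving search.
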