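# Methods

## Model

All four models are Gaussian mixed models on one yield record per
line × environment,

    y = μ·1 + Σ_t u_t + ε,   u_t ~ N(0, K_t σ²_t),   ε ~ N(0, I σ²_ε),

differing only in which record-level kernels `K_t` enter:

| term | kernel | meaning |
|------|--------|---------|
| E | `Z_E Z_E′` | environment (year × farm × soil trial) main effect |
| L | `Z_L Z_L′` | non-genomic line effect (i.i.d. across lines) |
| S | `Z_S Z_S′` | soil-texture class main effect |
| G | `Z_L G Z_L′` | genomic main effect, `G = X_c X_c′/p` |
| G×E | `(Z_L G Z_L′) # (Z_E Z_E′)` | marker-by-environment interaction |
| G×S | `(Z_L G Z_L′) # (Z_S Z_S′)` | marker-by-soil interaction |

M1 = {E, L, G}; M2 adds G×E; M3 = {E, L, S, G, G×E, G×S}; M4 = M3
without G×E.  The Hadamard products are positive semidefinite by the
Schur product theorem; every constructed kernel is checked for
symmetry (1e−10) and PSD-ness (smallest eigenvalue ≥ −1e−8 × largest).

Marker processing for `G`: missing dosages imputed with the marker
mean, columns centered, and by default scaled to unit variance
(`scale=False` recovers the literal cross-product of centered codes;
`center=False scale=False` the raw `XX′/p`).  Monomorphic markers are
dropped when scaling.  With centering and scaling the mean diagonal of
`G` is ≈ 1, so variance components are on the phenotypic scale;
kernels are not trace-normalized by default (a `normalize` switch
divides each by its mean diagonal).

Assumptions worth stating: a single record per line × environment
(replicate plots are pre-averaged), homoscedastic residuals across
environments, i.i.d. soil effects even though only ~3 classes exist,
and additive marker effects only (no dominance/epistasis kernels).

## Inference

A conjugate Gibbs sampler.  Each kernel is eigendecomposed once per
fit, `K_t = Γ_t Λ_t Γ_t′` (eigenvalues below 1e−10 × max dropped), and
the effect reparameterized as `u_t = Γ_t α_t` with independent
coordinates `α_tl ~ N(0, λ_tl σ²_t)`.  Full conditionals are then
univariate Gaussian for every `α_tl` and for μ, and scaled-inverse-χ²
for every variance.  Missing phenotypes are redrawn each iteration
from the current linear predictor plus residual noise (data
augmentation), so masked records contribute no information but
receive posterior predictions; this keeps a single code path for all
cross-validation schemes.  A training-only closed-form BLUP solver
(`mme_oracle`) provides the independent cross-check: with variances
fixed and the intercept pinned at the training mean, the sampler's
posterior-mean predictions must agree with it up to Monte-Carlo error
(the Monte-Carlo s.e. is estimated by batch means over 20 batches of
the thinned draws, since the linear-predictor chain stays
autocorrelated when kernels overlap).

Priors: every variance carries a scaled-inverse-χ² prior with df = 5.
Scales are elicited from the observed phenotypic variance with an
R² = 0.5 split: the residual prior mode is `0.5·var(y)` and the T
random terms share the other half equally (mode `0.5·var(y)/T`).  All
of df, R², and per-term scales are overridable.  This shrinks
low-rank components (e.g. soil, with 3 levels; environment, with a
few dozen) a few percentage points toward the prior mode — visible in
the recovery experiment, where shares of low-rank terms land within
but near the edges of a ±5-point band.

Chain defaults: 12 000 iterations, 2 000 burn-in, thinning 5.  The
experiments and tests use shorter, documented chains (300–6 000
iterations) matched to their problem sizes.  Crude autocorrelation-
based effective sample sizes of the variance chains are reported but
not enforced.  Same seed ⇒ bit-identical results.

Numerical choices: kernels symmetrized as `(K + K′)/2`; a 1e−8 ridge
on the oracle's training covariance; degenerate inputs (constant
phenotype, all-monomorphic markers, empty CV00 training sets) raise
or flag explicitly rather than limping through.

## Cross-validation

CV2 shuffles records into 5 folds; CV1 shuffles lines; both default
to 10 replicates, replicate r seeded as `seed + r`.  CV0 holds out
each environment; CV00 additionally deletes every record, anywhere,
of the lines present in the held-out environment (the leakage check
is exhaustive).  Within each partition everything outside the
training set is masked before fitting.  Per-environment correlations
pool a replicate's folds; environments with n < 3 or degenerate
variance are excluded from `r_w` with a logged reason, as are |r| = 1
entries (infinite weight).  One consequence of fold pooling worth
knowing: the fold-complement environment means are slightly
anti-correlated with the fold deviations, so with weak line-level
signal the pooled CV1 correlation can sit near or below zero even
when per-fold correlations are positive.

## Synthetic trials

The generator emulates a five-year advanced-yield-trial program:
yearly cohorts of lines (default 797 lines, ~160/cohort), each tested
in that year's environments — per year, two silt-loam and two clay
environments at one farm and one fine-sand environment at another —
giving the unbalanced incidence of real programs; a `carryover`
fraction re-tests part of the previous cohort.  Markers are
independent biallelic dosages, Binomial(2, q) with q uniform on
(0.05, 0.95) (default p = 6000).  Effects follow the generative model
above: i.i.d. main effects, `g = X_c b` with i.i.d. marker effects,
and interaction deviations drawn per environment (and per soil) as
`Γ√Λ z` from the eigendecomposition of `G`, which induces exactly the
Hadamard covariance.  Defaults: μ = 50, total variance 100, shares
(E, L, S, G, G×E, G×S, R) = (45.7, 2.2, 12.5, 3.5, 10.9, 9.5, 15.7).

Two calibrations keep "truth" well-defined at finite size:

* **Exact variance scaling** — each record-level contribution is
  centered and rescaled so its realized variance equals the
  configured component exactly.  With 3 soil levels or 20
  environments, raw draws miss their nominal variance by tens of
  percent, which would make share-recovery claims meaningless.
* **Environment/soil orthogonalization** — soil is constant within an
  environment, so the soil-group means of the environment draw are
  residualized out before scaling; otherwise part of the realized E
  variance is formally indistinguishable from S variance.  No finer
  projections are applied: residualizing interaction draws against
  line means, for instance, would force each line's few interaction
  deviations to sum to ~0 and distort the model's correlation
  structure.

What the generator does **not** emulate: linkage disequilibrium or
family structure among lines (lines are unrelated, so `G` is
near-diagonal and between-line transfer is weak — synthetic CV1/CV00
correlations are accordingly much lower than in real breeding data,
where relatedness is strong), spatial field trends, replicate plots,
heteroscedastic environments, or weather covariates.  Passing tests
therefore certify the machinery — kernels, sampler, schemes, metrics
— under the stated generative model, not field-level realism.

## Validation experiments and problem sizes

* **Oracle battery**: 5 toy configurations (12–20 lines, 2 years,
  models M1–M4), ~5 masked records each, 6 000-iteration chains;
  every masked prediction within 3 batch-means Monte-Carlo standard
  errors of the closed-form BLUP.
* **Share recovery**: 200 lines, 5 cohorts, 20 environments, 3 soils,
  800 records, truth shares (45, 2, 12, 4, 11, 10, 16); M3 posterior
  shares within ±5 percentage points of truth, averaged over 3 seeds.
* **Scheme ordering**: 100 lines, 12 environments, one replicate of
  fivefold for CV2/CV1 and leave-one-environment-out for CV0/CV00,
  600-iteration chains, 10 seeds; mean r_w(CV2) ≥ mean r_w(CV1) and
  mean r_w(CV0) ≥ mean r_w(CV00).

These sizes are fixed reference choices — large enough for the
properties to be meaningful, small enough that the whole battery runs
in minutes on one CPU.

## Known limitations

* Shares of variance for terms with few levels (soil above all) are
  prior-sensitive; with 3 levels no sampler can pin σ²_S tightly.
* The sampler is single-chain; between-chain diagnostics are out of
  scope.
* No REML/frequentist fitter, no multi-trait models, no VCF/PLINK
  input (CSV only), no balanced-sample-size CV variants.
* Replication of the original study's numbers on its deposited
  dataset requires downloading that dataset and depends on prior and
  chain settings the original analysis did not report; the
  corresponding check runs only when the data are placed under
  `data/soybean_trials/`.
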