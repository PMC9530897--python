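# Methods

This note documents the statistical machinery in `pedgxe`: the models it
fits, the numerical choices behind them, what the synthetic breeding-program
generator does and does not emulate, and the known limitations.

## Setting

The package targets multi-environment yield trials from a drought breeding
program: paired stress / non-stress trials run every year, a deep pedigree
connecting the tested lines, long-term checks repeated across years, and the
practical prediction questions breeders ask — how well can we predict a
line's yield in an environment where it was not tested (CV2), a line never
tested anywhere (CV1), or an entirely new year (CV0)?

## Pedigree and the additive relationship matrix

The additive (numerator) relationship matrix `A` is built with the tabular
method in topological pedigree order: founders have `A_ii = 1`; a line `k`
with parents `(s, d)` has `A_ki = (A_si + A_di)/2` for previous lines `i`
and `A_kk = 1 + A_sd/2`.  Unknown parents are treated as unrelated,
non-inbred founders — the standard tabular-method rule.  Deep pedigrees can
be truncated at a configurable number of generations (default 7) counted
upward from the terminal (phenotyped) lines; ancestors beyond the horizon
are dropped and their nearest retained descendants re-declared founders.
The truncation is monotone: entries whose connecting paths fit within the
horizon are unchanged by deepening it.

If assembly leaves a (numerically) slightly indefinite matrix, 1e-8 jitter
is added to the diagonal.  The GCA matrices `A_P1`, `A_P2` are sub-matrices
of the full `A` over the distinct parent-1 / parent-2 identities of the
phenotyped crosses; lines whose parents cannot be resolved are reported and
excluded from the combining-ability models.

The test-suite oracle for `A` is a vectorised gene-dropping simulation:
founder alleles are dropped through the pedigree and `A` is estimated as
twice the identity-by-descent probability.  Because ~10^3 entries are
compared at once, the 3-sigma agreement bound is applied familywise
(Sidak-adjusted per entry) rather than per entry, where it would fail
almost surely for a correct implementation.

## Stage one: from plots to BLUEs

Each trial is modelled as

    y = mu + g_i + beta * DTF_c + r_j (+ b_k) (+ s_l) + e

with genotype fixed (BLUE extraction) or random (genetic variance and
BLUPs), replications random, incomplete blocks random for alpha-lattice
designs only, a season term only when a trial genuinely spans seasons
(logged per trial; trials here are within-season, so the term usually
drops), and the days-to-flowering covariate centred within trial, with
missing covariate values imputed at the trial mean (logged).  Records with
missing yield are dropped; trials without design/replication metadata or
with more than 20% missing yield are discarded before fitting.

Variance components are estimated by REML.  Rather than an
average-information/EM iteration, the REML log-likelihood (profiled over
the fixed effects) is optimised over log-variances with L-BFGS-B from two
starting points, with dense Cholesky algebra; at trial sizes (tens to a few
hundred plots) this is simpler and equally accurate, and the tests pin it
against a brute-force zooming grid search (relative error <= 1e-3) and
against balanced-design closed forms.  Log-variance bounds are +/- ~10
orders of magnitude around the phenotypic variance, so degenerate fits
(zero residual) land on the bound rather than diverging.

Outliers are flagged once per trial: externally studentized residuals of
the whitened model are referred to a two-sided t distribution and corrected
with the Bonferroni-Holm step-down over the trial's records; flagged plots
are set missing and the trial refitted a single time (one pass keeps the
procedure deterministic).  With fewer than two residual degrees of freedom
the test is skipped with a warning.

The combined stress/non-stress model adds a fixed treatment effect (coded
+/-1/2 so the genotype means average the two treatments equally) and
separate residual variances per treatment.

One BLUE per genotype x environment is exported, where an **environment is
a year x condition combination** — the analyses compute accuracy "within
each environment-stress condition combination", so combined analyses have
up to two environments per year.  When several trials produce BLUEs for
the same genotype x environment they are merged by inverse-variance
weighting.  Stage two uses the BLUEs unweighted by default; an
inverse-variance weighting hook is deliberately out of scope.

Generalised (Cullis) heritability per trial is `H2 = 1 - vbar / (2
sigma2_g)` with `vbar` the mean prediction-error variance of a difference
of two genotype BLUPs, computed from the PEV matrix of the
genotype-random fit; values are clipped to [0, 1] with a warning and a zero
genetic variance yields `H2 = 0` by convention.

## Stage two: multi-kernel models M1-M7

The BLUEs are modelled as `y = mu + sum_k u_k + e`, where each `u_k` is a
zero-mean Gaussian effect with covariance `K_k sigma2_k`:

| model | components |
|-------|------------|
| M1 | E + A |
| M2 | E + A + AxE |
| M3 | E + GCA1 + GCA2 |
| M4 | E + GCA1 + GCA2 + SCA |
| M5 | E + GCA1 + GCA2 + SCA + GCA1xE + GCA2xE + SCAxE |
| M6 | E + GCA1 + GCA2 + SCA + GCA1xE + GCA2xE + AxE |
| M7 | E + GCA1 + GCA2 + A + GCA1xE + GCA2xE + AxE |

Main-effect kernels are `Z K Z'` (`K = I` for the environment blocks,
`A` for the additive line effect, `A_P1`/`A_P2` for the parental GCA
effects); interactions are Hadamard products, e.g. `AxE = (Z_g A Z_g') #
(Z_E Z_E')` and `SCA = (Z_P1 A_P1 Z_P1') # (Z_P2 A_P2 Z_P2')`, with the
triple product `SCAxE = SCA-kernel # E-kernel`.  The Schur product theorem
keeps every interaction kernel PSD.  In M6/M7 the `AxE` term uses the
line-level `A` kernel (the same object as in M2), not a re-derived cross
kernel.  The environment enters as a random effect with its own variance
(not as fixed effects); the only fixed effect is the intercept.

Inference is Bayesian Gibbs sampling — the de-facto standard for
multi-kernel pedigree/genomic models — with scaled-inverse-chi-square
priors (df 5; scales set so each kernel component's prior mode is an equal
share of 50% of the training phenotypic variance, the residual taking the
other 50%, mirroring common multi-kernel regression defaults).  Each kernel
is eigendecomposed once (eigenvalues clipped at 1e-10) and the effects are
sampled in the eigenbasis, where all full conditionals are diagonal; a
naive full-covariance Gibbs sampler kept in the test suite confirms the
eigenbasis sampler on small instances.  Responses are centred and scaled
internally and everything is reported back on the kg/ha scale.  Defaults
are 12,000 iterations / 2,000 burn-in / thinning 5; cross-validation runs
use shorter chains (the acceptance experiments use 800-1,500 iterations at
their problem sizes, which reproduce the full-chain accuracies to well
within scoring noise).  Identical seeds give bitwise-identical summaries.

Masked responses (the prediction targets) are treated as missing data and
imputed each sweep, so kernels are built over training + testing records
jointly and prediction falls out of the joint covariance.  A known
consequence of reporting posterior means of variances from finite chains
on modest data: with few levels (e.g. ~25 environments) the posterior mean
of a main-effect variance sits noticeably above the true value — the prior
mode and the per-level estimation uncertainty both push upward.  The
parameter-recovery tests document this: all components of the M2/M5
recovery study land within +/-35% of truth except the environment main
effect variance in M2, which is ~40% high for exactly this reason.

## Cross-validation schemes

* **CV2** (incomplete trials): records are dealt into 5 folds; each
  genotype may be observed in some environments and masked in others.
* **CV1** (untested lines): genotypes are dealt into 5 folds; all records
  of a masked genotype are withheld together.
* **CV0** (novel year): leave-one-year-out; the training set excludes the
  target year in both conditions.

Training sets can be restricted to stress (S), non-stress (NS), both (CSN),
or crossed for CV0 (S->NS, NS->S: train on one condition excluding the
target year, predict the other condition in that year).  Fold membership is
derived by hashing `seed:replicate:key` (key = record, genotype, or year),
so testing partitions are identical across training compositions and
models.  Checks are treated like any genotype in fold assignment.

Per replicate, the predictions from all folds are pooled into one vector
and scored as the Pearson correlation between predicted and observed BLUEs
within each environment; environments with fewer than 3 scoreable records
are skipped (logged as NaN).  The weighted average uses weights
proportional to per-environment record counts, and the mean across
replicates is the reported predictive ability.  CV1/CV2 default to 10
replicates, CV0 is deterministic with one.

## The synthetic generator

`SimConfig` defaults emulate a drought breeding program at desk scale:
10 years x 2 conditions, ~120 crosses per cycle from 36 founders over 2
cycles, 5 long-term checks planted every year, other lines evaluated for 2
consecutive years, RCBD trials with 3 replications, base yield 4,500 kg/ha
with a multiplicative drought penalty of 0.45, and per-plot residual SDs of
~630 (non-stress) and ~1,100 kg/ha (stress) with a per-trial uniform
spread.  Genetic effects are drawn from the kernel model's own multivariate
normals using the true `A`, `A_P1`, `A_P2`; a genotype-by-condition
variance (`GxC`, covariance `A` within each condition) is the one term the
fitted models do not carry — it is the minimal mechanism that makes
same-condition calibration beat crossed calibration under CV0 while keeping
the two conditions genetically correlated.  Days-to-flowering is simulated
independently of genetic value with a known yield slope (30 kg/ha per day)
purely to exercise the covariate path.  The default variance levels were
calibrated once, via the per-trial heritability profile, so stress-trial
Cullis H2 spans roughly 0.3-0.9 and sits stochastically below non-stress —
the envelope reported for managed-drought programs.

What the generator does **not** emulate: marker-level genetic architecture
(no QTL, no Mendelian-sampling segregation variance — effects are drawn at
the line level from `A`), selection across cycles, weather or management
covariates, spatial field trends, and non-Gaussian yield noise (plot yields
are truncated at zero, which slightly censors the stress tail).  Passing
tests therefore show the *machinery* is right under the assumed covariance
structure, not that real drought data behave this way.

A structural finding from calibrating the cross-validation experiments,
worth recording: which scheme is hardest depends strongly on program
topology.  Leave-one-year-out (CV0) is only clearly the weakest scheme when
most lines are tested in a single year, checks are a small fraction of each
trial, and G x E dominates the additive variance; with multi-year lines and
a strong additive signal (as in the generator's H2-calibrated defaults),
novel-year prediction can rival CV2 — visible in the acceptance script's
default-configuration output.  Small environments also attenuate CV1/CV2
scores specifically, because pooling predictions from five fold-models adds
between-fold jitter within an environment.  The qualitative-findings
experiment therefore uses a G x E-dominant, single-year-entry configuration
with ~30-line environments.

## Numerical choices and degenerate inputs

* REML: log-variance parametrisation, L-BFGS-B, two starts, ftol 1e-12;
  variances bounded at ~1e-10 x phenotypic variance.
* Gibbs: eigenvalue clip 1e-10; divergent (non-finite) draws raise with the
  iteration index; effective sample sizes via initial-positive-sequence
  autocorrelation sums.
* Ties and ordering: factor levels and ids are sorted wherever an order is
  needed, making kernels and plans permutation-equivariant.
* Degenerate inputs that raise: all-masked responses, zero-variance
  responses, single-condition input to the combined model, CV0 with one
  year, empty training compositions, parent models with unresolved parents.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
pedigrees up to a few hundred lines, 150-600 stage-two records, 10 trial
pairs, 5-fold cross-validation with 1-2 replicates and reduced chains.
These sizes were chosen so the full pipeline (including the brute-force
oracles) executes in minutes on one CPU while leaving every qualitative
contrast statistically resolvable.

## Known limitations

* Stage two assumes homoscedastic residuals across environments; the
  heteroscedasticity handled in stage one is not propagated (no
  inverse-variance weighting of BLUEs by default).
* Single-trait only; no multi-trait or factor-analytic structures.
* Dense linear algebra throughout — intended for up to a few thousand
  records, not biobank scale.
* Posterior means of weakly-informed variance components are biased upward
  at small level counts (see stage two above); report proportions or use
  longer chains with caution when levels are few.
* The CV experiments' statistical power depends on the generator regime;
  the frozen configurations are documented in the acceptance tests.
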