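# pedgxe

Pedigree-based multi-environment prediction for plant breeding programs.

Breeding programs accumulate years of yield trials — paired managed-stress
and non-stress trials, long-term checks, and deep genealogies — but most
lines are only ever tested in one or two environments.  `pedgxe` implements
the full pipeline that turns such historical data into predictions of
untested line x environment combinations: additive relationship matrices
from deep pedigrees, two-stage mixed-model analysis of the raw trials,
a family of kernel-based genotype-by-environment models, and the
cross-validation schemes breeders use to judge them.  It is aimed at
quantitative geneticists and breeding-program analysts; a synthetic
breeding-program generator makes every stage runnable and testable without
access to proprietary trial data.

## The models

Stage one fits each trial with REML,

    y_ijkl = mu + g_i + beta * DTF + r_j + b_k + s_l + e_ijkl,

(genotype fixed for BLUEs, random for the Cullis heritability
`H2 = 1 - vbar_BLUP / (2 sigma_g^2)`), and exports one BLUE per genotype x
environment, an environment being a year x condition (stress / non-stress)
combination.

Stage two models the BLUEs with sums of Gaussian kernel effects,

    y = mu + sum_k u_k + e,        u_k ~ N(0, K_k sigma_k^2),

where the kernels are built from incidence matrices and pedigree
relationship matrices: environment blocks `Z_E Z_E'`, the additive line
effect `Z_g A Z_g'`, parental general-combining-ability effects
`Z_P1 A_P1 Z_P1'` and `Z_P2 A_P2 Z_P2'`, the specific-combining-ability
kernel `(Z_P1 A_P1 Z_P1') # (Z_P2 A_P2 Z_P2')`, and Hadamard (`#`)
interactions of each with the environment blocks, e.g.
`A x E = (Z_g A Z_g') # (Z_E Z_E')`.  Seven standard component sets are
registered as models M1-M7 (from `E + A` up to
`E + GCA + A + GCA x E + A x E`).  Fitting is by Gibbs sampling in the
kernel eigenbasis with scaled-inverse-chi-square priors; prediction of
masked records falls out of the joint covariance over training + testing
records.

Predictive ability is assessed under three schemes — CV2 (incomplete
trials), CV1 (untested lines), CV0 (leave-one-year-out) — with training
sets composed of stress, non-stress, combined, or crossed-condition
records, scored as the within-environment Pearson correlation between
predicted and observed BLUEs, weight-averaged by environment size.

## Worked example

```python
from pedgxe import (
    SimConfig, simulate_trials, simulate_pedigree, stage_one_blues,
    build_genealogy, additive_relationship, attach_parents,
    MultiKernelModel, McmcConfig,
)

cfg = SimConfig(n_founders=12, n_crosses=40, n_cycles=1, n_checks=4,
                years=5, seed=7)
pheno, truth = simulate_trials(cfg)          # plot-level trial data
blues, report = stage_one_blues(pheno)       # stage 1: REML -> BLUEs
print("plots:", len(pheno), "| BLUEs:", len(blues),
      "| trials dropped:", len(report))

genealogy = build_genealogy(simulate_pedigree(cfg))
A = additive_relationship(genealogy)
fit = MultiKernelModel.from_blues(
    attach_parents(blues, genealogy), "M2", A=A,
).fit(McmcConfig(iterations=4000, burn_in=800, thin=4, seed=1))
print(fit.summary())
```

prints

```
plots: 510 | BLUEs: 170 | trials dropped: 0
Multi-kernel model M2  (n=170, masked=0)
intercept (posterior mean): 2694
component    symbol post_mean   post_sd proportion ess
        E  sigma2_E 1.476e+06  6.99e+05      0.477 437
        A  sigma2_a 7.427e+05 2.313e+05      0.240 547
      AxE sigma2_aE 2.916e+05 8.171e+04      0.094 244
 residual    sigma2 5.852e+05 1.031e+05      0.189 554
```

The rows decompose the BLUE variance (kg/ha squared): year x condition
main effects carry ~48%, the pedigree additive effect ~24%, its interaction
with environments ~9%, with ~19% residual — the intercept sits at the
drought-penalised average of the stress and non-stress means.  Masking
records before fitting (`MultiKernelModel.from_blues(..., mask=...)`)
returns their posterior-mean predictions via `fit.predict_masked()`.

Cross-validation runs hang off the same objects:

```python
from pedgxe import make_cv_plan, run_cv

plan = make_cv_plan(blues, "CV2", "CSN", folds=5, replicates=10, seed=3)
result = run_cv(blues, ["M1", "M2"], plan, A=A)
print(result.summary())          # models x scheme/composition table
```

A thin CLI mirrors the library: `pedgxe simulate`, `pedgxe stage1`,
`pedgxe fit`, `pedgxe crossval` (see `pedgxe --help`).

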