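"""Stage one of the two-stage analysis: trial quality control, per-trial
mixed models, outlier flagging, BLUE extraction and Cullis heritability.

Raw multi-environment trial data arrive as a long-format table with one row
per plot (genotype x trial x replication).  Each trial is modelled as

    y = mu + g_i + beta * DTF_c + r_j (+ b_k) (+ s_l) + e

with genotype fixed (for BLUEs) or random (for the genetic variance and
BLUPs feeding the Cullis heritability), replications random, blocks random
for alpha-lattice designs, a season term only when a trial genuinely spans
seasons, and the days-to-flowering covariate centered within trial.  The
combined stress/non-stress model adds a fixed treatment effect and allows
separate residual variances per treatment.

Stage one emits one BLUE (with standard error) per genotype x environment,
where an environment is a year x condition combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._mixed import MixedModelError, RemlFit, reml, studentized_residuals

#: canonical long-format phenotype columns
PHENO_COLUMNS = (
    "genotype", "year", "season", "condition", "trial",
    "rep", "block", "design", "GY", "DTF", "PH",
)

STRESS = "stress"
NON_STRESS = "non_stress"


class StageOneError(ValueError):
    pass


# ---------------------------------------------------------------------------
# quality filtering


def quality_filter(
    pheno: pd.DataFrame,
    max_missing_gy: float = 0.20,
    trait: str = "GY",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials with missing design/replication metadata or too much
    missing grain yield (default threshold: 20% missing).

    Returns the surviving records and a report of dropped trials with
    reasons.  Raises if nothing survives.
    """
    reports = []
    keep_trials = []
    for trial, sub in pheno.groupby("trial", sort=True):
        reason = None
        if "design" not in sub.columns or sub["design"].isna().any():
            reason = "missing design metadata"
        elif "rep" not in sub.columns or sub["rep"].isna().any():
            reason = "missing replication metadata"
        else:
            frac = float(sub[trait].isna().mean())
            if frac > max_missing_gy:
                reason = f"missing > {max_missing_gy:.0%} ({frac:.0%} missing)"
        if reason is None:
            keep_trials.append(trial)
        else:
            reports.append({"trial": trial, "reason": reason})
    report = pd.DataFrame(reports, columns=["trial", "reason"])
    out = pheno[pheno["trial"].isin(keep_trials)].copy()
    if out.empty:
        raise StageOneError("no trials survive filtering")
    return out, report


# ---------------------------------------------------------------------------
# trial models


@dataclass
class TrialResults:
    """REML results for one trial (or the combined stress/non-stress fit)."""

    trait: str
    trial: str
    genotype_as: str                       # "fixed" | "random"
    genotypes: list[str]
    blues: pd.Series | None                # genotype -> estimated mean
    blue_se: pd.Series | None
    blups: pd.Series | None                # genotype -> BLUP (random fit)
    blup_pev: np.ndarray | None            # PEV matrix of genotype BLUPs
    varcomps: dict[str, float]
    resid_vars: dict[str, float]           # residual variance per group
    covariate_slope: float | None
    treatment_effect: float | None
    loglik: float
    reml: RemlFit = field(repr=False, default=None)
    data_index: pd.Index = field(repr=False, default=None)
    notes: list[str] = field(default_factory=list)

    @property
    def sigma2_g(self) -> float:
        if "genotype" not in self.varcomps:
            raise StageOneError("genotype variance requires a genotype-random fit")
        return self.varcomps["genotype"]

    def summary(self) -> str:
        lines = [
            f"Trial {self.trial} [{self.trait}], genotype {self.genotype_as}",
            f"  log-likelihood (REML): {self.loglik:.3f}",
            "  variance components:",
        ]
        for k, v in self.varcomps.items():
            lines.append(f"    {k:<10s} {v:12.4g}")
        for k, v in self.resid_vars.items():
            lines.append(f"    resid[{k}] {v:12.4g}")
        if self.covariate_slope is not None:
            lines.append(f"  covariate slope: {self.covariate_slope:.4g}")
        if self.treatment_effect is not None:
            lines.append(f"  treatment (stress) effect: {self.treatment_effect:.4g}")
        return "\n".join(lines)


class TrialModel:
    """Single-trial mixed model (statsmodels-style: construct, then .fit())."""

    def __init__(
        self,
        data: pd.DataFrame,
        trait: str = "GY",
        covariate: str | None = "DTF",
        genotype_as: str = "fixed",
        trial: str | None = None,
    ):
        if genotype_as not in ("fixed", "random"):
            raise ValueError("genotype_as must be 'fixed' or 'random'")
        data = data.copy()
        if trial is not None:
            data = data[data["trial"] == trial]
        trials = data["trial"].unique() if "trial" in data.columns else ["?"]
        if len(trials) != 1:
            raise StageOneError(
                f"TrialModel expects one trial, got {sorted(map(str, trials))}"
            )
        self.trial = str(trials[0])
        data = data[data[trait].notna()].copy()
        if data["genotype"].nunique() < 2:
            raise StageOneError(f"trial {self.trial}: fewer than 2 genotypes")
        self.data = data.reset_index(drop=True)
        self.trait = trait
        self.covariate = covariate
        self.genotype_as = genotype_as
        self.notes: list[str] = []

    # -- design construction ------------------------------------------------

    def _designs(self):
        d = self.data
        y = d[self.trait].to_numpy(dtype=float)
        genotypes = sorted(d["genotype"].unique())
        gidx = {g: j for j, g in enumerate(genotypes)}
        Zg = np.zeros((len(d), len(genotypes)))
        Zg[np.arange(len(d)), [gidx[g] for g in d["genotype"]]] = 1.0

        cols = []
        if self.genotype_as == "fixed":
            cols.append(Zg)            # cell-means coding: one column per genotype
        else:
            cols.append(np.ones((len(d), 1)))

        cov_col = None
        if self.covariate is not None and self.covariate in d.columns:
            cov = d[self.covariate].to_numpy(dtype=float)
            if np.isnan(cov).any():
                cov = np.where(np.isnan(cov), np.nanmean(cov), cov)
                self.notes.append(
                    f"{int(d[self.covariate].isna().sum())} missing "
                    f"{self.covariate} values imputed at trial mean"
                )
            cov = cov - cov.mean()
            if np.ptp(cov) > 0:
                cov_col = cov[:, None]
                cols.append(cov_col)

        X = np.hstack(cols)

        random_terms: dict[str, np.ndarray] = {}

        def add_factor(name, series):
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                return
            li = {v: j for j, v in enumerate(levels)}
            Z = np.zeros((len(d), len(levels)))
            Z[np.arange(len(d)), [li[v] for v in series.astype(str)]] = 1.0
            random_terms[name] = Z

        add_factor("rep", d["rep"])
        designs = set(d["design"].astype(str).unique()) if "design" in d else set()
        if designs & {"alpha-lattice", "alpha_lattice"} and "block" in d.columns:
            add_factor("block", d["rep"].astype(str) + ":" + d["block"].astype(str))
        if "season" in d.columns and d["season"].nunique() > 1:
            add_factor("season", d["season"])
        else:
            self.notes.append("single-season trial: season term dropped")
        if self.genotype_as == "random":
            random_terms["genotype"] = Zg

        return y, X, random_terms, genotypes, cov_col is not None

    # -- fitting ------------------------------------------------------------

    def fit(self) -> TrialResults:
        y, X, random_terms, genotypes, has_cov = self._designs()
        fit = reml(y, X, random_terms)

        blues = blue_se = blups = pev = None
        slope = float(fit.beta[-1]) if has_cov else None
        if self.genotype_as == "fixed":
            k = len(genotypes)
            blues = pd.Series(fit.beta[:k], index=genotypes, name="blue")
            blue_se = pd.Series(
                np.sqrt(np.diag(fit.cov_beta)[:k]), index=genotypes, name="se"
            )
        else:
            u = fit.blup("genotype")
            blups = pd.Series(u, index=genotypes, name="blup")
            pev = fit.blup_pev("genotype")

        return TrialResults(
            trait=self.trait,
            trial=self.trial,
            genotype_as=self.genotype_as,
            genotypes=genotypes,
            blues=blues,
            blue_se=blue_se,
            blups=blups,
            blup_pev=pev,
            varcomps={k: v for k, v in fit.varcomps.items()},
            resid_vars={"all": float(fit.resid_vars[0])},
            covariate_slope=slope,
            treatment_effect=None,
            loglik=fit.loglik,
            reml=fit,
            data_index=self.data.index,
            notes=list(self.notes),
        )


class CombinedTrialModel(TrialModel):
    """Combined stress/non-stress model: adds a fixed treatment effect and
    a separate residual variance per treatment; one BLUE per genotype
    (genotype mean averaged equally over the two treatments)."""

    def __init__(
        self,
        data: pd.DataFrame,
        trait: str = "GY",
        covariate: str | None = "DTF",
        genotype_as: str = "fixed",
    ):
        conditions = sorted(data["condition"].astype(str).unique())
        if len(conditions) < 2:
            raise StageOneError(
                "combined model needs both conditions; use TrialModel for "
                "a single-condition trial"
            )
        data = data.copy()
        data["trial"] = "combined"
        super().__init__(data, trait, covariate, genotype_as)
        self.conditions = conditions

    def _designs(self):
        y, X, random_terms, genotypes, has_cov = super()._designs()
        cond = self.data["condition"].astype(str).to_numpy()
        # +/- 0.5 coding: genotype columns stay the equally-weighted means
        t = np.where(cond == STRESS, 0.5, -0.5)[:, None]
        X = np.hstack([X, t])
        self._resid_groups = np.where(cond == STRESS, 1, 0)
        return y, X, random_terms, genotypes, has_cov

    def fit(self) -> TrialResults:
        y, X, random_terms, genotypes, has_cov = self._designs()
        fit = reml(y, X, random_terms, resid_groups=self._resid_groups)

        blues = blue_se = blups = pev = None
        slope = float(fit.beta[-2]) if has_cov else None
        t_eff = float(fit.beta[-1])
        if self.genotype_as == "fixed":
            k = len(genotypes)
            blues = pd.Series(fit.beta[:k], index=genotypes, name="blue")
            blue_se = pd.Series(
                np.sqrt(np.diag(fit.cov_beta)[:k]), index=genotypes, name="se"
            )
        else:
            blups = pd.Series(fit.blup("genotype"), index=genotypes, name="blup")
            pev = fit.blup_pev("genotype")

        return TrialResults(
            trait=self.trait,
            trial="combined",
            genotype_as=self.genotype_as,
            genotypes=genotypes,
            blues=blues,
            blue_se=blue_se,
            blups=blups,
            blup_pev=pev,
            varcomps=dict(fit.varcomps),
            resid_vars={
                NON_STRESS: float(fit.resid_vars[0]),
                STRESS: float(fit.resid_vars[1]),
            },
            covariate_slope=slope,
            treatment_effect=t_eff,
            loglik=fit.loglik,
            reml=fit,
            data_index=self.data.index,
            notes=list(self.notes),
        )


def fit_trial_model(
    data: pd.DataFrame,
    trial: str | None = None,
    trait: str = "GY",
    covariate: str | None = "DTF",
    genotype_as: str = "fixed",
) -> TrialResults:
    """Functional wrapper around :class:`TrialModel`."""
    return TrialModel(data, trait, covariate, genotype_as, trial=trial).fit()


def fit_combined_model(
    data: pd.DataFrame,
    trait: str = "GY",
    covariate: str | None = "DTF",
    genotype_as: str = "fixed",
) -> TrialResults:
    """Functional wrapper around :class:`CombinedTrialModel`."""
    return CombinedTrialModel(data, trait, covariate, genotype_as).fit()


# ---------------------------------------------------------------------------
# outlier flagging


def flag_outliers(results: TrialResults, alpha: float = 0.05) -> np.ndarray:
    """Flag outlying records via Bonferroni-Holm on externally studentized
    residuals.

    Residuals are studentized in the whitened model and referred to a
    two-sided t distribution; the Holm step-down controls the family-wise
    error over the trial's records.  Returns a boolean mask aligned with the
    model's data rows.
    """
    fit = results.reml
    if fit is None:
        raise StageOneError("results carry no REML fit")
    if fit.n - fit.p - 1 < 2:
        warnings.warn(
            f"trial {results.trial}: too few residual degrees of freedom "
            "for outlier testing", stacklevel=2,
        )
        return np.zeros(fit.n, dtype=bool)
    t, df = studentized_residuals(fit)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject


def fit_with_outlier_rejection(
    data: pd.DataFrame,
    trial: str | None = None,
    trait: str = "GY",
    covariate: str | None = "DTF",
    genotype_as: str = "fixed",
    alpha: float = 0.05,
) -> tuple[TrialResults, np.ndarray]:
    """Fit, flag outliers once, set them missing, refit once (deterministic)."""
    model = TrialModel(data, trait, covariate, genotype_as, trial=trial)
    res = model.fit()
    flags = flag_outliers(res, alpha=alpha)
    if flags.any():
        cleaned = model.data.copy()
        cleaned.loc[cleaned.index[flags], trait] = np.nan
        res = TrialModel(cleaned, trait, covariate, genotype_as).fit()
        res.notes.append(f"{int(flags.sum())} outlier record(s) removed")
    return res, flags


# ---------------------------------------------------------------------------
# heritability


def cullis_heritability(results: TrialResults) -> float:
    """Cullis generalised heritability H2 = 1 - vbar_BLUP / (2 sigma2_g).

    ``vbar_BLUP`` is the mean prediction-error variance of a difference of
    two genotype BLUPs.  Values outside [0, 1] are clipped with a warning;
    a zero genetic variance gives H2 = 0 by convention.
    """
    if results.blup_pev is None:
        raise StageOneError("Cullis H2 requires a genotype-random fit")
    s2g = results.sigma2_g
    vy = float(np.var(results.reml.y)) if results.reml is not None else (
        s2g + sum(results.resid_vars.values())
    )
    if s2g <= 1e-8 * vy:
        warnings.warn("sigma2_g ~ 0: H2 set to 0", stacklevel=2)
        return 0.0
    C = results.blup_pev
    m = C.shape[0]
    if m < 2:
        raise StageOneError("H2 needs at least two genotypes")
    diag = np.diag(C)
    # mean over ordered pairs i != j of C_ii + C_jj - 2 C_ij
    vbar = 2.0 * diag.mean() - 2.0 * (C.sum() - diag.sum()) / (m * (m - 1))
    h2 = 1.0 - vbar / (2.0 * s2g)
    if h2 < 0.0 or h2 > 1.0:
        warnings.warn(f"H2 = {h2:.3f} outside [0, 1]; clipped", stacklevel=2)
    return float(np.clip(h2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# stage-one pipeline


def environment_label(year, condition) -> str:
    return f"{year}_{condition}"


def stage_one_blues(
    pheno: pd.DataFrame,
    trait: str = "GY",
    covariate: str | None = "DTF",
    max_missing_gy: float = 0.20,
    outlier_alpha: float | None = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run stage one over all trials: quality filter, per-trial fixed-genotype
    fits (with one outlier-rejection pass), and BLUE extraction.

    Returns ``(blues, report)`` where ``blues`` has one row per
    genotype x environment (environment = year x condition; duplicates from
    multiple trials merged by inverse-variance weighting) with columns
    ``genotype, year, condition, environment, blue, se, trial``.
    """
    filtered, report = quality_filter(pheno, max_missing_gy, trait)
    rows = []
    for trial, sub in filtered.groupby("trial", sort=True):
        year = sub["year"].iloc[0]
        condition = str(sub["condition"].iloc[0])
        if outlier_alpha is not None:
            res, _ = fit_with_outlier_rejection(
                sub, trait=trait, covariate=covariate, alpha=outlier_alpha
            )
        else:
            res = fit_trial_model(sub, trait=trait, covariate=covariate)
        for g in res.genotypes:
            rows.append(
                {
                    "genotype": g,
                    "year": year,
                    "condition": condition,
                    "environment": environment_label(year, condition),
                    "blue": float(res.blues[g]),
                    "se": float(res.blue_se[g]),
                    "trial": trial,
                }
            )
    blues = pd.DataFrame(rows)

    # merge duplicate genotype x environment entries by inverse-variance weight
    merged = []
    for _, group in blues.groupby(["genotype", "environment"], sort=True):
        if len(group) == 1:
            merged.append(group.iloc[0])
            continue
        w = 1.0 / np.maximum(group["se"].to_numpy() ** 2, 1e-12)
        out = group.iloc[0].copy()
        out["blue"] = float(np.average(group["blue"], weights=w))
        out["se"] = float(np.sqrt(1.0 / w.sum()))
        out["trial"] = "+".join(sorted(group["trial"].astype(str)))
        merged.append(out)
    blues = pd.DataFrame(merged).reset_index(drop=True)
    blues = blues[
        ["genotype", "year", "condition", "environment", "blue", "se", "trial"]
    ]
    return blues, report


def trial_heritabilities(
    pheno: pd.DataFrame,
    trait: str = "GY",
    covariate: str | None = "DTF",
) -> pd.DataFrame:
    """Genotype-random fits per trial -> Cullis H2 per trial."""
    rows = []
    for trial, sub in pheno.groupby("trial", sort=True):
        res = fit_trial_model(
            sub, trait=trait, covariate=covariate, genotype_as="random"
        )
        rows.append(
            {
                "trial": trial,
                "year": sub["year"].iloc[0],
                "condition": str(sub["condition"].iloc[0]),
                "sigma2_g": res.sigma2_g,
                "h2": cullis_heritability(res),
            }
        )
    return pd.DataFrame(rows)
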