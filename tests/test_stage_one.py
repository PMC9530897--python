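"""Stage-one tests: quality filtering, REML trial models against closed-form
and grid-search oracles, outlier flagging, Cullis heritability."""

import numpy as np
import pandas as pd
import pytest

from pedgxe.stage_one import (
    StageOneError,
    cullis_heritability,
    fit_combined_model,
    fit_trial_model,
    fit_with_outlier_rejection,
    flag_outliers,
    quality_filter,
    stage_one_blues,
)

from conftest import balanced_rcbd
from _oracles import grid_reml, reml_neg_loglik


# ---------------------------------------------------------------------------
# quality filter


def make_trial(trial, n_geno=4, missing_frac=0.0, design="RCBD", seed=0):
    df, _ = balanced_rcbd(n_geno=n_geno, n_rep=3, seed=seed, trial=trial)
    df["design"] = design
    if missing_frac:
        n_missing = int(missing_frac * len(df))
        df.loc[df.index[:n_missing], "GY"] = np.nan
    return df


def test_quality_filter_drops_and_reports():
    t = pd.concat(
        [
            make_trial("ok1"),
            make_trial("ok2", seed=1),
            make_trial("gappy", missing_frac=0.25),
            make_trial("nodesign", design=np.nan),
        ]
    )
    out, report = quality_filter(t)
    assert sorted(out["trial"].unique()) == ["ok1", "ok2"]
    reasons = dict(zip(report["trial"], report["reason"]))
    assert "missing > 20%" in reasons["gappy"]
    assert "design" in reasons["nodesign"]


def test_quality_filter_keeps_clean_trials_with_empty_report():
    t = pd.concat([make_trial("a"), make_trial("b", seed=3)])
    out, report = quality_filter(t)
    assert report.empty and len(out) == len(t)


def test_quality_filter_errors_when_nothing_survives():
    with pytest.raises(StageOneError, match="no trials survive"):
        quality_filter(make_trial("bad", missing_frac=0.5))


# ---------------------------------------------------------------------------
# trial model vs closed forms


def test_balanced_rcbd_blues_equal_genotype_means():
    df, _ = balanced_rcbd(n_geno=5, n_rep=3, seed=2)
    res = fit_trial_model(df, covariate=None)
    expected = df.groupby("genotype")["GY"].mean()
    np.testing.assert_allclose(
        res.blues[expected.index].to_numpy(), expected.to_numpy(), atol=1e-6
    )


def test_zero_noise_degenerate_limit():
    df, means = balanced_rcbd(n_geno=5, n_rep=3, resid_sd=0.0, seed=3,
                              rep_effects=np.zeros(3))
    res = fit_trial_model(df, covariate=None)
    vy = float(np.var(df["GY"]))
    assert res.resid_vars["all"] <= 1e-6 * vy
    np.testing.assert_allclose(
        res.blues[list(means)].to_numpy(), list(means.values()), atol=1e-5
    )


def test_gls_oracle_small_instance():
    """BLUEs match the closed-form GLS solution by direct matrix inversion
    at the REML variance estimates (5 genotypes x 3 reps)."""
    df, _ = balanced_rcbd(n_geno=5, n_rep=3, seed=4)
    res = fit_trial_model(df, covariate=None)
    genotypes = sorted(df["genotype"].unique())
    y = df["GY"].to_numpy()
    X = (df["genotype"].to_numpy()[:, None] == np.array(genotypes)).astype(float)
    reps = sorted(df["rep"].unique())
    Z = (df["rep"].to_numpy()[:, None] == np.array(reps)).astype(float)
    V = res.varcomps["rep"] * Z @ Z.T + res.resid_vars["all"] * np.eye(len(df))
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    np.testing.assert_allclose(res.blues[genotypes].to_numpy(), beta, atol=1e-8)


def test_covariate_slope_recovery():
    rng = np.random.default_rng(5)
    rows = []
    for i in range(8):
        for r in range(4):
            dtf = rng.normal(75, 5)
            rows.append(
                dict(genotype=f"G{i}", year=2003, season="dry",
                     condition="non_stress", trial="T1", rep=f"R{r}",
                     block=f"R{r}", design="RCBD",
                     GY=3000 + 40 * i + 30 * (dtf - 75) + rng.normal(0, 30),
                     DTF=dtf, PH=np.nan)
            )
    res = fit_trial_model(pd.DataFrame(rows))
    # slope SE ~ resid_sd / (sd(DTF) sqrt(n)); 3 SE band around the truth
    se = 30 / (5 * np.sqrt(32))
    assert abs(res.covariate_slope - 30.0) < 3 * 3 * se


def test_reml_matches_grid_search_oracle():
    """Iterative REML equals a brute-force zooming grid search over the
    profile likelihood (<= 50 records, 2 variance components)."""
    df, _ = balanced_rcbd(n_geno=8, n_rep=4, resid_sd=4.0, seed=6)
    res = fit_trial_model(df, covariate=None)
    genotypes = sorted(df["genotype"].unique())
    y = df["GY"].to_numpy()
    X = (df["genotype"].to_numpy()[:, None] == np.array(genotypes)).astype(float)
    reps = sorted(df["rep"].unique())
    Z = (df["rep"].to_numpy()[:, None] == np.array(reps)).astype(float)
    grid_vars, grid_val = grid_reml(y, X, [Z @ Z.T])
    fitted = np.array([res.varcomps["rep"], res.resid_vars["all"]])
    np.testing.assert_allclose(fitted, grid_vars, rtol=1e-3)
    fit_val = reml_neg_loglik(np.log(fitted), y, X, [Z @ Z.T])
    assert fit_val <= grid_val + 1e-6


# ---------------------------------------------------------------------------
# combined model


def _combined_data(ratio=4.0, n_geno=25, t_eff=-2000.0, seed=8):
    rng = np.random.default_rng(seed)
    gv = rng.normal(0, 300, n_geno)
    rows = []
    for i in range(n_geno):
        for cond, sd, mu in (
            ("non_stress", 300.0, 4000.0),
            ("stress", 300.0 * np.sqrt(ratio), 4000.0 + t_eff),
        ):
            for r in range(6):
                rows.append(
                    dict(genotype=f"G{i:02d}", year=2003, season="dry",
                         condition=cond, trial=f"T_{cond}", rep=f"R{r}",
                         block=f"R{r}", design="RCBD",
                         GY=mu + gv[i] + rng.normal(0, sd), DTF=np.nan, PH=np.nan)
                )
    return pd.DataFrame(rows)


def test_combined_model_heteroscedastic_recovery():
    df = _combined_data(ratio=4.0)          # 600 records
    res = fit_combined_model(df, covariate=None)
    ratio = res.resid_vars["stress"] / res.resid_vars["non_stress"]
    assert 2.0 <= ratio <= 8.0


def test_combined_model_treatment_effect_recovery():
    df = _combined_data(ratio=2.0, t_eff=-2000.0)
    res = fit_combined_model(df, covariate=None)
    se = np.sqrt(
        res.resid_vars["stress"] / 150 + res.resid_vars["non_stress"] / 150
    )
    assert abs(res.treatment_effect - (-2000.0)) < 3 * se


def test_combined_model_nests_homoscedastic_fit():
    df = _combined_data(ratio=1.0, n_geno=12, seed=9)
    res = fit_combined_model(df, covariate=None)
    # refit forcing one residual variance by relabeling the groups
    from pedgxe._mixed import reml

    genotypes = sorted(df["genotype"].unique())
    X = np.hstack(
        [
            (df["genotype"].to_numpy()[:, None] == np.array(genotypes)).astype(float),
            np.where(df["condition"] == "stress", 0.5, -0.5)[:, None],
        ]
    )
    reps = sorted(df["rep"].unique())
    Z = (df["rep"].to_numpy()[:, None] == np.array(reps)).astype(float)
    homo = reml(df["GY"].to_numpy(), X, {"rep": Z})
    assert res.loglik >= homo.loglik - 1e-6


def test_combined_model_rejects_single_condition():
    df, _ = balanced_rcbd(n_geno=4, n_rep=2)
    with pytest.raises(StageOneError, match="both conditions"):
        fit_combined_model(df)


# ---------------------------------------------------------------------------
# outlier flagging


def test_single_gross_outlier_is_flagged():
    df, _ = balanced_rcbd(n_geno=20, n_rep=5, resid_sd=3.0, seed=10)
    res = fit_trial_model(df, covariate=None)
    sigma = np.sqrt(res.resid_vars["all"])
    df = df.copy()
    df.loc[df.index[37], "GY"] += 10 * sigma
    res2 = fit_trial_model(df, covariate=None)
    flags = flag_outliers(res2, alpha=0.05)
    assert flags[37] and flags.sum() == 1


def test_flag_outliers_matches_direct_holm_stepdown():
    """Package flags = direct Holm step-down over the studentized-residual
    t p-values, computed independently here."""
    from scipy import stats

    df, _ = balanced_rcbd(n_geno=10, n_rep=4, resid_sd=3.0, seed=11)
    df.loc[df.index[5], "GY"] += 25.0
    res = fit_trial_model(df, covariate=None)
    from pedgxe._mixed import studentized_residuals

    t, dof = studentized_residuals(res.reml)
    p = 2 * stats.t.sf(np.abs(t), dof)
    order = np.argsort(p)
    m = len(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] * (m - rank) > 0.05:
            break
        reject[idx] = True
    np.testing.assert_array_equal(flag_outliers(res, alpha=0.05), reject)


def test_familywise_false_flag_rate_under_null():
    """With pure N(0, s2) residuals the Holm procedure flags anything in at
    most ~5% of trials (familywise error control)."""
    rng = np.random.default_rng(12)
    n_flagged_trials = 0
    reps = 120
    for k in range(reps):
        df, _ = balanced_rcbd(
            n_geno=20, n_rep=5, resid_sd=3.0, seed=1000 + k,
            rep_effects=rng.normal(0, 4, 5),
        )
        res = fit_trial_model(df, covariate=None)
        if flag_outliers(res, alpha=0.05).any():
            n_flagged_trials += 1
    # binomial(120, 0.05): 3 sigma above the mean is ~13
    assert n_flagged_trials <= 13


def test_outlier_refit_is_single_pass(recwarn):
    df, _ = balanced_rcbd(n_geno=10, n_rep=4, resid_sd=3.0, seed=13)
    df.loc[df.index[7], "GY"] += 40.0
    res, flags = fit_with_outlier_rejection(df, covariate=None)
    assert flags.sum() == 1
    assert any("outlier" in n for n in res.notes)


def test_too_few_records_warns_not_flags():
    df = pd.DataFrame(
        dict(genotype=["A", "B"], year=2003, season="dry",
             condition="non_stress", trial="T", rep=["R1", "R1"],
             block="B1", design="RCBD", GY=[1.0, 2.0], DTF=np.nan, PH=np.nan)
    )
    res = fit_trial_model(df, covariate=None)
    with pytest.warns(UserWarning, match="degrees of freedom"):
        flags = flag_outliers(res)
    assert not flags.any()


# ---------------------------------------------------------------------------
# Cullis heritability


def _random_genotype_trial(n_geno, n_rep, s2g, s2e, seed):
    rng = np.random.default_rng(seed)
    gv = rng.normal(0, np.sqrt(s2g), n_geno)
    rows = []
    for i in range(n_geno):
        for r in range(n_rep):
            rows.append(
                dict(genotype=f"G{i:02d}", year=2003, season="dry",
                     condition="stress", trial="T", rep=f"R{r}", block=f"R{r}",
                     design="RCBD", GY=2000 + gv[i] + rng.normal(0, np.sqrt(s2e)),
                     DTF=np.nan, PH=np.nan)
            )
    return pd.DataFrame(rows)


def test_h2_zero_when_no_genetic_variance():
    # identical genotype means: the genetic variance is estimated at its
    # floor and the zero-variance convention kicks in
    df = _random_genotype_trial(15, 3, s2g=0.0, s2e=0.0, seed=14)
    rng = np.random.default_rng(14)
    df["GY"] += df["rep"].map(
        dict(zip(sorted(df["rep"].unique()), rng.normal(0, 30, 3)))
    )
    res = fit_trial_model(df, covariate=None, genotype_as="random")
    with pytest.warns(UserWarning):
        assert cullis_heritability(res) == 0.0


def test_h2_closed_form_and_monotone_in_replication():
    """On a balanced design (genotype + residual only) the mixed-model
    equations give vbar = 2 s2e / (r + s2e/s2g), hence a closed-form H2;
    H2 increases with replication."""
    s2g, s2e = 400.0, 900.0
    prev = 0.0
    for n_rep in (2, 4, 8):
        df = _random_genotype_trial(40, n_rep, s2g, s2e, seed=15)
        res = fit_trial_model(df, covariate=None, genotype_as="random")
        # closed form at the *estimated* variances
        g, e = res.sigma2_g, res.resid_vars["all"]
        lam = e / g
        vbar = 2.0 * e / (n_rep + lam)
        expected = 1.0 - vbar / (2.0 * g)
        h2 = cullis_heritability(res)
        assert h2 == pytest.approx(expected, abs=0.02)
        assert h2 > prev
        prev = h2


def test_h2_decreases_with_residual_variance():
    h2s = []
    for s2e in (200.0, 800.0, 3200.0):
        df = _random_genotype_trial(40, 3, 400.0, s2e, seed=16)
        res = fit_trial_model(df, covariate=None, genotype_as="random")
        h2s.append(cullis_heritability(res))
    assert h2s[0] > h2s[1] > h2s[2]


# ---------------------------------------------------------------------------
# pipeline


def test_stage_one_blues_merges_duplicates_by_inverse_variance():
    a, _ = balanced_rcbd(n_geno=5, n_rep=3, seed=17, trial="T1")
    b, _ = balanced_rcbd(n_geno=5, n_rep=2, seed=18, trial="T2")
    blues, report = stage_one_blues(pd.concat([a, b]), covariate=None,
                                    outlier_alpha=None)
    # both trials share year x condition -> one merged row per genotype
    assert len(blues) == 5
    assert (blues["trial"] == "T1+T2").all()
    assert report.empty


def test_blues_invariant_to_replication_relabeling():
    df, _ = balanced_rcbd(n_geno=6, n_rep=3, seed=19)
    relabeled = df.copy()
    relabeled["rep"] = relabeled["rep"].map({"R0": "Z9", "R1": "A0", "R2": "M5"})
    r1 = fit_trial_model(df, covariate=None)
    r2 = fit_trial_model(relabeled, covariate=None)
    np.testing.assert_allclose(
        r1.blues.to_numpy(), r2.blues.to_numpy(), atol=1e-8
    )
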