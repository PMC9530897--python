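"""Cross-validation schemes CV2 / CV1 / CV0 for multi-environment prediction.

* **CV2** — incomplete trials: records are split at random into 5 folds;
  each genotype can be observed in some environments and masked in others.
* **CV1** — untested lines: genotypes (all their records together) are split
  into 5 folds, so a masked line is unobserved everywhere.
* **CV0** — novel years: leave-one-year-out; the training set excludes the
  target year entirely.

Training sets can be composed of stress records only (``S``), non-stress
only (``NS``), both (``CSN``), or crossed (``S->NS`` / ``NS->S``, CV0 only:
train on one condition excluding the target year, predict the other
condition in the target year).  Fold membership is derived by hashing record
keys, so for a fixed seed the testing partitions are identical across
training compositions.  Predicted values from all folds of a replicate are
pooled into one vector and scored as the Pearson correlation between
predicted and observed BLUEs within each environment (year x condition),
then averaged with weights proportional to environment size.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import build_model_kernels
from .model_engine import (
    CV_MCMC,
    FitResult,
    McmcConfig,
    MultiKernelModel,
    PreparedKernels,
)
from .pedigree import RelationshipMatrix
from .stage_one import NON_STRESS, STRESS

SCHEMES = ("CV0", "CV1", "CV2")
COMPOSITIONS = ("S", "NS", "CSN", "S->NS", "NS->S")
MIN_ENV_N = 3


class CrossvalError(ValueError):
    pass


def _hash_fraction(key: str) -> float:
    """Stable hash of a string key to [0, 1)."""
    digest = hashlib.md5(key.encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2.0**64


@dataclass
class CVPlan:
    """Masked-record partitions for one scheme.

    ``fold_ids`` maps replicate -> array of fold index per BLUE-table row
    (CV0 folds are years, one replicate).
    """

    scheme: str
    composition: str
    folds: int
    replicates: int
    seed: int
    fold_ids: dict[int, np.ndarray] = field(repr=False)
    fold_labels: list = field(default_factory=list)
    n_records: int = 0

    def masked(self, replicate: int, fold: int) -> np.ndarray:
        return self.fold_ids[replicate] == fold


def make_cv_plan(
    blues: pd.DataFrame,
    scheme: str,
    composition: str = "CSN",
    folds: int = 5,
    replicates: int = 10,
    seed: int = 0,
) -> CVPlan:
    """Build the fold partition for a scheme.

    Fold assignment hashes ``seed:replicate:key`` where the key is the
    record (CV2), the genotype (CV1) or the year (CV0); records are ranked
    by hash and dealt round-robin into folds.  This keeps testing partitions
    identical across training compositions and models.
    """
    if scheme not in SCHEMES:
        raise CrossvalError(f"unknown scheme {scheme!r}")
    if composition not in COMPOSITIONS:
        raise CrossvalError(f"unknown composition {composition!r}")
    if composition in ("S->NS", "NS->S") and scheme != "CV0":
        raise CrossvalError("crossed calibration is defined for CV0 only")
    blues = blues.reset_index(drop=True)
    n = len(blues)
    if blues["environment"].nunique() < 2:
        raise CrossvalError("need records in at least 2 environments")

    if scheme == "CV0":
        years = sorted(blues["year"].unique())
        if len(years) < 2:
            raise CrossvalError("CV0 needs at least 2 years")
        year_index = {y: i for i, y in enumerate(years)}
        ids = blues["year"].map(year_index).to_numpy()
        return CVPlan(
            scheme, composition, len(years), 1, seed,
            {0: ids}, fold_labels=years, n_records=n,
        )

    keys = (
        blues["genotype"].astype(str)
        if scheme == "CV1"
        else blues["genotype"].astype(str) + "|" + blues["environment"].astype(str)
    )
    fold_ids: dict[int, np.ndarray] = {}
    for rep in range(replicates):
        if scheme == "CV1":
            units = sorted(keys.unique())
        else:
            units = list(keys)  # one unit per record (keys are unique)
        hashes = [_hash_fraction(f"{seed}:{rep}:{u}") for u in units]
        order = np.argsort(hashes, kind="stable")
        unit_fold = np.empty(len(units), dtype=int)
        unit_fold[order] = np.arange(len(units)) % folds
        if scheme == "CV1":
            lookup = {u: f for u, f in zip(units, unit_fold)}
            fold_ids[rep] = keys.map(lookup).to_numpy()
        else:
            fold_ids[rep] = unit_fold
    return CVPlan(
        scheme, composition, folds, replicates, seed,
        fold_ids, fold_labels=list(range(folds)), n_records=n,
    )


def compose_training(
    plan: CVPlan,
    blues: pd.DataFrame,
    replicate: int,
    fold: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Training / testing index arrays (positions into the BLUE table) for
    one fold under the plan's training composition."""
    blues = blues.reset_index(drop=True)
    masked = plan.masked(replicate, fold)
    cond = blues["condition"].astype(str).to_numpy()
    is_s = cond == STRESS
    is_ns = cond == NON_STRESS
    comp = plan.composition

    if comp in ("S->NS", "NS->S"):
        # CV0 crossed calibration: the whole target year is excluded from
        # training in both conditions (novel-environment reading)
        target_year = plan.fold_labels[fold]
        in_year = (blues["year"] == target_year).to_numpy()
        if comp == "S->NS":
            train = is_s & ~in_year
            test = is_ns & in_year
        else:
            train = is_ns & ~in_year
            test = is_s & in_year
    else:
        if comp == "S":
            pool = is_s
        elif comp == "NS":
            pool = is_ns
        else:
            pool = np.ones(len(blues), dtype=bool)
        train = pool & ~masked
        test = pool & masked

    if not train.any():
        raise CrossvalError(
            f"{plan.scheme}/{comp} fold {fold}: empty training set"
        )
    return np.flatnonzero(train), np.flatnonzero(test)


def weighted_env_correlation(
    pred: np.ndarray,
    obs: np.ndarray,
    env_labels: np.ndarray,
    min_n: int = MIN_ENV_N,
) -> tuple[pd.DataFrame, float]:
    """Within-environment Pearson correlations and their size-weighted mean.

    Environments with fewer than ``min_n`` records are excluded (reported
    with NaN correlation).  Raises when no environment is scoreable.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    env_labels = np.asarray(env_labels)
    rows = []
    for env in sorted(pd.unique(env_labels)):
        sel = env_labels == env
        n_env = int(sel.sum())
        if n_env < min_n or np.std(pred[sel]) == 0 or np.std(obs[sel]) == 0:
            rows.append({"environment": env, "n": n_env, "correlation": np.nan})
            continue
        r = float(np.corrcoef(pred[sel], obs[sel])[0, 1])
        rows.append({"environment": env, "n": n_env, "correlation": r})
    per_env = pd.DataFrame(rows)
    scored = per_env.dropna(subset=["correlation"])
    if scored.empty:
        raise CrossvalError(
            f"no environment has >= {min_n} scoreable records"
        )
    w = scored["n"].to_numpy(dtype=float)
    weighted = float(np.average(scored["correlation"], weights=w / w.sum()))
    return per_env, weighted


@dataclass
class CVResult:
    """Tidy per-environment correlations plus replicate-level summaries."""

    per_environment: pd.DataFrame   # scheme,model,composition,replicate,environment,n,correlation
    per_replicate: pd.DataFrame     # scheme,model,composition,replicate,weighted

    def mean_accuracy(self) -> pd.DataFrame:
        """Mean weighted predictive ability across replicates."""
        return (
            self.per_replicate.groupby(
                ["scheme", "model", "composition"], as_index=False
            )["weighted"]
            .mean()
            .rename(columns={"weighted": "accuracy"})
        )

    def summary(self) -> pd.DataFrame:
        """Models as rows, scheme x composition as columns (table layout)."""
        acc = self.mean_accuracy()
        return acc.pivot_table(
            index="model", columns=["scheme", "composition"], values="accuracy"
        )

    def to_csv(self, path) -> None:
        self.per_environment.to_csv(path, index=False)

    def plot(self, ax=None):
        """Bar plot of mean predictive ability per model and scheme."""
        import matplotlib.pyplot as plt

        acc = self.mean_accuracy()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        pivot = acc.pivot_table(
            index="model", columns=["scheme", "composition"], values="accuracy"
        )
        pivot.plot.bar(ax=ax)
        ax.set_ylabel("weighted predictive ability")
        ax.set_xlabel("model")
        return ax


def _sampler_seed(base: int, replicate: int, fold: int) -> int:
    return (base * 1_000_003 + replicate * 97 + fold * 7 + 13) % (2**31 - 1)


def run_cv(
    blues: pd.DataFrame,
    model_ids: list[str],
    plan: CVPlan,
    cfg: McmcConfig | None = None,
    A: RelationshipMatrix | None = None,
    A_P1: RelationshipMatrix | None = None,
    A_P2: RelationshipMatrix | None = None,
    min_env_n: int = MIN_ENV_N,
) -> CVResult:
    """Execute a CV plan for a list of models.

    For each model x replicate, every fold is fitted with kernels built over
    that fold's training + testing records, testing responses masked; the
    pooled predictions are scored within environment and weight-averaged.
    Kernel eigendecompositions are cached per distinct record set, so the
    fold loop costs only Gibbs sweeps.
    """
    cfg = cfg or CV_MCMC
    blues = blues.reset_index(drop=True)
    prepared_cache: dict[tuple, PreparedKernels] = {}
    env_rows = []
    rep_rows = []

    for model_id in model_ids:
        for rep in range(plan.replicates):
            preds = np.full(len(blues), np.nan)
            for fold in range(plan.folds):
                train_idx, test_idx = compose_training(plan, blues, rep, fold)
                if len(test_idx) == 0:
                    continue
                rows = np.concatenate([train_idx, test_idx])
                rows = np.sort(rows)
                key = (model_id, rows.tobytes())
                if key not in prepared_cache:
                    sub = blues.iloc[rows].reset_index(drop=True)
                    ks = build_model_kernels(
                        model_id, sub, A=A, A_P1=A_P1, A_P2=A_P2
                    )
                    prepared_cache[key] = PreparedKernels.from_kernel_set(ks)
                pk = prepared_cache[key]
                pos = {r: i for i, r in enumerate(rows)}
                mask = np.zeros(len(rows), dtype=bool)
                mask[[pos[t] for t in test_idx]] = True
                y = blues["blue"].to_numpy(dtype=float)[rows]
                fold_cfg = McmcConfig(
                    iterations=cfg.iterations,
                    burn_in=cfg.burn_in,
                    thin=cfg.thin,
                    seed=_sampler_seed(plan.seed + cfg.seed, rep, fold),
                    prior_df=cfg.prior_df,
                    prior_share=cfg.prior_share,
                )
                try:
                    fit = MultiKernelModel(y, pk, mask).fit(fold_cfg)
                except Exception as exc:
                    raise CrossvalError(
                        f"{plan.scheme}/{model_id}/rep{rep}/fold{fold}: {exc}"
                    ) from exc
                preds[test_idx] = fit.linear_predictor[mask]

            scored = ~np.isnan(preds)
            if not scored.any():
                raise CrossvalError(
                    f"{plan.scheme}/{model_id}/rep{rep}: nothing predicted"
                )
            per_env, weighted = weighted_env_correlation(
                preds[scored],
                blues["blue"].to_numpy(dtype=float)[scored],
                blues["environment"].to_numpy()[scored],
                min_n=min_env_n,
            )
            per_env.insert(0, "replicate", rep)
            per_env.insert(0, "composition", plan.composition)
            per_env.insert(0, "model", model_id)
            per_env.insert(0, "scheme", plan.scheme)
            env_rows.append(per_env)
            rep_rows.append(
                {
                    "scheme": plan.scheme,
                    "model": model_id,
                    "composition": plan.composition,
                    "replicate": rep,
                    "weighted": weighted,
                }
            )

    return CVResult(
        per_environment=pd.concat(env_rows, ignore_index=True),
        per_replicate=pd.DataFrame(rep_rows),
    )
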