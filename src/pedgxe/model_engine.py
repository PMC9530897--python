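"""Stage two: Bayesian multi-kernel mixed models fitted by Gibbs sampling.

The stage-one BLUEs are modelled as

    y = mu + sum_k u_k + e,    u_k ~ N(0, K_k s2_k),    e ~ N(0, I s2)

where each K_k is one of the model's covariance kernels (environment blocks,
pedigree additive, GCA/SCA, and their Hadamard environment interactions).
Each kernel is eigendecomposed once, K_k = U_k D_k U_k', and the effects are
sampled in the eigenbasis where the full conditionals are diagonal — the
standard trick that makes multi-kernel Gibbs sampling cheap.  Variance
components carry scaled-inverse-chi-square priors; masked responses are
treated as missing and imputed every sweep, so prediction of masked records
falls out of the joint covariance over training + testing records.

The sampler is fully deterministic given the seed in :class:`McmcConfig`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import KernelSet, build_model_kernels
from .pedigree import RelationshipMatrix


class EngineError(RuntimeError):
    pass


@dataclass(frozen=True)
class McmcConfig:
    """Gibbs sampler settings.

    ``prior_df`` and ``prior_share`` define the scaled-inverse-chi-square
    priors: every kernel component's prior mode is an equal share of
    ``prior_share`` of the phenotypic variance of the training responses,
    the residual's prior mode is the remaining ``1 - prior_share``.
    """

    iterations: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_share: float = 0.5
    standardize: bool = True
    sample_intercept: bool = True
    update_variances: bool = True
    fixed_variances: dict | None = None
    eigen_tol: float = 1e-10

    def __post_init__(self):
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.fixed_variances is not None and self.standardize:
            raise ValueError("fixed_variances requires standardize=False")


#: reduced settings for cross-validation runs
CV_MCMC = McmcConfig(iterations=6_000, burn_in=1_000, thin=5)


def effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS (Geyer-style)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


@dataclass
class PreparedKernels:
    """Eigendecomposed kernel set, reusable across fits on the same records."""

    model_id: str
    names: list[str]
    symbols: list[str]
    U: list[np.ndarray]
    d: list[np.ndarray]
    n_records: int

    @classmethod
    def from_kernel_set(cls, ks: KernelSet, tol: float = 1e-10) -> "PreparedKernels":
        U, d = [], []
        for comp in ks.components:
            w, V = np.linalg.eigh(comp.kernel)
            keep = w > tol
            if not keep.any():
                raise EngineError(f"component {comp.name}: kernel is null")
            U.append(np.ascontiguousarray(V[:, keep]))
            d.append(np.ascontiguousarray(w[keep]))
        return cls(
            model_id=ks.model_id,
            names=ks.names,
            symbols=[c.symbol for c in ks.components],
            U=U,
            d=d,
            n_records=ks.n_records,
        )


@dataclass
class FitResult:
    """Posterior summaries of one multi-kernel fit."""

    model_id: str
    component_names: list[str]
    component_symbols: list[str]
    vc_mean: dict[str, float]
    vc_sd: dict[str, float]
    vc_ess: dict[str, float]
    resid_mean: float
    resid_sd: float
    mu_mean: float
    linear_predictor: np.ndarray           # posterior mean, original scale
    mask: np.ndarray
    records: pd.DataFrame | None
    config: McmcConfig
    vc_draws: pd.DataFrame = field(repr=False, default=None)

    # -- reporting ----------------------------------------------------------

    def variance_summary(self) -> pd.DataFrame:
        """One row per variance component (incl. residual): posterior mean,
        SD, proportion of total variance, effective sample size."""
        rows = []
        total = sum(self.vc_mean.values()) + self.resid_mean
        for name, symbol in zip(self.component_names, self.component_symbols):
            rows.append(
                {
                    "component": name,
                    "symbol": symbol,
                    "post_mean": self.vc_mean[name],
                    "post_sd": self.vc_sd[name],
                    "proportion": self.vc_mean[name] / total,
                    "ess": self.vc_ess[name],
                }
            )
        rows.append(
            {
                "component": "residual",
                "symbol": "sigma2",
                "post_mean": self.resid_mean,
                "post_sd": self.resid_sd,
                "proportion": self.resid_mean / total,
                "ess": self.vc_ess.get("residual", np.nan),
            }
        )
        return pd.DataFrame(rows)

    def predict_masked(self) -> pd.Series:
        """Posterior-mean linear predictor restricted to the masked records,
        keyed by (genotype, environment) when record metadata is available."""
        if not self.mask.any():
            warnings.warn("no masked records to predict", stacklevel=2)
            return pd.Series(dtype=float)
        values = self.linear_predictor[self.mask]
        if self.records is not None:
            idx = pd.MultiIndex.from_frame(
                self.records.loc[self.mask, ["genotype", "environment"]]
            )
            return pd.Series(values, index=idx, name="prediction")
        return pd.Series(values, index=np.flatnonzero(self.mask), name="prediction")

    def summary(self) -> str:
        df = self.variance_summary()
        lines = [
            f"Multi-kernel model {self.model_id}  "
            f"(n={len(self.mask)}, masked={int(self.mask.sum())})",
            f"intercept (posterior mean): {self.mu_mean:.4g}",
            df.to_string(
                index=False,
                formatters={
                    "post_mean": "{:.4g}".format,
                    "post_sd": "{:.4g}".format,
                    "proportion": "{:.3f}".format,
                    "ess": "{:.0f}".format,
                },
            ),
        ]
        return "\n".join(lines)

    def plot_variance_components(self, ax=None):
        """Horizontal bar plot of posterior variance proportions."""
        import matplotlib.pyplot as plt

        df = self.variance_summary()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 * len(df) + 1))
        ax.barh(df["component"], df["proportion"], xerr=df["post_sd"] /
                (df["post_mean"].sum()), color="#4c72b0")
        ax.set_xlabel("proportion of total variance")
        ax.set_title(f"model {self.model_id}")
        return ax

    def save(self, directory: str | Path) -> None:
        """Serialise: JSON scalars/summaries + TSV per-record predictions."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "model_id": self.model_id,
            "mu_mean": self.mu_mean,
            "resid_mean": self.resid_mean,
            "resid_sd": self.resid_sd,
            "vc_mean": self.vc_mean,
            "vc_sd": self.vc_sd,
            "vc_ess": self.vc_ess,
            "config": {
                "iterations": self.config.iterations,
                "burn_in": self.config.burn_in,
                "thin": self.config.thin,
                "seed": self.config.seed,
            },
        }
        (directory / "fit.json").write_text(json.dumps(payload, indent=1))
        out = pd.DataFrame({"prediction": self.linear_predictor, "masked": self.mask})
        if self.records is not None:
            out = pd.concat(
                [self.records[["genotype", "environment"]].reset_index(drop=True), out],
                axis=1,
            )
        out.to_csv(directory / "predictions.tsv", sep="\t", index=False)


class MultiKernelModel:
    """Bayesian multi-kernel regression model over stage-one BLUEs.

    Parameters
    ----------
    y
        Responses, one per record; masked entries may be anything (ignored).
    kernels
        A :class:`~pedgxe.kernels.KernelSet` or :class:`PreparedKernels`
        covering all records.
    mask
        Boolean array, ``True`` marks records whose response is withheld and
        predicted.  Default: nothing masked.
    records
        Optional record metadata (``genotype``/``environment`` columns) used
        to key predictions.
    """

    def __init__(
        self,
        y: np.ndarray,
        kernels: KernelSet | PreparedKernels,
        mask: np.ndarray | None = None,
        records: pd.DataFrame | None = None,
    ):
        y = np.asarray(y, dtype=float)
        if isinstance(kernels, KernelSet):
            kernels = PreparedKernels.from_kernel_set(kernels)
        if len(y) != kernels.n_records:
            raise EngineError("y and kernels disagree on record count")
        if mask is None:
            mask = np.zeros(len(y), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.all():
            raise EngineError("at least one unmasked response is required")
        obs = y[~mask]
        if not np.isfinite(obs).all():
            raise EngineError("non-finite response among unmasked records")
        if np.var(obs) == 0:
            raise EngineError("zero-variance response")
        self.y = y
        self.kernels = kernels
        self.mask = mask
        self.records = records.reset_index(drop=True) if records is not None else None

    @classmethod
    def from_blues(
        cls,
        blues: pd.DataFrame,
        model_id: str,
        A: RelationshipMatrix | None = None,
        A_P1: RelationshipMatrix | None = None,
        A_P2: RelationshipMatrix | None = None,
        mask: np.ndarray | None = None,
        response: str = "blue",
    ) -> "MultiKernelModel":
        """Build model ``model_id`` (M1-M7) directly from a BLUE table.

        The table needs ``genotype``/``environment`` columns plus
        ``parent1``/``parent2`` for the combining-ability models (see
        :func:`attach_parents`).
        """
        blues = blues.reset_index(drop=True)
        ks = build_model_kernels(model_id, blues, A=A, A_P1=A_P1, A_P2=A_P2)
        return cls(blues[response].to_numpy(dtype=float), ks, mask, records=blues)

    # -- sampling -----------------------------------------------------------

    def fit(self, config: McmcConfig | None = None) -> FitResult:
        cfg = config or McmcConfig()
        rng = np.random.default_rng(cfg.seed)
        pk = self.kernels
        K = len(pk.names)
        n = pk.n_records
        mask = self.mask
        obs = ~mask

        y_obs = self.y[obs]
        m = float(y_obs.mean()) if cfg.standardize else 0.0
        s = float(y_obs.std()) if cfg.standardize else 1.0
        if s == 0:
            s = 1.0
        yw = (self.y - m) / s
        yw = np.where(mask, 0.0, yw)

        vy = float(np.var((self.y[obs] - m) / s))
        # scaled-inv-chi2(nu, tau2): mode = nu tau2 / (nu + 2)
        nu0 = cfg.prior_df
        mode_comp = cfg.prior_share * vy / max(K, 1)
        mode_res = (1.0 - cfg.prior_share) * vy
        tau2_comp = mode_comp * (nu0 + 2.0) / nu0
        tau2_res = mode_res * (nu0 + 2.0) / nu0

        if cfg.fixed_variances is not None:
            fixed = dict(cfg.fixed_variances)
            s2 = np.array([fixed[name] for name in pk.names])
            s2_e = float(fixed.get("residual", vy / 2))
        else:
            s2 = np.full(K, mode_comp if mode_comp > 0 else vy / (K + 1.0))
            s2_e = mode_res if mode_res > 0 else vy / 2.0

        alphas = [np.zeros(len(d)) for d in pk.d]
        fitted = [np.zeros(n) for _ in range(K)]
        mu = 0.0
        eta = np.zeros(n)                   # mu + sum fitted
        r = yw - eta                        # residual on working scale

        n_kept = -(-(cfg.iterations - cfg.burn_in) // cfg.thin)
        vc_draws = np.empty((n_kept, K + 2))  # components + residual + mu
        lp_sum = np.zeros(n)
        kept = 0

        for it in range(cfg.iterations):
            # impute masked responses
            if mask.any():
                yw[mask] = eta[mask] + rng.normal(0.0, np.sqrt(s2_e), mask.sum())
                r = yw - eta

            # intercept
            if cfg.sample_intercept:
                r += mu
                mu = rng.normal(r.mean(), np.sqrt(s2_e / n))
                r -= mu

            # component effects in the eigenbasis (diagonal conditionals)
            for k in range(K):
                Uk, dk = pk.U[k], pk.d[k]
                r += fitted[k]
                t = Uk.T @ r
                prec = 1.0 / s2_e + 1.0 / (dk * s2[k])
                var = 1.0 / prec
                mean = var * t / s2_e
                a = mean + np.sqrt(var) * rng.standard_normal(len(dk))
                alphas[k] = a
                fitted[k] = Uk @ a
                r -= fitted[k]

                if cfg.update_variances:
                    ss = float(a @ (a / dk)) + nu0 * tau2_comp
                    df = nu0 + len(dk)
                    s2[k] = ss / rng.chisquare(df)

            if cfg.update_variances:
                ss = float(r @ r) + nu0 * tau2_res
                df = nu0 + n
                s2_e = ss / rng.chisquare(df)

            if not np.isfinite(s2_e) or not np.all(np.isfinite(s2)):
                raise EngineError(f"divergent sampler state at iteration {it}")

            eta = mu + np.sum(fitted, axis=0)

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                vc_draws[kept, :K] = s2
                vc_draws[kept, K] = s2_e
                vc_draws[kept, K + 1] = mu
                lp_sum += eta
                kept += 1

        if kept == 0:
            raise EngineError("no post-burn-in samples kept; check config")
        vc_draws = vc_draws[:kept]
        lp_mean = lp_sum / kept

        scale2 = s * s
        names = pk.names
        vc_mean = {nm: float(vc_draws[:, i].mean() * scale2) for i, nm in enumerate(names)}
        vc_sd = {nm: float(vc_draws[:, i].std() * scale2) for i, nm in enumerate(names)}
        vc_ess = {nm: effective_sample_size(vc_draws[:, i]) for i, nm in enumerate(names)}
        vc_ess["residual"] = effective_sample_size(vc_draws[:, K])

        draws_df = pd.DataFrame(vc_draws, columns=names + ["residual", "mu"])
        draws_df[names + ["residual"]] *= scale2

        return FitResult(
            model_id=pk.model_id,
            component_names=list(names),
            component_symbols=list(pk.symbols),
            vc_mean=vc_mean,
            vc_sd=vc_sd,
            vc_ess=vc_ess,
            resid_mean=float(vc_draws[:, K].mean() * scale2),
            resid_sd=float(vc_draws[:, K].std() * scale2),
            mu_mean=float(m + s * vc_draws[:, K + 1].mean()),
            linear_predictor=m + s * lp_mean,
            mask=mask,
            records=self.records,
            config=cfg,
            vc_draws=draws_df,
        )


def fit_model(
    kernels: KernelSet | PreparedKernels,
    y: np.ndarray,
    cfg: McmcConfig,
    mask: np.ndarray | None = None,
    records: pd.DataFrame | None = None,
) -> FitResult:
    """Functional wrapper: fit a kernel set to responses with a mask."""
    return MultiKernelModel(y, kernels, mask, records).fit(cfg)


def attach_parents(blues: pd.DataFrame, genealogy) -> pd.DataFrame:
    """Add ``parent1``/``parent2`` columns to a BLUE table from a genealogy.

    Lines with unresolved parents get NA parents; the combining-ability
    models will then refuse them by name.
    """
    from .pedigree import UNKNOWN

    out = blues.copy()
    p1, p2 = [], []
    for g in out["genotype"]:
        if g in genealogy:
            a, b = genealogy.parents[g]
            p1.append(a if a != UNKNOWN else np.nan)
            p2.append(b if b != UNKNOWN else np.nan)
        else:
            p1.append(np.nan)
            p2.append(np.nan)
    out["parent1"] = p1
    out["parent2"] = p2
    return out


def reduced_config(cfg: McmcConfig, factor: float) -> McmcConfig:
    """Scale chain length down by ``factor`` (for quick exploratory runs)."""
    return replace(
        cfg,
        iterations=max(int(cfg.iterations / factor), cfg.thin * 10),
        burn_in=int(cfg.burn_in / factor),
    )
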