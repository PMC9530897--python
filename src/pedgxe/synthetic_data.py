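"""Synthetic breeding-program data with the structure the analysis assumes.

The generator emulates a multi-year drought breeding program at desk scale:

* a multi-generation pedigree whose parents recur across crosses (the
  borrowing structure that motivates the combining-ability models),
* year x condition trials (paired stress / non-stress), with long-term
  checks present every year so the genotype x year incidence graph stays
  connected,
* phenotypes simulated from any of the M1-M7 kernel models with known
  variance components, a multiplicative drought yield penalty on the mean,
  condition-specific residual variances (with per-trial spread so trial
  heritabilities span a realistic range), replication effects and a
  days-to-flowering covariate with a known yield slope.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .kernels import MODEL_REGISTRY, KernelComponent, build_model_kernels, incidence, hadamard_interaction, main_effect_kernel
from .pedigree import (
    Genealogy,
    PedigreeRecord,
    RelationshipMatrix,
    additive_relationship,
    build_genealogy,
    crosses_from_genealogy,
    parent_relationship_matrices,
)
from .stage_one import NON_STRESS, STRESS, environment_label


class SimulationError(ValueError):
    pass


def _default_variances() -> dict[str, float]:
    # kg/ha^2 scale: sd(a) ~ 894, sd(E) = 500, sd(aE) = 500, sd(GxC) ~ 283.
    # Calibrated (jointly with the residual variances below) so that
    # per-trial Cullis heritabilities land in the printed ranges of managed
    # drought programs: stress trials ~0.3-0.9, non-stress above them.
    return {"E": 250_000.0, "A": 800_000.0, "AxE": 250_000.0, "GxC": 80_000.0}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings (defaults emulate the study conditions at desk
    scale: ~10 year-environments, paired conditions, ~65 concurrent lines
    connected by 5 checks, drought yield penalty 0.45)."""

    n_founders: int = 36
    n_crosses: int = 120         # per cycle
    n_cycles: int = 2
    n_checks: int = 5
    years: int = 10
    start_year: int = 2003
    conditions: tuple[str, ...] = (NON_STRESS, STRESS)
    carry_years: int = 2         # consecutive years each new line is evaluated
    reps: int = 3
    design: str = "RCBD"
    model_id: str = "M2"
    variances: dict = field(default_factory=_default_variances)
    base_mean: float = 4_500.0
    drought_penalty: float = 0.45
    resid_ns: float = 400_000.0   # sd ~632 kg/ha per plot
    resid_s: float = 1_200_000.0  # sd ~1095 kg/ha per plot
    resid_jitter: float = 0.25    # per-trial uniform spread of residual sd
    rep_var: float = 22_500.0     # sd 150
    dtf_mean: float = 75.0
    dtf_sd: float = 7.0
    dtf_noise_sd: float = 2.0
    dtf_slope: float = 30.0       # kg/ha per day
    disjoint_parent_roles: bool = False
    stagger: bool = True          # False: every line tested in every year
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 4:
            raise SimulationError("need at least 4 founders")
        if self.years < 2:
            raise SimulationError("need at least 2 years")
        if not 0 < self.drought_penalty <= 1:
            raise SimulationError("drought penalty must be in (0, 1]")
        if any(v < 0 for v in self.variances.values()):
            raise SimulationError("variances must be >= 0")


@dataclass
class SimTruth:
    """Realised effects and noiseless genetic values per simulated record."""

    records: pd.DataFrame
    component_values: dict[str, np.ndarray]
    variances: dict[str, float]
    genetic_values: np.ndarray          # sum of non-environment components
    noiseless: np.ndarray               # condition mean + all components
    dtf_genotype_means: pd.Series


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(cfg: SimConfig) -> list[PedigreeRecord]:
    """Founders plus ``n_cycles`` rounds of crossing with parent reuse.

    Cycle-c crosses draw parents from everything generated before cycle c,
    so with more crosses than available parents each parent is expected in
    several crosses.  Deterministic per ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    records = [PedigreeRecord(f"F{i:03d}") for i in range(cfg.n_founders)]
    pool = [r.id for r in records]
    for cycle in range(1, cfg.n_cycles + 1):
        if cfg.disjoint_parent_roles:
            half = len(pool) // 2
            pool1, pool2 = pool[:half], pool[half:]
        else:
            pool1 = pool2 = pool
        new = []
        for k in range(cfg.n_crosses):
            p1 = pool1[rng.integers(len(pool1))]
            p2 = pool2[rng.integers(len(pool2))]
            tries = 0
            while p2 == p1 and tries < 20:
                p2 = pool2[rng.integers(len(pool2))]
                tries += 1
            if p1 == p2:
                raise SimulationError("cannot sample distinct parents")
            new.append(PedigreeRecord(f"C{cycle}_{k:03d}", p1, p2))
        records.extend(new)
        pool = pool + [r.id for r in new]
    return records


def phenotyped_lines(cfg: SimConfig, records: Sequence[PedigreeRecord]) -> tuple[list[str], list[str]]:
    """(checks, other phenotyped lines): the final-cycle crosses, the first
    ``n_checks`` of which serve as long-term checks."""
    last = sorted(r.id for r in records if r.id.startswith(f"C{cfg.n_cycles}_"))
    if len(last) <= cfg.n_checks:
        raise SimulationError("not enough final-cycle crosses for checks")
    return last[: cfg.n_checks], last[cfg.n_checks:]


# ---------------------------------------------------------------------------
# record layout and genetic values


def simulate_record_layout(cfg: SimConfig, g: Genealogy) -> pd.DataFrame:
    """One row per genotype x environment: checks appear every year, other
    lines enter in a staggered start year and stay ``carry_years`` years."""
    records = [PedigreeRecord(i, *g.parents[i]) for i in g.ordered_ids]
    checks, lines = phenotyped_lines(cfg, records)
    years = [cfg.start_year + t for t in range(cfg.years)]

    rows = []
    for j, line in enumerate(lines):
        if cfg.stagger:
            start = years[j % cfg.years]
            span = [y for y in years if start <= y < start + cfg.carry_years]
        else:
            span = years
        for y in span:
            rows.append((line, y))
    for chk in checks:
        for y in years:
            rows.append((chk, y))

    out = []
    for genotype, year in rows:
        for cond in cfg.conditions:
            p1, p2 = g.parents[genotype]
            out.append(
                {
                    "genotype": genotype,
                    "year": year,
                    "condition": cond,
                    "environment": environment_label(year, cond),
                    "parent1": p1,
                    "parent2": p2,
                    "is_check": genotype in checks,
                }
            )
    df = pd.DataFrame(out).sort_values(
        ["year", "condition", "genotype"], kind="stable"
    )
    return df.reset_index(drop=True)


def draw_component_values(
    records: pd.DataFrame,
    model_id: str,
    variances: dict[str, float],
    A: RelationshipMatrix,
    A_P1: RelationshipMatrix | None,
    A_P2: RelationshipMatrix | None,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw one effect vector per model component from N(0, K_k v_k), plus
    an optional genotype-by-condition term ("GxC") when configured."""
    ks = build_model_kernels(model_id, records, A=A, A_P1=A_P1, A_P2=A_P2)
    components = list(ks.components)
    if variances.get("GxC", 0.0) > 0 and records["condition"].nunique() > 1:
        Z_g, g_levels = incidence(records, "genotype")
        a_kern = main_effect_kernel(Z_g, A.submatrix(g_levels), "Ag")
        Z_c, _ = incidence(records, "condition")
        c_kern = KernelComponent("C", Z_c @ Z_c.T)
        components.append(hadamard_interaction(a_kern, c_kern, "GxC"))

    values: dict[str, np.ndarray] = {}
    n = len(records)
    for comp in components:
        v = float(variances.get(comp.name, 0.0))
        if v <= 0:
            values[comp.name] = np.zeros(n)
            continue
        K = comp.kernel + 1e-8 * np.eye(n)
        L = np.linalg.cholesky(K)
        values[comp.name] = L @ rng.standard_normal(n) * np.sqrt(v)
    return values


def _relationship_matrices(cfg: SimConfig, g: Genealogy):
    A = additive_relationship(g)
    records = [PedigreeRecord(i, *g.parents[i]) for i in g.ordered_ids]
    checks, lines = phenotyped_lines(cfg, records)
    crosses = crosses_from_genealogy(g, checks + lines)
    A_P1, A_P2, info = parent_relationship_matrices(crosses, g, A)
    return A, A_P1, A_P2, info


# ---------------------------------------------------------------------------
# simulation entry points


def simulate_blues(
    cfg: SimConfig,
    resid_var: float = 1.0,
    mu: float = 0.0,
    genealogy: Genealogy | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Record-level responses straight from the kernel model (no trial
    design, no covariate): ``y = mu + sum_k u_k + N(0, resid_var)``.

    Used to exercise stage two at known variance components.
    """
    rng = np.random.default_rng(cfg.seed)
    g = genealogy or build_genealogy(simulate_pedigree(cfg))
    A, A_P1, A_P2, _ = _relationship_matrices(cfg, g)
    records = simulate_record_layout(cfg, g)
    values = draw_component_values(
        records, cfg.model_id, cfg.variances, A, A_P1, A_P2, rng
    )
    genetic = np.sum(
        [v for k, v in values.items() if k != "E"], axis=0
    ) if values else np.zeros(len(records))
    noiseless = mu + genetic + values.get("E", 0.0)
    y = noiseless + rng.normal(0.0, np.sqrt(resid_var), len(records))
    blues = records.copy()
    blues["blue"] = y
    truth = SimTruth(
        records=records,
        component_values=values,
        variances={**cfg.variances, "residual": resid_var},
        genetic_values=genetic,
        noiseless=noiseless,
        dtf_genotype_means=pd.Series(dtype=float),
    )
    return blues, truth


def simulate_trials(
    cfg: SimConfig,
    genealogy: Genealogy | None = None,
    model_id: str | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Plot-level multi-environment trial data.

    Records are laid out as year x condition trials with ``cfg.reps``
    replications; stress plots get the drought-penalised mean and their own
    residual variance (with a per-trial spread so heritabilities vary);
    checks appear in every year; days-to-flowering is simulated
    independently of genetic value with a known yield slope.
    """
    model_id = model_id or cfg.model_id
    if model_id not in MODEL_REGISTRY:
        raise SimulationError(f"unknown model {model_id!r}")
    rng = np.random.default_rng(cfg.seed)
    g = genealogy or build_genealogy(simulate_pedigree(cfg))
    A, A_P1, A_P2, info = _relationship_matrices(cfg, g)
    if info["excluded"]:
        raise SimulationError(
            f"phenotyped lines with unresolved parents: {info['excluded'][:5]}"
        )
    records = simulate_record_layout(cfg, g)
    values = draw_component_values(
        records, model_id, cfg.variances, A, A_P1, A_P2, rng
    )
    genetic = np.sum([v for k, v in values.items() if k != "E"], axis=0)
    env_effect = values.get("E", np.zeros(len(records)))

    genotypes = sorted(records["genotype"].unique())
    dtf_means = pd.Series(
        cfg.dtf_mean + rng.normal(0.0, cfg.dtf_sd, len(genotypes)),
        index=genotypes,
        name="dtf_mean",
    )

    cond_mean = {
        c: cfg.base_mean * (cfg.drought_penalty if c == STRESS else 1.0)
        for c in cfg.conditions
    }
    resid_var = {STRESS: cfg.resid_s}
    for c in cfg.conditions:
        resid_var.setdefault(c, cfg.resid_ns)

    # per-trial residual-sd factor and replication effects
    trials = sorted(records["environment"].unique())
    trial_factor = {
        t: 1.0 + cfg.resid_jitter * (2.0 * rng.random() - 1.0) for t in trials
    }
    rep_effect = {
        (t, r): rng.normal(0.0, np.sqrt(cfg.rep_var))
        for t in trials
        for r in range(cfg.reps)
    }

    noiseless = np.empty(len(records))
    rows = []
    for i, rec in records.iterrows():
        cond = rec["condition"]
        env = rec["environment"]
        base = cond_mean[cond] + env_effect[i] + genetic[i]
        noiseless[i] = base
        sd = np.sqrt(resid_var[cond]) * trial_factor[env]
        for r in range(cfg.reps):
            dtf = float(dtf_means[rec["genotype"]]) + rng.normal(0.0, cfg.dtf_noise_sd)
            y = (
                base
                + cfg.dtf_slope * (dtf - cfg.dtf_mean)
                + rep_effect[(env, r)]
                + rng.normal(0.0, sd)
            )
            rows.append(
                {
                    "genotype": rec["genotype"],
                    "year": rec["year"],
                    "season": "dry",
                    "condition": cond,
                    "trial": f"T{env}",
                    "rep": f"R{r + 1}",
                    "block": f"R{r + 1}",
                    "design": cfg.design,
                    "GY": max(y, 0.0),
                    "DTF": dtf,
                    "PH": np.nan,
                }
            )
    pheno = pd.DataFrame(rows)
    truth = SimTruth(
        records=records,
        component_values=values,
        variances=dict(cfg.variances),
        genetic_values=genetic,
        noiseless=noiseless,
        dtf_genotype_means=dtf_means,
    )
    return pheno, truth


def trial_h2_profile(pheno: pd.DataFrame, covariate: str | None = "DTF") -> pd.DataFrame:
    """Per-trial Cullis heritabilities of simulated (or real) trial data."""
    from .stage_one import trial_heritabilities

    return trial_heritabilities(pheno, covariate=covariate)


def genotype_year_connected(pheno: pd.DataFrame) -> bool:
    """Is the genotype x year incidence graph connected?"""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    genotypes = {v: i for i, v in enumerate(sorted(pheno["genotype"].unique()))}
    years = {v: i for i, v in enumerate(sorted(pheno["year"].unique()))}
    ng, ny = len(genotypes), len(years)
    pairs = pheno[["genotype", "year"]].drop_duplicates()
    gi = pairs["genotype"].map(genotypes).to_numpy()
    yi = pairs["year"].map(years).to_numpy() + ng
    n = ng + ny
    adj = coo_matrix(
        (np.ones(2 * len(pairs)), (np.r_[gi, yi], np.r_[yi, gi])), shape=(n, n)
    )
    ncomp, _ = connected_components(adj, directed=False)
    return ncomp == 1


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed."""
    return replace(cfg, seed=seed)
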