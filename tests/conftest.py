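import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pedgxe.pedigree import (
    PedigreeRecord,
    additive_relationship,
    build_genealogy,
)
from pedgxe.synthetic_data import SimConfig, simulate_pedigree, simulate_trials

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_genealogy():
    """Two founders, full sibs, a half sib, and a selfed line."""
    recs = [
        PedigreeRecord("X"),
        PedigreeRecord("Y"),
        PedigreeRecord("Z"),
        PedigreeRecord("C1", "X", "Y"),
        PedigreeRecord("C2", "X", "Y"),
        PedigreeRecord("H", "X", "Z"),
        PedigreeRecord("S", "C1", "C1"),
    ]
    return build_genealogy(recs)


@pytest.fixture(scope="session")
def small_A(small_genealogy):
    return additive_relationship(small_genealogy)


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic dataset shared across tests."""
    cfg = SimConfig(seed=20_03)
    pheno, truth = simulate_trials(cfg)
    return cfg, pheno, truth


def balanced_rcbd(n_geno=5, n_rep=3, means=None, resid_sd=2.0, seed=0,
                  condition="non_stress", trial="T1", rep_effects=None):
    """Small balanced RCBD phenotype table with known genotype means."""
    rng = np.random.default_rng(seed)
    if means is None:
        means = {f"G{i}": 100.0 + 10.0 * i for i in range(n_geno)}
    if rep_effects is None:
        rep_effects = rng.normal(0, 5, n_rep)
    rows = []
    for g, m in means.items():
        for r in range(n_rep):
            rows.append(
                dict(
                    genotype=g, year=2003, season="dry", condition=condition,
                    trial=trial, rep=f"R{r}", block=f"R{r}", design="RCBD",
                    GY=m + rep_effects[r] + rng.normal(0, resid_sd),
                    DTF=np.nan, PH=np.nan,
                )
            )
    return pd.DataFrame(rows), means
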