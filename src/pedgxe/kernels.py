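"""Incidence matrices and covariance kernels for models M1-M7.

Each model is declared as a list of named variance components, every
component carrying an ``n_records x n_records`` covariance kernel built from
incidence matrices and relationship matrices:

* main effects: ``Z K Z'`` (environment: K = I, giving the block structure
  ``Z_E Z_E'``; additive line effect: K = A; GCA effects: K = A_P1 / A_P2),
* interactions: Hadamard (cell-by-cell) products of main-effect kernels,
  e.g. ``AxE = (Z_g A Z_g') # (Z_E Z_E')`` and the specific-combining-ability
  kernel ``SCA = (Z_P1 A_P1 Z_P1') # (Z_P2 A_P2 Z_P2')``.

The Schur product theorem keeps every Hadamard product of PSD kernels PSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import RelationshipMatrix

#: component lists per model id; order = order of terms in the linear predictor
MODEL_REGISTRY: dict[str, tuple[str, ...]] = {
    "M1": ("E", "A"),
    "M2": ("E", "A", "AxE"),
    "M3": ("E", "GCA1", "GCA2"),
    "M4": ("E", "GCA1", "GCA2", "SCA"),
    "M5": ("E", "GCA1", "GCA2", "SCA", "GCA1xE", "GCA2xE", "SCAxE"),
    "M6": ("E", "GCA1", "GCA2", "SCA", "GCA1xE", "GCA2xE", "AxE"),
    "M7": ("E", "GCA1", "GCA2", "A", "GCA1xE", "GCA2xE", "AxE"),
}

#: variance-component symbol carried by each kernel (reporting only)
VARIANCE_SYMBOLS: dict[str, str] = {
    "E": "sigma2_E",
    "A": "sigma2_a",
    "AxE": "sigma2_aE",
    "GCA1": "sigma2_aP1",
    "GCA2": "sigma2_aP2",
    "SCA": "sigma2_aP1xP2",
    "GCA1xE": "sigma2_aE_P1",
    "GCA2xE": "sigma2_aE_P2",
    "SCAxE": "sigma2_aE_P1xP2",
}

#: components that require resolved parents for every record
_PARENT_COMPONENTS = {"GCA1", "GCA2", "SCA", "GCA1xE", "GCA2xE", "SCAxE"}


class KernelError(ValueError):
    """Raised for inconsistent kernel construction input."""


@dataclass
class KernelComponent:
    """A named variance component: an n x n PSD covariance kernel."""

    name: str
    kernel: np.ndarray
    symbol: str = ""

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 2 or self.kernel.shape[0] != self.kernel.shape[1]:
            raise KernelError(f"component {self.name}: kernel must be square")
        if not self.symbol:
            self.symbol = VARIANCE_SYMBOLS.get(self.name, f"sigma2_{self.name}")

    @property
    def n(self) -> int:
        return self.kernel.shape[0]


@dataclass
class KernelSet:
    """Ordered collection of kernel components defining one model."""

    model_id: str
    components: list[KernelComponent]

    def __post_init__(self) -> None:
        ns = {c.n for c in self.components}
        if len(ns) > 1:
            raise KernelError(f"components disagree on record count: {ns}")

    @property
    def n_records(self) -> int:
        return self.components[0].n

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def __getitem__(self, name: str) -> KernelComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def export(self, directory) -> None:
        """Debug export: one TSV per component plus a JSON manifest."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c in self.components:
            np.savetxt(directory / f"{c.name}.tsv", c.kernel, delimiter="\t")
        manifest = {
            "model_id": self.model_id,
            "components": self.names,
            "n_records": self.n_records,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------
# building blocks


def incidence(records: pd.DataFrame, factor: str) -> tuple[np.ndarray, list]:
    """0/1 incidence matrix connecting records to the levels of ``factor``.

    Levels are sorted for a deterministic column order.  Returns the matrix
    and the level list.
    """
    if factor not in records.columns:
        raise KernelError(f"records lack a {factor!r} column")
    col = records[factor]
    if col.isna().any():
        bad = records.index[col.isna()].tolist()
        raise KernelError(f"records {bad} have no level for factor {factor!r}")
    levels = sorted(col.unique())
    index = {lv: j for j, lv in enumerate(levels)}
    Z = np.zeros((len(records), len(levels)))
    Z[np.arange(len(records)), [index[v] for v in col]] = 1.0
    return Z, levels


def main_effect_kernel(
    Z: np.ndarray,
    K: RelationshipMatrix | np.ndarray | None = None,
    name: str = "",
) -> KernelComponent:
    """``Z K Z'`` covariance kernel; ``K=None`` means identity (``Z Z'``)."""
    Z = np.asarray(Z, dtype=float)
    if K is None:
        kernel = Z @ Z.T
    else:
        Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K)
        if Kv.shape[0] != Z.shape[1]:
            raise KernelError(
                f"incidence has {Z.shape[1]} columns but K is {Kv.shape[0]}x"
                f"{Kv.shape[1]}"
            )
        kernel = Z @ Kv @ Z.T
    return KernelComponent(name or "main", kernel)


def hadamard_interaction(
    k1: KernelComponent, k2: KernelComponent, name: str = ""
) -> KernelComponent:
    """Entrywise (Hadamard) product of two kernels; PSD by Schur's theorem."""
    if k1.n != k2.n:
        raise KernelError(
            f"kernel dimensions differ: {k1.name}={k1.n}, {k2.name}={k2.n}"
        )
    return KernelComponent(name or f"{k1.name}x{k2.name}", k1.kernel * k2.kernel)


# ---------------------------------------------------------------------------
# model assembly


def build_model_kernels(
    model_id: str,
    records: pd.DataFrame,
    A: RelationshipMatrix | None = None,
    A_P1: RelationshipMatrix | None = None,
    A_P2: RelationshipMatrix | None = None,
) -> KernelSet:
    """Build the :class:`KernelSet` for one of M1-M7 over the given records.

    ``records`` must carry ``genotype`` and ``environment`` columns; models
    with combining-ability terms additionally need ``parent1``/``parent2``
    columns with a resolved parent for every record.
    """
    if model_id not in MODEL_REGISTRY:
        raise KernelError(
            f"unknown model {model_id!r}; expected one of {sorted(MODEL_REGISTRY)}"
        )
    wanted = MODEL_REGISTRY[model_id]
    needs_parents = bool(_PARENT_COMPONENTS & set(wanted))
    if needs_parents:
        for col in ("parent1", "parent2"):
            if col not in records.columns or records[col].isna().any():
                bad = (
                    sorted(records.loc[records[col].isna(), "genotype"].unique())
                    if col in records.columns
                    else sorted(records["genotype"].unique())
                )
                raise KernelError(
                    f"model {model_id} needs resolved parents; missing {col} "
                    f"for genotypes {bad[:10]}"
                )

    cache: dict[str, KernelComponent] = {}

    def env() -> KernelComponent:
        if "E" not in cache:
            Z_E, _ = incidence(records, "environment")
            cache["E"] = main_effect_kernel(Z_E, None, "E")
        return cache["E"]

    def additive() -> KernelComponent:
        if "A" not in cache:
            if A is None:
                raise KernelError(f"model {model_id} requires A")
            Z_g, levels = incidence(records, "genotype")
            cache["A"] = main_effect_kernel(Z_g, A.submatrix(levels), "A")
        return cache["A"]

    def gca(which: int) -> KernelComponent:
        key = f"GCA{which}"
        if key not in cache:
            AP = A_P1 if which == 1 else A_P2
            if AP is None:
                raise KernelError(f"model {model_id} requires A_P{which}")
            Z_P, levels = incidence(records, f"parent{which}")
            cache[key] = main_effect_kernel(Z_P, AP.submatrix(levels), key)
        return cache[key]

    components: list[KernelComponent] = []
    for name in wanted:
        if name == "E":
            comp = KernelComponent("E", env().kernel)
        elif name == "A":
            comp = KernelComponent("A", additive().kernel)
        elif name in ("GCA1", "GCA2"):
            comp = KernelComponent(name, gca(int(name[-1])).kernel)
        elif name == "AxE":
            comp = hadamard_interaction(additive(), env(), "AxE")
        elif name == "SCA":
            comp = hadamard_interaction(gca(1), gca(2), "SCA")
        elif name in ("GCA1xE", "GCA2xE"):
            comp = hadamard_interaction(gca(int(name[3])), env(), name)
        elif name == "SCAxE":
            sca = hadamard_interaction(gca(1), gca(2), "SCA")
            comp = hadamard_interaction(sca, env(), "SCAxE")
        else:  # pragma: no cover - registry and branches kept in sync
            raise KernelError(f"no builder for component {name!r}")
        components.append(comp)

    return KernelSet(model_id, components)
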