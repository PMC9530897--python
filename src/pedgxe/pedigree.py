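"""Pedigree handling and additive (numerator) relationship matrices.

The additive relationship matrix A holds expected additive genetic
relationships between lines: ``A[i, j] = 2 * kinship(i, j)`` and
``A[i, i] = 1 + F_i`` where ``F_i`` is the inbreeding coefficient.  It is
assembled with the tabular (recursive) method in topological pedigree order:

* founders: ``A[i, i] = 1``, relationship with anything earlier = 0,
* child k of parents (s, d): ``A[k, i] = 0.5 * (A[s, i] + A[d, i])`` for
  every earlier line i, and ``A[k, k] = 1 + 0.5 * A[s, d]``,
* an unknown parent contributes 0 (treated as an unrelated, non-inbred
  founder).

Deep pedigrees can be truncated: ancestors further than ``max_depth``
generations above every terminal (phenotyped) line are dropped and the
closest retained ancestors re-declared founders, mirroring breeding-database
extractions that only go a fixed number of generations up.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = "__UNKNOWN__"
DEFAULT_NA_TOKENS = ("NA", "", "0")
DEFAULT_MAX_DEPTH = 7


class PedigreeError(ValueError):
    """Raised for malformed or inconsistent pedigree input."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree row: a line and its two parents (or UNKNOWN)."""

    id: str
    parent1: str = UNKNOWN
    parent2: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("pedigree record with empty id")
        if self.id in (self.parent1, self.parent2):
            raise PedigreeError(f"line {self.id!r} listed as its own parent")


@dataclass
class Genealogy:
    """Validated, topologically ordered pedigree.

    Attributes
    ----------
    ordered_ids
        Ids with every parent preceding all of its offspring.
    parents
        id -> (parent1, parent2); founders map to (UNKNOWN, UNKNOWN).
    generation
        id -> integer depth; founders are generation 0 and
        ``generation(child) = 1 + max(generation(parents))``.
    truncated
        Ids that were re-declared founders by depth truncation.
    """

    ordered_ids: list[str]
    parents: dict[str, tuple[str, str]]
    generation: dict[str, int]
    truncated: set[str] = field(default_factory=set)

    @property
    def founders(self) -> list[str]:
        return [i for i in self.ordered_ids if self.generation[i] == 0]

    def __len__(self) -> int:
        return len(self.ordered_ids)

    def __contains__(self, line_id: str) -> bool:
        return line_id in self.parents


@dataclass
class RelationshipMatrix:
    """Symmetric PSD additive-relationship matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"relationship matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        self._index = {line_id: k for k, line_id in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate ids in relationship matrix")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = [self._index[i] for i in ids]
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def ensure_psd(self, tol: float = 1e-8) -> "RelationshipMatrix":
        """Add diagonal jitter if numerical error pushed an eigenvalue < -tol."""
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -tol:
            self.values = self.values + np.eye(len(self.ids)) * tol
        return self

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", float_format="%.12g", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# reading


def read_pedigree(
    source: str | Path | io.TextIOBase,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> list[PedigreeRecord]:
    """Read a three-column pedigree file (``id,parent1,parent2``).

    Comma- or tab-delimited, with a header row.  Tokens in ``na_tokens``
    (default ``NA``, empty, ``0``) mark an unknown parent.  Duplicate ids and
    self-parentage raise :class:`PedigreeError` naming the offender.
    """
    na = set(na_tokens)

    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PedigreeError("empty pedigree file")
    sep = "\t" if "\t" in lines[0] else ","

    records: list[PedigreeRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in raw.split(sep)]
        if len(parts) != 3:
            raise PedigreeError(
                f"line {lineno}: expected 3 columns, got {len(parts)}"
            )
        line_id, p1, p2 = parts
        if line_id in na or not line_id:
            raise PedigreeError(f"line {lineno}: missing line id")
        if line_id in seen:
            raise PedigreeError(f"duplicate id {line_id!r} (line {lineno})")
        seen.add(line_id)
        p1 = UNKNOWN if p1 in na else p1
        p2 = UNKNOWN if p2 in na else p2
        try:
            records.append(PedigreeRecord(line_id, p1, p2))
        except PedigreeError as exc:
            raise PedigreeError(f"line {lineno}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# genealogy construction


def _find_cycle(parents: dict[str, tuple[str, str]]) -> list[str]:
    """Return one parent->child cycle (ids in order) for the error message."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {i: WHITE for i in parents}
    stack: list[str] = []

    def dfs(node: str) -> list[str] | None:
        color[node] = GREY
        stack.append(node)
        for p in parents[node]:
            if p == UNKNOWN or p not in parents:
                continue
            if color[p] == GREY:
                return stack[stack.index(p):] + [p]
            if color[p] == WHITE:
                found = dfs(p)
                if found:
                    return found
        stack.pop()
        color[node] = BLACK
        return None

    for start in parents:
        if color[start] == WHITE:
            cyc = dfs(start)
            if cyc:
                return cyc
    return []


def build_genealogy(
    records: Sequence[PedigreeRecord],
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> Genealogy:
    """Validate, topologically order and depth-truncate a pedigree.

    Parents referenced but never listed as rows are added as founders.
    ``max_depth`` counts generations upward from the terminal (childless,
    i.e. phenotyped) lines: an ancestor more than ``max_depth`` steps above
    every terminal descendant is dropped and its nearest retained
    descendants become founders.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")

    parents: dict[str, tuple[str, str]] = {}
    for rec in records:
        parents[rec.id] = (rec.parent1, rec.parent2)
    # implicit founders: referenced parents without their own row
    for rec in records:
        for p in (rec.parent1, rec.parent2):
            if p != UNKNOWN and p not in parents:
                parents[p] = (UNKNOWN, UNKNOWN)

    # Kahn topological sort over parent -> child edges
    children: dict[str, list[str]] = {i: [] for i in parents}
    indeg: dict[str, int] = {i: 0 for i in parents}
    for child, (p1, p2) in parents.items():
        for p in (p1, p2):
            if p != UNKNOWN:
                children[p].append(child)
                indeg[child] += 1
    queue = deque(sorted(i for i, d in indeg.items() if d == 0))
    ordered: list[str] = []
    while queue:
        node = queue.popleft()
        ordered.append(node)
        for ch in children[node]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                queue.append(ch)
    if len(ordered) != len(parents):
        cyc = _find_cycle(parents)
        raise PedigreeError(
            "pedigree contains a cycle: " + " -> ".join(cyc)
        )

    # distance down to the nearest terminal descendant
    terminal = {i for i in parents if not children[i]}
    dist = {i: (0 if i in terminal else None) for i in parents}
    for node in reversed(ordered):
        if dist[node] is None:
            ds = [dist[c] for c in children[node] if dist[c] is not None]
            dist[node] = min(ds) + 1 if ds else 0

    keep = {i for i in parents if dist[i] <= max_depth}
    truncated: set[str] = set()
    new_parents: dict[str, tuple[str, str]] = {}
    for i in keep:
        p1, p2 = parents[i]
        kp1 = p1 if p1 != UNKNOWN and p1 in keep else UNKNOWN
        kp2 = p2 if p2 != UNKNOWN and p2 in keep else UNKNOWN
        if (kp1, kp2) != (p1, p2):
            truncated.add(i)
        new_parents[i] = (kp1, kp2)

    ordered = [i for i in ordered if i in keep]
    generation: dict[str, int] = {}
    for i in ordered:
        p1, p2 = new_parents[i]
        gens = [generation[p] for p in (p1, p2) if p != UNKNOWN]
        generation[i] = 1 + max(gens) if gens else 0

    return Genealogy(ordered, new_parents, generation, truncated)


# ---------------------------------------------------------------------------
# relationship matrices


def additive_relationship(g: Genealogy) -> RelationshipMatrix:
    """Tabular-method additive relationship matrix over the genealogy."""
    ids = g.ordered_ids
    n = len(ids)
    index = {line_id: k for k, line_id in enumerate(ids)}
    A = np.zeros((n, n))
    for k, line_id in enumerate(ids):
        p1, p2 = g.parents[line_id]
        i1 = index.get(p1, -1) if p1 != UNKNOWN else -1
        i2 = index.get(p2, -1) if p2 != UNKNOWN else -1
        row = np.zeros(k)
        if i1 >= 0:
            row += 0.5 * A[i1, :k]
        if i2 >= 0:
            row += 0.5 * A[i2, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[i1, i2] if i1 >= 0 and i2 >= 0 else 0.0)
    return RelationshipMatrix(list(ids), A).ensure_psd()


def parent_relationship_matrices(
    phenotyped_crosses: Sequence[tuple[str, str, str]],
    g: Genealogy,
    A: RelationshipMatrix | None = None,
) -> tuple[RelationshipMatrix, RelationshipMatrix, dict]:
    """Parent-set relationship matrices for GCA/SCA models.

    Parameters
    ----------
    phenotyped_crosses
        ``(line_id, parent1, parent2)`` triples for the phenotyped lines.
    g
        Genealogy containing the parents.
    A
        Precomputed full relationship matrix; computed from ``g`` if omitted.

    Returns
    -------
    (A_P1, A_P2, info) where ``A_P1``/``A_P2`` are sub-matrices of the full A
    over the distinct parent-1 / parent-2 identities and ``info`` carries
    ``parent1_of``/``parent2_of`` maps plus an ``excluded`` report of lines
    whose parents could not be resolved.
    """
    if A is None:
        A = additive_relationship(g)

    excluded: list[tuple[str, str]] = []
    parent1_of: dict[str, str] = {}
    parent2_of: dict[str, str] = {}
    for line_id, p1, p2 in phenotyped_crosses:
        if p1 == UNKNOWN or p1 not in g:
            excluded.append((line_id, "parent1 unresolved"))
            continue
        if p2 == UNKNOWN or p2 not in g:
            excluded.append((line_id, "parent2 unresolved"))
            continue
        parent1_of[line_id] = p1
        parent2_of[line_id] = p2

    p1_ids = sorted(set(parent1_of.values()))
    p2_ids = sorted(set(parent2_of.values()))
    if not p1_ids or not p2_ids:
        raise PedigreeError("no crosses with both parents resolvable")

    info = {
        "parent1_of": parent1_of,
        "parent2_of": parent2_of,
        "excluded": excluded,
    }
    return A.submatrix(p1_ids), A.submatrix(p2_ids), info


def crosses_from_genealogy(
    g: Genealogy, line_ids: Sequence[str]
) -> list[tuple[str, str, str]]:
    """Convenience: ``(id, parent1, parent2)`` triples for the given lines."""
    return [(i, g.parents[i][0], g.parents[i][1]) for i in line_ids]
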