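"""Pedigree parsing and the numerator relationship matrix (tabular method)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = "0"


@dataclass
class Pedigree:
    """Topologically ordered pedigree; parent indices are -1 when unknown."""

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = self.ids.shape[0]
        if self.sire.shape[0] != n or self.dam.shape[0] != n:
            raise ValueError("parent arrays must match id count")
        for j in range(n):
            if self.sire[j] >= j or self.dam[j] >= j:
                raise ValueError("pedigree is not topologically sorted (parent after child)")

    @property
    def n(self) -> int:
        return self.ids.shape[0]

    def index_of(self, ids: Iterable) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        return np.array([lookup[i] for i in ids], dtype=np.int64)


@dataclass
class RelationshipMatrix:
    ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.ids.shape[0], self.ids.shape[0]):
            raise ValueError("matrix must be square over the pedigree ids")

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.values)


def _normalize(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return UNKNOWN
    s = str(v).strip()
    return s if s and s.lower() not in ("nan", "na") else UNKNOWN


def sort_pedigree(records) -> Pedigree:
    """Topologically sort (id, sire, dam) records; reject cycles and duplicates.

    Accepts a DataFrame with columns id/sire/dam or an iterable of triples.
    Parents referenced but not listed are appended as founders.  The sort is
    stable: founders and already-ordered records keep their relative order.
    """
    if isinstance(records, pd.DataFrame):
        rows = [(r.id, r.sire, r.dam) for r in records.itertuples(index=False)]
    else:
        rows = [tuple(r) for r in records]
    ids, sires, dams = [], [], []
    seen = set()
    for rid, s, d in rows:
        rid, s, d = _normalize(rid), _normalize(s), _normalize(d)
        if rid == UNKNOWN:
            raise ValueError("individual id cannot be the unknown sentinel")
        if rid in seen:
            raise ValueError(f"duplicate pedigree id: {rid}")
        seen.add(rid)
        ids.append(rid)
        sires.append(s)
        dams.append(d)
    # implicit founders for parents that never appear as records
    for p in [p for pair in zip(sires, dams) for p in pair]:
        if p != UNKNOWN and p not in seen:
            seen.add(p)
            ids.insert(0, p)
            sires.insert(0, UNKNOWN)
            dams.insert(0, UNKNOWN)

    parent_map = {i: (s, d) for i, s, d in zip(ids, sires, dams)}
    order: list[str] = []
    placed: set[str] = set()
    state: dict[str, int] = {}

    def visit(node: str, stack: list[str]) -> None:
        if state.get(node) == 1:
            raise ValueError(f"pedigree cycle detected involving {node}")
        if state.get(node) == 2:
            return
        state[node] = 1
        for p in parent_map[node]:
            if p != UNKNOWN:
                visit(p, stack + [node])
        state[node] = 2
        order.append(node)
        placed.add(node)

    for node in ids:
        visit(node, [])

    pos = {v: i for i, v in enumerate(order)}
    sire_idx = np.array([pos[parent_map[v][0]] if parent_map[v][0] != UNKNOWN else -1
                         for v in order], dtype=np.int64)
    dam_idx = np.array([pos[parent_map[v][1]] if parent_map[v][1] != UNKNOWN else -1
                        for v in order], dtype=np.int64)
    return Pedigree(ids=np.asarray(order, dtype=object), sire=sire_idx, dam=dam_idx)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular recursion.

    A[j,j] = 1 + 0.5 * A[sire(j), dam(j)] (term 0 if a parent is unknown);
    A[i,j] = 0.5 * (A[i, sire(j)] + A[i, dam(j)]).  Inbreeding is implicit.
    """
    n = ped.n
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        A[j, j] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for i in range(j):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[i, s]
            if d >= 0:
                val += 0.5 * A[i, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(ids=ped.ids, values=A)


def write_A_triplets(A: RelationshipMatrix, path) -> None:
    """Sparse triplet text: id_i id_j value, upper triangle, non-zeros only."""
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tvalue\n")
        n = A.ids.shape[0]
        for i in range(n):
            for j in range(i, n):
                if A.values[i, j] != 0.0:
                    fh.write(f"{A.ids[i]}\t{A.ids[j]}\t{A.values[i, j]:.12g}\n")
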