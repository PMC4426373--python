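"""Pedigree parsing and additive genetic relationship structures.

A pedigree here is the three-generation experimental design of the study
population (wild P1 founders, F1 and F2 captive progeny), but the code is
generic: any acyclic sire/dam table works.  The numerator relationship
matrix A holds expected additive relationships a_ij; its diagonal is
1 + F_i with F_i the inbreeding coefficient.  Founders (unknown parents)
are treated as non-inbred and mutually unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse as sp

CROSS_TYPES = ("AxA", "AxR", "RxA", "RxR", "ARxAR", "RAxRA", "founder")

UNKNOWN = -1  # integer code for an unknown parent


class PedigreeError(ValueError):
    """Raised for invalid pedigrees (duplicates, missing parents, cycles)."""


@dataclass
class Pedigree:
    """A validated pedigree in topological order (parents before offspring).

    Attributes
    ----------
    ids : list of str
        Individual identifiers, topologically sorted.
    sire, dam : ndarray of int
        Positional parent indices into ``ids``; ``-1`` marks an unknown
        (founder) parent.
    generation, cross_type, family : ndarray of object
        Per-individual labels carried through from the input table.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray = None
    cross_type: np.ndarray = None
    family: np.ndarray = None
    _index: dict = field(default=None, repr=False)

    def __post_init__(self):
        if self._index is None:
            self._index = {iid: i for i, iid in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, iid) -> int:
        return self._index[iid]

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficients F (Meuwissen–Luo)."""
        return _inbreeding_ml(self.sire, self.dam)

    def to_frame(self) -> pd.DataFrame:
        """Round-trip back to the pedigree CSV column layout."""
        sid = ["0" if s == UNKNOWN else self.ids[s] for s in self.sire]
        did = ["0" if d == UNKNOWN else self.ids[d] for d in self.dam]
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": sid,
                "dam": did,
                "generation": self.generation,
                "cross_type": self.cross_type,
                "family": self.family,
            }
        )


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix aligned with a Pedigree."""

    ids: list
    values: np.ndarray

    @property
    def order(self) -> int:
        return len(self.ids)

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0

    def loc(self, i, j) -> float:
        idx = {iid: k for k, iid in enumerate(self.ids)}
        return self.values[idx[i], idx[j]]


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Validate a pedigree table and return it in topological order.

    Unknown parents are coded ``0``, empty, or NA.  Raises
    :class:`PedigreeError` naming the offending ids for duplicates, missing
    parent records, or cycles.
    """
    df = df.copy()
    df["id"] = df["id"].astype(str).str.strip()
    for col in ("sire", "dam"):
        df[col] = df[col].fillna("0").astype(str).str.strip().replace("", "0")

    ids = df["id"].tolist()
    seen = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise PedigreeError(f"duplicate individual ids: {dups}")
    idset = set(ids)
    missing = sorted(
        {p for p in pd.concat([df["sire"], df["dam"]]) if p != "0" and p not in idset}
    )
    if missing:
        raise PedigreeError(f"named parents without a record: {missing}")

    # Kahn topological sort, stable in input order.
    pos = {iid: k for k, iid in enumerate(ids)}
    parents = {
        iid: [p for p in (s, d) if p != "0"]
        for iid, s, d in zip(ids, df["sire"], df["dam"])
    }
    children: dict = {iid: [] for iid in ids}
    indeg = {}
    for iid, ps in parents.items():
        indeg[iid] = len(ps)
        for p in ps:
            children[p].append(iid)
    ready = sorted((iid for iid in ids if indeg[iid] == 0), key=pos.get)
    order = []
    import heapq

    heap = [pos[i] for i in ready]
    heapq.heapify(heap)
    while heap:
        k = heapq.heappop(heap)
        iid = ids[k]
        order.append(iid)
        for ch in children[iid]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                heapq.heappush(heap, pos[ch])
    if len(order) != len(ids):
        cyc = sorted(i for i in ids if indeg[i] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving: {cyc}")

    df = df.set_index("id").loc[order].reset_index()
    new_index = {iid: k for k, iid in enumerate(order)}
    sire = np.array(
        [UNKNOWN if s == "0" else new_index[s] for s in df["sire"]], dtype=np.int64
    )
    dam = np.array(
        [UNKNOWN if d == "0" else new_index[d] for d in df["dam"]], dtype=np.int64
    )

    def col(name):
        return df[name].to_numpy() if name in df else np.array([None] * len(order))

    return Pedigree(
        ids=order,
        sire=sire,
        dam=dam,
        generation=col("generation"),
        cross_type=col("cross_type"),
        family=col("family"),
    )


def read_pedigree(path) -> Pedigree:
    """Read the pedigree CSV dialect (``id,sire,dam,generation,cross_type,family``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree file must have columns {sorted(required)}")
    return pedigree_from_frame(df)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the recursive tabular method.

    Processing individuals in topological order:
    a_ii = 1 + 0.5 * a(sire_i, dam_i) and a_ij = 0.5 * (a(j, sire_i) +
    a(j, dam_i)) for j earlier than i; unknown parents contribute zero.
    """
    n = ped.n
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si == UNKNOWN and di == UNKNOWN:
            A[i, i] = 1.0
            continue
        row = np.zeros(i)
        if si != UNKNOWN:
            row += A[si, :i]
        if di != UNKNOWN:
            row += A[di, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si != UNKNOWN and di != UNKNOWN) else 0.0)
    return RelationshipMatrix(ids=list(ped.ids), values=A)


def _inbreeding_ml(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Meuwissen & Luo style inbreeding via diagonal of the tabular A.

    O(n * depth^2) worst case; avoids the dense n x n table so it scales to
    the full 16k-individual study pedigree.
    """
    n = len(sire)
    F = np.zeros(n)
    # L[i] caches the relationship of i to each of its ancestors lazily via
    # recursion on kinship f(i, j).
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def kin(i: int, j: int) -> float:
        if i == UNKNOWN or j == UNKNOWN:
            return 0.0
        if i == j:
            si, di = sire[i], dam[i]
            return 0.5 * (1.0 + kin(si, di))
        if i < j:
            i, j = j, i
        return 0.5 * (kin(sire[i], j) + kin(dam[i], j))

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 1000))
    try:
        for i in range(n):
            F[i] = kin(sire[i], dam[i]) if (sire[i] != UNKNOWN or dam[i] != UNKNOWN) else 0.0
    finally:
        sys.setrecursionlimit(old)
    return F


def sparse_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Inverse of the numerator relationship matrix by Henderson's rules.

    Uses per-individual Mendelian-sampling variances with inbreeding:
    d_i = 0.5 - 0.25 * (F_s + F_d) over known parents.  The product with
    :func:`relationship_matrix` output is the identity to 1e-8.
    """
    n = ped.n
    F = ped.inbreeding()
    s, d = ped.sire, ped.dam
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        fs = F[si] if si != UNKNOWN else 0.0
        fd = F[di] if di != UNKNOWN else 0.0
        nk = (si != UNKNOWN) + (di != UNKNOWN)
        dii = 1.0 - 0.25 * ((1 + fs) if si != UNKNOWN else 0.0) - 0.25 * (
            (1 + fd) if di != UNKNOWN else 0.0
        )
        # dii reduces to 1, 0.75 - F_p/4, or 0.5 - (Fs+Fd)/4 for 0/1/2 known parents
        w = 1.0 / dii
        add(i, i, w)
        for p in (si, di):
            if p != UNKNOWN:
                add(p, i, -0.5 * w)
                add(i, p, -0.5 * w)
        for p in (si, di):
            if p != UNKNOWN:
                for q in (si, di):
                    if q != UNKNOWN:
                        add(p, q, 0.25 * w)
    Ainv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Ainv.sum_duplicates()
    if not np.all(np.isfinite(Ainv.data)):
        raise PedigreeError("numerical failure building the sparse A-inverse")
    return Ainv
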