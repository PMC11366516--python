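"""Pedigrees and the numerator relationship matrix A.

The additive (numerator) relationship matrix A underlies both pedigree BLUP
and the pedigree part of the single-step H matrix.  A is built by the tabular
method, its sparse inverse by Henderson's rules with inbreeding coefficients
from the Meuwissen–Luo recursion, and A22 is the submatrix for genotyped
animals.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: sentinel for an unknown parent in input files
UNKNOWN = "0"


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree.

    ``sire`` / ``dam`` hold positional indices into ``ids`` (-1 = unknown);
    parents always precede their offspring.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            object.__setattr__(self, "index", {a: i for i, a in enumerate(self.ids)})

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, str]], unknown_code: str = UNKNOWN
    ) -> "Pedigree":
        """Validate, complete, and topologically order raw (animal, sire, dam) rows.

        Parents that are referenced but never listed as animals are appended
        as founders.  Duplicate animal ids and pedigree cycles (an animal
        being its own ancestor) raise ``ValueError``.
        """
        animals = [str(r[0]) for r in records]
        if len(set(animals)) != len(animals):
            dups = {a for a in animals if animals.count(a) > 1}
            raise ValueError(f"duplicate animal id(s): {sorted(dups)}")
        parent_of: dict[str, tuple[str, str]] = {}
        for a, s, d in records:
            a, s, d = str(a), str(s), str(d)
            s = "" if s == unknown_code or s == "" else s
            d = "" if d == unknown_code or d == "" else d
            if s == a or d == a:
                raise ValueError(f"animal {a!r} listed as its own parent")
            parent_of[a] = (s, d)
        # referenced-but-unlisted parents become founders
        for s, d in list(parent_of.values()):
            for p in (s, d):
                if p and p not in parent_of:
                    parent_of[p] = ("", "")
        ts = TopologicalSorter(
            {a: [p for p in ps if p] for a, ps in parent_of.items()}
        )
        try:
            order = list(ts.static_order())
        except CycleError as exc:
            raise ValueError(f"cyclic pedigree: {exc.args[1]}") from exc
        index = {a: i for i, a in enumerate(order)}
        sire = np.array(
            [index[parent_of[a][0]] if parent_of[a][0] else -1 for a in order],
            dtype=np.int64,
        )
        dam = np.array(
            [index[parent_of[a][1]] if parent_of[a][1] else -1 for a in order],
            dtype=np.int64,
        )
        return cls(ids=tuple(order), sire=sire, dam=dam, index=index)

    def parents_of(self, animal_id: str) -> tuple[str | None, str | None]:
        i = self.index[animal_id]
        s, d = self.sire[i], self.dam[i]
        return (self.ids[s] if s >= 0 else None, self.ids[d] if d >= 0 else None)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Symmetric additive-relationship matrix keyed by animal ids.

    ``values`` is dense (tabular A, A22) or sparse CSR (Henderson A inverse,
    single-step H inverse).
    """

    ids: tuple[str, ...]
    values: np.ndarray | sp.spmatrix

    @property
    def n(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)


def read_pedigree(path, unknown_code: str = UNKNOWN) -> Pedigree:
    """Read a pedigree CSV with columns ``animal,sire,dam``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree CSV must have columns {sorted(required)}")
    recs = list(df[["animal", "sire", "dam"]].itertuples(index=False, name=None))
    return Pedigree.from_records(recs, unknown_code=unknown_code)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen–Luo recursion.

    F_i = a(sire, dam)/2 is computed from the within-individual sum
    a_ii = sum_j L_ij^2 D_j over ancestors, processed youngest-first.
    Founders and animals with an unknown parent have F = 0.
    """
    n = ped.n
    F = np.zeros(n)
    D = np.zeros(n)

    def f_of(j: int) -> float:
        # Mrode's convention: an unknown parent contributes F = -1, which
        # folds the one/none-known Mendelian variance cases into one formula
        return F[j] if j >= 0 else -1.0

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        D[i] = 0.5 - 0.25 * (f_of(s) + f_of(d))
        if s < 0 or d < 0:
            continue
        # accumulate a_ii = 1 + F_i by walking the ancestor closure
        coeff: dict[int, float] = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            c = coeff.pop(j, 0.0)
            if c == 0.0:
                continue
            aii += c * c * D[j]
            for p in (ped.sire[j], ped.dam[j]):
                if p >= 0:
                    if p not in coeff:
                        heapq.heappush(heap, -int(p))
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * c
        F[i] = aii - 1.0
    return F


def numerator_matrix(
    ped: Pedigree, subset: Sequence[str] | None = None
) -> RelationshipMatrix:
    """Tabular-method A, or the submatrix A22 for ``subset`` (in subset order).

    a_ij = (a_{i,sire(j)} + a_{i,dam(j)})/2 for j != i and
    a_jj = 1 + a_{sire(j),dam(j)}/2, with unknown-parent terms zero.
    """
    n = ped.n
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire[j], ped.dam[j]
        row = np.zeros(j)
        if s >= 0:
            row += 0.5 * A[:j, s]
        if d >= 0:
            row += 0.5 * A[:j, d]
        A[:j, j] = row
        A[j, :j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    if subset is None:
        return RelationshipMatrix(ids=ped.ids, values=A)
    missing = [a for a in subset if a not in ped.index]
    if missing:
        raise KeyError(f"subset ids not in pedigree: {missing[:5]}")
    pos = [ped.index[a] for a in subset]
    return RelationshipMatrix(ids=tuple(subset), values=A[np.ix_(pos, pos)])


def a_inverse(ped: Pedigree, use_inbreeding: bool = True) -> RelationshipMatrix:
    """Sparse A inverse by Henderson's rules.

    Each animal contributes a triplet pattern scaled by the inverse of its
    Mendelian-sampling variance; with ``use_inbreeding`` the variance uses the
    parents' F (BLUPF90-style), otherwise F = 0 is assumed throughout.
    """
    n = ped.n
    F = inbreeding(ped) if use_inbreeding else np.zeros(n)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        if s >= 0 and d >= 0:
            mend = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mend = 0.75 - 0.25 * F[p]
        else:
            mend = 1.0
        alpha = 1.0 / mend
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * alpha)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(ids=ped.ids, values=Ainv)
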