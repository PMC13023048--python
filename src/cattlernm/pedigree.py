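"""Numerator relationship matrix A, its sparse inverse and inbreeding.

The pedigree is held as integer parent indices in topological order
(parents precede offspring, -1 = unknown).  A is built by the tabular
method only for small problems (test oracle); the model consumes the
Henderson sparse inverse with inbreeding, where per-animal Mendelian
sampling variances d_i = 0.5 - 0.25 (F_s + F_d) come from the
Meuwissen-Luo recursion.  Unknown parents are one phantom founder
population (no genetic groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

A_DENSE_CAP = 5000


class PedigreeError(ValueError):
    pass


@dataclass
class PedigreeTable:
    """Topologically sorted pedigree: ids plus parent indices (-1 unknown)."""

    ids: np.ndarray            # object/str array, length n
    sire: np.ndarray           # int indices into ids, -1 unknown
    dam: np.ndarray
    meta: pd.DataFrame | None = None  # optional per-animal metadata, same order
    index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.index = {a: i for i, a in enumerate(self.ids)}
        n = len(self.ids)
        if len(self.index) != n:
            raise PedigreeError("duplicate animal ids")
        for p in (self.sire, self.dam):
            if np.any(p >= np.arange(n)):
                raise PedigreeError("pedigree not topologically sorted")

    def __len__(self) -> int:
        return len(self.ids)

    def generation_depth(self) -> np.ndarray:
        """Per-animal number of ancestral generations (founder = 0)."""
        n = len(self)
        depth = np.zeros(n, dtype=np.int64)
        for i in range(n):
            ds = depth[self.sire[i]] + 1 if self.sire[i] >= 0 else 0
            dd = depth[self.dam[i]] + 1 if self.dam[i] >= 0 else 0
            depth[i] = max(ds, dd)
        return depth


def validate_and_sort(raw: pd.DataFrame, *, on_parent_after_offspring: str = "error"
                      ) -> PedigreeTable:
    """Build a :class:`PedigreeTable` from columns animal/sire/dam.

    Unknown parents are NA, empty or '0'.  Animals appearing only as
    parents are added as founders.  Orders parents before offspring; a
    parentage cycle raises :class:`PedigreeError` naming the animals
    involved.  If birth_date is present, a parent born after its
    offspring raises (``on_parent_after_offspring='error'``) or has the
    link severed (``'coerce-unknown'``).
    """
    def norm(v):
        if pd.isna(v) or v in ("", "0", 0):
            return None
        return v

    animals = list(raw["animal"])
    if len(set(animals)) != len(animals):
        raise PedigreeError("duplicate animal ids in pedigree input")
    parents = {a: (norm(s), norm(d)) for a, s, d in
               zip(raw["animal"], raw["sire"], raw["dam"])}
    for a in list(parents):
        for p in parents[a]:
            if p is not None and p not in parents:
                parents[p] = (None, None)
                animals.append(p)

    if "birth_date" in raw.columns:
        born = dict(zip(raw["animal"], pd.to_datetime(raw["birth_date"], errors="coerce")))
        for a, (s, d) in list(parents.items()):
            ba = born.get(a)
            fixed = []
            for p in (s, d):
                bp = born.get(p) if p is not None else None
                if p is not None and ba is not None and bp is not None and bp > ba:
                    if on_parent_after_offspring == "error":
                        raise PedigreeError(f"parent {p} born after offspring {a}")
                    p = None  # coerce-unknown
                fixed.append(p)
            parents[a] = tuple(fixed)

    # Kahn topological sort, deterministic (input order as tie-break)
    order: list = []
    state = {a: 0 for a in animals}  # 0 unvisited, 1 in stack, 2 done

    def visit(a, chain):
        if state[a] == 2:
            return
        if state[a] == 1:
            k = chain.index(a)
            raise PedigreeError(f"pedigree cycle: {' -> '.join(map(str, chain[k:] + [a]))}")
        state[a] = 1
        chain.append(a)
        for p in parents[a]:
            if p is not None:
                visit(p, chain)
        chain.pop()
        state[a] = 2
        order.append(a)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(animals) + 1000))
    try:
        for a in animals:
            visit(a, [])
    finally:
        sys.setrecursionlimit(old)

    idx = {a: i for i, a in enumerate(order)}
    sire = np.array([idx[parents[a][0]] if parents[a][0] is not None else -1 for a in order])
    dam = np.array([idx[parents[a][1]] if parents[a][1] is not None else -1 for a in order])
    meta = None
    if raw.columns.difference(["animal", "sire", "dam"]).size:
        meta = raw.set_index("animal").reindex(order).reset_index(names="animal")
    return PedigreeTable(np.array(order, dtype=object), sire, dam, meta)


@njit(cache=True)
def _inbreeding_ml(sire, dam):
    """Meuwissen & Luo recursion: F plus Mendelian variances d_i.

    a(i,i) = sum_k T_ik^2 d_k over ancestors k (A = T D T'), traced with a
    descending-index linked list, so F_i = a(i,i) - 1.  Unknown parents
    enter d_i with F = -1 (d gains 0.25 per unknown parent).
    """
    n = sire.shape[0]
    f = np.zeros(n)
    d = np.zeros(n)
    anc_v = np.zeros(n)               # path coefficient per ancestor
    nxt = np.full(n, -1, dtype=np.int64)  # linked list, descending index
    for i in range(n):
        s, dd = sire[i], dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[dd] if dd >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or dd < 0:
            f[i] = 0.0  # phantom parents unrelated
            continue
        fi = -1.0
        anc_v[i] = 1.0
        head = i
        while head != -1:
            k = head
            r = anc_v[k]
            anc_v[k] = 0.0
            head = nxt[k]
            nxt[k] = -1
            fi += r * r * d[k]
            for p in (sire[k], dam[k]):
                if p >= 0:
                    if anc_v[p] == 0.0:
                        if head == -1 or p > head:
                            nxt[p] = head
                            head = p
                        else:
                            q = head
                            while nxt[q] != -1 and nxt[q] > p:
                                q = nxt[q]
                            nxt[p] = nxt[q]
                            nxt[q] = p
                    anc_v[p] += 0.5 * r
        f[i] = fi
    return f, d


def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients F (Meuwissen-Luo)."""
    f, _ = _inbreeding_and_d(ped)
    return f


def _inbreeding_and_d(ped: PedigreeTable) -> tuple[np.ndarray, np.ndarray]:
    f, d = _inbreeding_ml(ped.sire, ped.dam)
    return f, d


def build_a_matrix(ped: PedigreeTable) -> np.ndarray:
    """Dense A by the tabular method (test oracle; capped at 5000 animals).

    a(i,i) = 1 + 0.5 a(s,d); a(i,j) = 0.5 (a(j,s) + a(j,d)); unknown
    parents contribute zero.
    """
    n = len(ped)
    if n > A_DENSE_CAP:
        raise MemoryError(
            f"dense A capped at {A_DENSE_CAP} animals (n={n}); use build_a_inverse"
        )
    a = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        asd = a[s[i], d[i]] if (s[i] >= 0 and d[i] >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * asd
        row = np.zeros(i)
        if s[i] >= 0:
            row += a[s[i], :i]
        if d[i] >= 0:
            row += a[d[i], :i]
        a[i, :i] = a[:i, i] = 0.5 * row
    return a


def build_a_inverse(ped: PedigreeTable, f: np.ndarray | None = None
                    ) -> tuple[sparse.csr_matrix, np.ndarray, float]:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Per animal: alpha_i = 1/d_i with d_i = 0.5 - 0.25 (F_s + F_d)
    (unknown parent contributes F = -1, i.e. d gains 0.25).  Each animal's
    contribution touches only the {animal, sire, dam} 3x3 block.

    Returns (A_inverse, F, logdet_A); log|A| = sum log d_i since
    A = T D T' with unit-triangular T.
    """
    f_ml, d = _inbreeding_and_d(ped)
    if f is None:
        f = f_ml
    n = len(ped)
    rows, cols, vals = [], [], []
    s, dd = ped.sire, ped.dam
    alpha = 1.0 / d
    for i in range(n):
        par = [p for p in (s[i], dd[i]) if p >= 0]
        rows.append(i); cols.append(i); vals.append(alpha[i])
        for p in par:
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * alpha[i]] * 2
        for p in par:
            for q in par:
                rows.append(p); cols.append(q); vals.append(0.25 * alpha[i])
    ainv = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    ainv.sum_duplicates()
    return ainv, f, float(np.sum(np.log(d)))


def write_a_inverse(ainv: sparse.spmatrix, path) -> None:
    """Coordinate-format text export (row, col, value), lower triangle."""
    coo = sparse.tril(ainv).tocoo()
    with open(path, "w") as fh:
        fh.write("row,col,value\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i},{j},{v!r}\n")


def pedigree_summary(ped: PedigreeTable) -> dict:
    """Basic depth/completeness statistics."""
    depth = ped.generation_depth()
    known_s = int((ped.sire >= 0).sum())
    known_d = int((ped.dam >= 0).sum())
    n = len(ped)
    return {
        "n_animals": n,
        "mean_depth": float(depth.mean()),
        "max_depth": int(depth.max()),
        "prop_known_sire": known_s / n,
        "prop_known_dam": known_d / n,
    }
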