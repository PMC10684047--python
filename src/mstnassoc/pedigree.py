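"""Numerator relationship matrix machinery.

The additive genetic covariance among animals implied by a pedigree is
``A * sigma2_g`` where A is the numerator relationship matrix.  The mixed
models in this package never form A explicitly at scale: they use its sparse
inverse, assembled by Henderson's rules with inbreeding accounted for via
the Meuwissen–Luo recursion for the Mendelian-sampling variances.

Identifiers are arbitrary (ints or strings); a :class:`Pedigree` recodes
them to a topological order in which parents precede offspring, with ties
broken by birth date and then identifier, so the sparse structures are
deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Recoded pedigree: ``sire[i]``/``dam[i]`` are positions or -1 (unknown).

    ``ids`` lists the original identifiers in the internal (topological)
    order; all package code indexes animals by this order.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    birth_date: pd.Series | None = None
    sex: pd.Series | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def indices_of(self, animals) -> np.ndarray:
        return np.array([self._index[a] for a in animals], dtype=np.int64)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire < 0) & (self.dam < 0)))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a table with columns animal, sire, dam and optionally
        birth_date and sex.  Unknown parents are NA/empty/0.
        """
        df = frame.copy()
        for col in ("animal", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree table lacks required column {col!r}")
        animals = df["animal"].tolist()
        if len(set(animals)) != len(animals):
            raise PedigreeError("duplicate animal identifiers in pedigree")
        known = set(animals)

        def parent_of(row, col):
            v = row[col]
            if pd.isna(v) or v == 0 or v == "" or v == "0":
                return None
            return v

        parents = {}
        for _, row in df.iterrows():
            a = row["animal"]
            s = parent_of(row, "sire")
            d = parent_of(row, "dam")
            if a == s or a == d:
                raise PedigreeError(f"animal {a!r} is its own parent")
            if s is not None and s == d:
                raise PedigreeError(f"animal {a!r} has identical sire and dam {s!r}")
            parents[a] = (s if s in known else None, d if d in known else None)

        # Kahn topological sort; deterministic tie-break by (birth_date, id).
        bd = {}
        if "birth_date" in df.columns:
            bdser = pd.to_datetime(df["birth_date"], errors="coerce")
            bd = dict(zip(animals, bdser))
        sortkey = {a: (bd.get(a, pd.NaT), str(a)) for a in animals}

        children: dict = {a: [] for a in animals}
        indeg = {a: 0 for a in animals}
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p is not None:
                    children[p].append(a)
                    indeg[a] += 1
        ready = sorted(
            (a for a in animals if indeg[a] == 0),
            key=lambda a: (pd.isna(sortkey[a][0]), sortkey[a]),
        )
        heap = [((pd.isna(sortkey[a][0]), str(sortkey[a][0]), sortkey[a][1]), a) for a in ready]
        heapq.heapify(heap)
        order = []
        while heap:
            _, a = heapq.heappop(heap)
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    k = sortkey[c]
                    heapq.heappush(heap, ((pd.isna(k[0]), str(k[0]), k[1]), c))
        if len(order) != len(animals):
            cyc = _find_cycle(parents, set(order), animals)
            raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(map(str, cyc))}")

        idx = {a: i for i, a in enumerate(order)}
        sire = np.full(len(order), -1, dtype=np.int64)
        dam = np.full(len(order), -1, dtype=np.int64)
        for a, (s, d) in parents.items():
            if s is not None:
                sire[idx[a]] = idx[s]
            if d is not None:
                dam[idx[a]] = idx[d]
        birth = None
        if bd:
            birth = pd.Series([bd.get(a, pd.NaT) for a in order], index=order)
        sex = None
        if "sex" in df.columns:
            sexmap = dict(zip(animals, df["sex"]))
            sex = pd.Series([sexmap[a] for a in order], index=order)
            for a, (s, d) in parents.items():
                if s is not None and sexmap.get(s) not in (None, "M", "male", np.nan):
                    if sexmap.get(s) in ("F", "female"):
                        raise PedigreeError(f"sire {s!r} of {a!r} is recorded female")
                if d is not None and sexmap.get(d) in ("M", "male"):
                    raise PedigreeError(f"dam {d!r} of {a!r} is recorded male")
        return cls(ids=order, sire=sire, dam=dam, birth_date=birth, sex=sex, _index=idx)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "animal": self.ids,
            "sire": [self.ids[s] if s >= 0 else None for s in self.sire],
            "dam": [self.ids[d] if d >= 0 else None for d in self.dam],
        })
        if self.birth_date is not None:
            out["birth_date"] = self.birth_date.values
        if self.sex is not None:
            out["sex"] = self.sex.values
        return out


def _find_cycle(parents, placed, animals):
    # Any unplaced animal lies on or below a cycle; walk parent links.
    start = next(a for a in animals if a not in placed)
    seen = {}
    node, path = start, []
    while node is not None and node not in seen:
        seen[node] = len(path)
        path.append(node)
        s, d = parents.get(node, (None, None))
        node = s if (s is not None and s not in placed) else (
            d if (d is not None and d not in placed) else None)
    if node is None:
        return path
    return path[seen[node]:] + [node]


def inbreeding(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Inbreeding coefficients F and Mendelian-sampling variance ratios d.

    Meuwissen–Luo recursion: F_i = a(sire, dam)/2 computed by walking the
    L-row of the ancestor set; d_i is the variance of the Mendelian-sampling
    deviation relative to sigma2_g (1 for founders, 0.5 - 0.25(F_s + F_d)
    with both parents known, 0.75 - 0.25 F_p with one).
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    d = np.ones(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        di = 1.0
        if s >= 0:
            di -= 0.25 * (1.0 + F[s])
        if m >= 0:
            di -= 0.25 * (1.0 + F[m])
        d[i] = di
        if s < 0 or m < 0:
            F[i] = 0.0
            continue
        # a_ii = sum_j L_j^2 d_j over the ancestor closure of i (incl. i)
        L = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            c = L.pop(j, 0.0)
            if c == 0.0:
                continue
            aii += c * c * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in L:
                        heapq.heappush(heap, -p)
                        L[p] = 0.0
                    L[p] += 0.5 * c
        F[i] = aii - 1.0
    return F, d


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with its animal order."""

    ids: list
    values: np.ndarray
    inbreeding: np.ndarray

    def to_coordinate_frame(self, tol: float = 0.0) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(np.abs(self.values) > tol))
        return pd.DataFrame({
            "animal_i": [self.ids[k] for k in i],
            "animal_j": [self.ids[k] for k in j],
            "value": self.values[i, j],
        })


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Tabular method with inbreeding.  Dense: intended for moderate
    pedigrees (tests, oracle comparisons); large models use build_A_inverse.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    A = np.zeros((n, n))
    for j in range(n):
        s, m = sire[j], dam[j]
        if j > 0:
            col = np.zeros(j)
            if s >= 0:
                col += A[:j, s]
            if m >= 0:
                col += A[:j, m]
            col *= 0.5
            A[:j, j] = col
            A[j, :j] = col
        ajj = 1.0
        if s >= 0 and m >= 0:
            ajj += 0.5 * A[s, m]
        A[j, j] = ajj
    return RelationshipMatrix(ids=list(ped.ids), values=A, inbreeding=np.diag(A) - 1.0)


def build_A_inverse(ped: Pedigree) -> sp.csc_matrix:
    """Henderson's rules with inbreeding (Meuwissen–Luo d).

    The non-zero pattern touches only (animal, sire, dam) triples; the
    result is the exact inverse of build_A's matrix.
    """
    n = len(ped)
    _, d = inbreeding(ped)
    sire, dam = ped.sire, ped.dam
    alpha = 1.0 / d
    rows, cols, vals = [], [], []

    def put(i, j, v):
        rows.append(i); cols.append(j); vals.append(v)

    for i in range(n):
        a = alpha[i]
        s, m = sire[i], dam[i]
        put(i, i, a)
        for p in (s, m):
            if p >= 0:
                put(i, p, -0.5 * a)
                put(p, i, -0.5 * a)
                put(p, p, 0.25 * a)
        if s >= 0 and m >= 0:
            put(s, m, 0.25 * a)
            put(m, s, 0.25 * a)
    M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return M.tocsc()


def log_det_A(ped: Pedigree) -> float:
    """log |A| = sum log d_i (A = T D T' with unit-triangular T)."""
    _, d = inbreeding(ped)
    return float(np.sum(np.log(d)))
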