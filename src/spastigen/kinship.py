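"""Pedigree handling and additive (numerator) relationship matrices.

The additive relationship matrix A of a pedigree has entries equal to twice
the kinship coefficient between animals; its diagonal is 1 + F, where F is
the inbreeding coefficient.  ``build_A`` uses the classic tabular recursion,
``inbreeding`` the Meuwissen–Luo algorithm (no full A materialised), and
``a_inverse`` Henderson's rules with inbreeding, which yield the sparse
inverse needed by animal-model mixed equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = "0"


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Parentage triples (animal, sire, dam); ``"0"`` marks an unknown parent.

    Stored topologically sorted: every parent precedes its offspring.
    """

    animal: list[str]
    sire: list[str]
    dam: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.animal) == len(self.sire) == len(self.dam)):
            raise PedigreeError("animal/sire/dam columns differ in length")
        self.animal = [str(a) for a in self.animal]
        self.sire = [_norm_parent(s) for s in self.sire]
        self.dam = [_norm_parent(d) for d in self.dam]
        if len(set(self.animal)) != len(self.animal):
            raise PedigreeError("duplicate animal ids in pedigree")
        self._toposort()
        self._index = {a: i for i, a in enumerate(self.animal)}

    def _toposort(self) -> None:
        order: dict[str, int] = {}
        sire = dict(zip(self.animal, self.sire))
        dam = dict(zip(self.animal, self.dam))

        def visit(a: str, stack: tuple[str, ...]) -> int:
            if a in order:
                return order[a]
            if a in stack:
                cycle = stack[stack.index(a):] + (a,)
                raise PedigreeError(f"pedigree cycle: {' -> '.join(cycle)}")
            depth = 0
            for p in (sire.get(a, UNKNOWN), dam.get(a, UNKNOWN)):
                if p != UNKNOWN and p in sire:
                    depth = max(depth, visit(p, stack + (a,)) + 1)
            order[a] = depth
            return depth

        for a in self.animal:
            visit(a, ())
        idx = sorted(range(len(self.animal)),
                     key=lambda i: (order[self.animal[i]], i))
        self.animal = [self.animal[i] for i in idx]
        self.sire = [self.sire[i] for i in idx]
        self.dam = [self.dam[i] for i in idx]

    def __len__(self) -> int:
        return len(self.animal)

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam row indices, -1 for unknown or unlisted."""
        out = np.full((len(self), 2), -1, dtype=np.int64)
        for i, (s, d) in enumerate(zip(self.sire, self.dam)):
            out[i, 0] = self._index.get(s, -1)
            out[i, 1] = self._index.get(d, -1)
        return out

    def founders(self) -> list[str]:
        return [a for a, s, d in zip(self.animal, self.sire, self.dam)
                if s == UNKNOWN and d == UNKNOWN]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = list(df.columns[:3])
        return cls(df[cols[0]].astype(str).tolist(),
                   df[cols[1]].astype(str).tolist(),
                   df[cols[2]].astype(str).tolist())

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.animal, "sire": self.sire,
                             "dam": self.dam})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _norm_parent(p) -> str:
    p = str(p).strip()
    return UNKNOWN if p in ("", "0", "nan", "NA", ".") else p


@dataclass
class AdditiveRelationship:
    """Dense numerator relationship matrix with its animal ordering."""

    ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.ids), len(self.ids)):
            raise ValueError("A shape does not match id list")

    def submatrix(self, ids: list[str]) -> "AdditiveRelationship":
        pos = {a: i for i, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in pos]
        if missing:
            raise KeyError(f"animals absent from relationship matrix: {missing[:5]}")
        idx = np.array([pos[a] for a in ids])
        return AdditiveRelationship(list(ids), self.A[np.ix_(idx, idx)])

    def inbreeding(self) -> pd.Series:
        return pd.Series(np.diag(self.A) - 1.0, index=self.ids, name="F")


def build_A(p: Pedigree) -> AdditiveRelationship:
    """Tabular method: a_ii = 1 + a_sd/2, a_ij = (a_js + a_jd)/2 for j < i."""
    n = len(p)
    par = p.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        contrib = np.zeros(n)
        if s >= 0:
            contrib[:i] += 0.5 * A[s, :i]
        if d >= 0:
            contrib[:i] += 0.5 * A[d, :i]
        A[i, :i] = contrib[:i]
        A[:i, i] = contrib[:i]
    return AdditiveRelationship(list(p.animal), A)


def inbreeding(p: Pedigree) -> pd.Series:
    """Per-animal inbreeding coefficients via Meuwissen & Luo.

    Computes F = a_ii - 1 without materialising the full A matrix, so it
    scales to national-evaluation-sized pedigrees.
    """
    n = len(p)
    par = p.parent_indices()
    F = np.zeros(n)
    # d_i: Mendelian sampling variance coefficient for each animal
    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            continue
        # trace ancestors of i, accumulating additive contributions
        AN = np.zeros(n)  # coefficient of each ancestor path
        AN[i] = 1.0
        f_ii = 0.0
        for j in range(i, -1, -1):
            if AN[j] == 0.0:
                continue
            sj, dj = par[j]
            djj = _mendelian_d(F, sj, dj)
            f_ii += AN[j] * AN[j] * djj
            if sj >= 0:
                AN[sj] += 0.5 * AN[j]
            if dj >= 0:
                AN[dj] += 0.5 * AN[j]
        # f_ii is a_ii = 1 + F_i
        F[i] = f_ii - 1.0
    return pd.Series(F, index=p.animal, name="F")


def _mendelian_d(F: np.ndarray, s: int, d: int) -> float:
    if s >= 0 and d >= 0:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s >= 0:
        return 0.75 - 0.25 * F[s]
    if d >= 0:
        return 0.75 - 0.25 * F[d]
    return 1.0


def inbreeding_summary(p: Pedigree) -> dict:
    """Mean F over all animals and over inbred (F > 0) animals only.

    Both are reported because descriptive pedigree statistics are quoted
    ambiguously in the literature (mean over inbred animals vs over all).
    """
    F = inbreeding(p)
    inbred = F[F > 0]
    return {
        "n_animals": int(len(F)),
        "n_inbred": int(len(inbred)),
        "mean_F_all": float(F.mean()) if len(F) else float("nan"),
        "mean_F_inbred": float(inbred.mean()) if len(inbred) else 0.0,
    }


def a_inverse(p: Pedigree) -> tuple[sparse.csc_matrix, float]:
    """Sparse inverse of A via Henderson's rules (inbreeding-corrected).

    Returns (A^-1 in CSC format, log|A|).  log|A| = sum_i log d_i where d_i
    is the Mendelian sampling variance coefficient, a byproduct of the rules.
    """
    n = len(p)
    par = p.parent_indices()
    F = inbreeding(p).to_numpy()
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    logdet = 0.0
    for i in range(n):
        s, d = par[i]
        di = _mendelian_d(F, s, d)
        logdet += np.log(di)
        alpha = 1.0 / di
        rows.append(i); cols.append(i); vals.append(alpha)
        for pidx in (s, d):
            if pidx >= 0:
                rows += [i, pidx]; cols += [pidx, i]; vals += [-alpha / 2] * 2
        for p1 in (s, d):
            for p2 in (s, d):
                if p1 >= 0 and p2 >= 0:
                    rows.append(p1); cols.append(p2); vals.append(alpha / 4)
    Ainv = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return Ainv, float(logdet)


def write_matrix(rel: AdditiveRelationship, path, fmt: str = "dense") -> None:
    if fmt == "dense":
        df = pd.DataFrame(rel.A, index=rel.ids, columns=rel.ids)
        df.to_csv(path, float_format="%.10g")
    elif fmt == "triplet":
        i, j = np.nonzero(np.triu(rel.A))
        pd.DataFrame({"id_i": [rel.ids[k] for k in i],
                      "id_j": [rel.ids[k] for k in j],
                      "a": rel.A[i, j]}).to_csv(path, index=False,
                                                float_format="%.10g")
    else:
        raise ValueError(f"unknown matrix format: {fmt}")


def read_matrix(path) -> AdditiveRelationship:
    df = pd.read_csv(path, index_col=0)
    return AdditiveRelationship([str(c) for c in df.index], df.to_numpy())
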