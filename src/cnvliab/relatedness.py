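"""Pedigree (numerator) and genomic relationship matrices.

The additive (numerator) relationship matrix A is built with the tabular
method from a sire/dam pedigree; the genomic relationship matrix G is the
VanRaden method-1 centered cross-product of SNP dosages.  Both are the
covariance structures used by the threshold animal model and the mixed-model
association scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = {"0", 0, None, "", "NA", "nan"}


@dataclass
class RelationshipMatrix:
    """Symmetric PSD relationship matrix with its animal ordering.

    ``values[i, j]`` is the (dimensionless) relationship coefficient between
    ``ids[i]`` and ``ids[j]``.  For a pedigree matrix the diagonal is
    ``1 + F`` (inbreeding coefficient F >= 0); for a genomic matrix the
    diagonal averages ~1 under Hardy-Weinberg equilibrium.
    """

    ids: list
    values: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def index_of(self, animal) -> int:
        try:
            return self.ids.index(animal)
        except ValueError:
            raise KeyError(f"animal {animal!r} not in relationship matrix") from None

    def subset(self, animals) -> "RelationshipMatrix":
        idx = [self.index_of(a) for a in animals]
        return RelationshipMatrix(list(animals), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def _is_unknown(parent) -> bool:
    if parent is None:
        return True
    if isinstance(parent, float) and np.isnan(parent):
        return True
    return parent in UNKNOWN


def read_pedigree(path) -> pd.DataFrame:
    """Read an animal/sire/dam CSV; ``0`` or empty marks an unknown parent."""
    ped = pd.read_csv(path, dtype=str).rename(columns=str.lower)
    required = {"animal", "sire", "dam"}
    if not required.issubset(ped.columns):
        raise ValueError(f"pedigree CSV needs columns {sorted(required)}")
    return ped[["animal", "sire", "dam"]]


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    out = pedigree.copy()
    for col in ("sire", "dam"):
        out[col] = [("0" if _is_unknown(p) else p) for p in out[col]]
    out.to_csv(path, index=False)


def topological_order(pedigree: pd.DataFrame) -> list:
    """Order animals so every parent precedes its offspring.

    Raises ``ValueError`` naming an animal on a pedigree cycle (an animal
    that is its own ancestor).
    """
    ids = list(pedigree["animal"])
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise ValueError(f"duplicate animal ids: {list(dup[dup > 1].index)}")
    parents = {}
    for row in pedigree.itertuples(index=False):
        parents[row.animal] = [
            p for p in (row.sire, row.dam) if not _is_unknown(p)
        ]
    order: list = []
    state: dict = {}  # 0 = visiting, 1 = done

    for root in ids:
        if state.get(root) == 1:
            continue
        stack = [(root, iter(parents.get(root, [])))]
        state[root] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for par in it:
                if par not in parents:
                    continue  # parent outside the table: treated as founder
                s = state.get(par)
                if s == 0:
                    raise ValueError(
                        f"pedigree cycle detected at animal {par!r}"
                    )
                if s is None:
                    state[par] = 0
                    stack.append((par, iter(parents[par])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                state[node] = 1
                order.append(node)
    return order


def a_matrix(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + 0.5 * a(sire_i, dam_i); a_ij = 0.5 * (a(j, sire_i) +
    a(j, dam_i)); an unknown parent contributes 0 (unrelated,
    non-inbred founder).
    """
    order = topological_order(pedigree)
    idx = {a: i for i, a in enumerate(order)}
    par = {}
    for row in pedigree.itertuples(index=False):
        par[row.animal] = (
            None if _is_unknown(row.sire) else row.sire,
            None if _is_unknown(row.dam) else row.dam,
        )
    n = len(order)
    A = np.zeros((n, n))
    for a in order:
        i = idx[a]
        s, d = par.get(a, (None, None))
        si = idx.get(s) if s is not None else None
        di = idx.get(d) if d is not None else None
        row = np.zeros(n)
        if si is not None:
            row += 0.5 * A[si]
        if di is not None:
            row += 0.5 * A[di]
        A[i, :] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    # return in the pedigree's own order
    perm = [idx[a] for a in pedigree["animal"]]
    return RelationshipMatrix(list(pedigree["animal"]), A[np.ix_(perm, perm)])


def grm(genotypes: pd.DataFrame) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    ``genotypes`` is animals x markers with dosages in {0, 1, 2} (NaN =
    missing, mean-imputed per marker).  G = Z Z' / (2 sum p_k (1 - p_k))
    with Z the column-centered dosage matrix and p_k the sample allele
    frequency.  Monomorphic markers are dropped; the count is reported in
    ``info['n_monomorphic_dropped']``.
    """
    X = genotypes.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need an animals x markers matrix with >= 1 marker")
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X = np.where(nan_mask, col_mean[np.newaxis, :], X)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    Xp = X[:, poly]
    pp = p[poly]
    Z = Xp - 2.0 * pp
    denom = 2.0 * np.sum(pp * (1.0 - pp))
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(
        list(genotypes.index),
        G,
        info={"n_monomorphic_dropped": n_dropped, "n_markers_used": int(poly.sum())},
    )
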