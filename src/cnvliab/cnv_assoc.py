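"""CNV-region construction and the genome-wide mixed-model association scan.

Per-animal CNV calls are unioned into CNV regions (CNVRs): same-type
overlapping calls merged per chromosome, kept when detected in at least two
animals and at a carrier frequency above a floor.  Each region is then
tested against a quantitative phenotype (typically the breeding value of
embryonic mortality) with a single-random-effect linear mixed model

    y = W alpha + x beta + u + eps,   u ~ N(0, sigma2_g G)

where G is a genomic relationship matrix.  The variance ratio
delta = sigma2_g / sigma2_e is profiled by REML on the eigendecomposed
model (the GEMMA strategy) and the carrier effect beta is assessed by a
Wald chi-square(1) test.  Genomic-control inflation (lambda_GC) and a
Bonferroni threshold provide stratification and multiple-testing control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .relatedness import RelationshipMatrix

__all__ = [
    "CnvCall",
    "CnvRegion",
    "AssociationResult",
    "merge_cnvrs",
    "KinshipEigen",
    "lmm_assoc",
    "lambda_gc",
    "bonferroni_threshold",
    "ld_r2",
    "manhattan_table",
    "manhattan_plot",
]

CHI2_1_MEDIAN = chi2.ppf(0.5, 1)  # 0.454936...


@dataclass(frozen=True)
class CnvCall:
    """One CNV call in one animal (1-based inclusive coordinates)."""

    animal: str
    chrom: str
    start: int
    end: int
    type: str = "loss"
    copy_number: int | None = None

    def __post_init__(self):
        if self.start <= 0 or self.end <= 0:
            raise ValueError("coordinates must be positive")
        if self.start >= self.end:
            raise ValueError("start must be < end")


@dataclass(frozen=True)
class CnvRegion:
    """Union region of overlapping same-type calls across animals."""

    region_id: str
    chrom: str
    start: int
    end: int
    type: str
    carriers: frozenset
    cohort_size: int

    @property
    def frequency(self) -> float:
        """Carrier frequency: carriers / cohort size."""
        return len(self.carriers) / self.cohort_size

    @property
    def allele_frequency(self) -> float:
        """Assuming all carriers heterozygous: carriers / (2 * cohort size)."""
        return len(self.carriers) / (2 * self.cohort_size)

    def length(self, convention="difference") -> int:
        return self.end - self.start + (1 if convention == "inclusive" else 0)


@dataclass(frozen=True)
class AssociationResult:
    """Mixed-model Wald test for one region."""

    region_id: str
    effect: float
    se: float
    p_value: float
    delta: float  # REML variance ratio sigma2_g / sigma2_e

    @property
    def neglog10_p(self) -> float:
        return -math.log10(self.p_value)


def read_cnv_calls(path) -> list:
    """BED-like TSV: chrom, start, end, animal, type, copy_number."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CnvCall(r.animal, str(r.chrom), int(r.start), int(r.end), r.type,
                int(r.copy_number) if "copy_number" in df.columns else None)
        for r in df.itertuples(index=False)
    ]


def _chrom_sort_key(chrom):
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


def merge_cnvrs(
    calls,
    cohort_size: int,
    min_animals: int = 2,
    min_freq: float = 0.01,
    known_chromosomes=None,
) -> list:
    """Union overlapping same-type calls into CNVRs and filter them.

    Regions carried by fewer than ``min_animals`` distinct animals, or at a
    carrier frequency <= ``min_freq``, are dropped.  Loss and gain calls are
    merged separately.  Order of the input calls does not matter and the
    operation is idempotent over region-shaped calls.
    """
    if known_chromosomes is not None:
        unknown = {c.chrom for c in calls} - set(known_chromosomes)
        if unknown:
            raise ValueError(f"calls on unknown chromosome(s): {sorted(unknown)}")
    groups: dict = {}
    for c in calls:
        groups.setdefault((c.type, c.chrom), []).append(c)
    merged = []
    for (cnv_type, chrom), group in groups.items():
        group.sort(key=lambda c: (c.start, c.end, c.animal))
        cur_start, cur_end, cur_animals = None, None, set()
        for c in group:
            if cur_start is None:
                cur_start, cur_end, cur_animals = c.start, c.end, {c.animal}
            elif c.start <= cur_end:  # 1-based inclusive overlap
                cur_end = max(cur_end, c.end)
                cur_animals.add(c.animal)
            else:
                merged.append((chrom, cur_start, cur_end, cnv_type, cur_animals))
                cur_start, cur_end, cur_animals = c.start, c.end, {c.animal}
        if cur_start is not None:
            merged.append((chrom, cur_start, cur_end, cnv_type, cur_animals))
    merged.sort(key=lambda m: (_chrom_sort_key(m[0]), m[1], m[2], m[3]))
    regions = []
    i = 0
    for chrom, start, end, cnv_type, animals in merged:
        if len(animals) < min_animals:
            continue
        if len(animals) / cohort_size <= min_freq:
            continue
        i += 1
        regions.append(
            CnvRegion(f"CNVR_{i:03d}", chrom, start, end, cnv_type,
                      frozenset(animals), cohort_size)
        )
    return regions


@dataclass
class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix for repeated scans."""

    ids: list
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @classmethod
    def from_matrix(cls, G: RelationshipMatrix) -> "KinshipEigen":
        lam, U = np.linalg.eigh(G.values)
        return cls(list(G.ids), np.clip(lam, 0.0, None), U)


def _reml_neg_loglik(log_delta, lam, Xr, yr):
    delta = math.exp(log_delta)
    h = delta * lam + 1.0
    w = 1.0 / h
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWy = Xr.T @ (w * yr)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    pyy = float(yr @ (w * yr) - beta @ XtWy)
    n, c = Xr.shape
    if pyy <= 0:
        return np.inf
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    return 0.5 * ((n - c) * math.log(pyy) + float(np.log(h).sum()) + logdet_xwx)


def lmm_assoc(
    phenotype,
    carrier_code,
    G: RelationshipMatrix | KinshipEigen | None = None,
    covariates=None,
    region_id: str = "",
) -> AssociationResult:
    """Single-region mixed-model association with a Wald chi-square(1) test.

    ``phenotype`` and ``carrier_code`` are per-animal vectors in the same
    order as ``G``.  The variance ratio is REML-profiled by 1-D optimization
    over log delta on the rotated (eigenbasis) model; with ``G=None`` (or an
    identity kinship) the result coincides with the ordinary least-squares
    Wald test.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(carrier_code, dtype=float)
    n = len(y)
    if len(x) != n:
        raise ValueError("phenotype and carrier code lengths differ")
    if np.ptp(x) == 0:
        raise ValueError("monomorphic predictor")
    cols = [np.ones(n)]
    if covariates is not None:
        W = np.atleast_2d(np.asarray(covariates, dtype=float))
        if W.shape[0] != n:
            W = W.T
        cols.extend(W.T)
    cols.append(x)
    X = np.column_stack(cols)

    if G is None:
        lam = np.zeros(n)
        U = None
        Xr, yr = X, y
    else:
        eig = G if isinstance(G, KinshipEigen) else KinshipEigen.from_matrix(G)
        if len(eig.ids) != n:
            raise ValueError("kinship dimension does not match phenotype length")
        lam, U = eig.eigenvalues, eig.eigenvectors
        Xr, yr = U.T @ X, U.T @ y

    if np.ptp(lam) == 0:
        best_logd = -math.inf
        delta = 0.0
    else:
        grid = np.linspace(-10.0, 10.0, 41)
        vals = [_reml_neg_loglik(g, lam, Xr, yr) for g in grid]
        j = int(np.argmin(vals))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(lo, hi), args=(lam, Xr, yr), method="bounded"
        )
        best_logd = float(res.x)
        delta = math.exp(best_logd)

    h = delta * lam + 1.0
    w = 1.0 / h
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWy = Xr.T @ (w * yr)
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ XtWy
    c = X.shape[1]
    pyy = float(yr @ (w * yr) - beta @ XtWy)
    sigma2 = pyy / (n - c)
    se = math.sqrt(max(sigma2 * XtWX_inv[-1, -1], 0.0))
    if se == 0.0:
        p = np.nextafter(0.0, 1.0)
    else:
        wald = (beta[-1] / se) ** 2
        p = float(chi2.sf(wald, 1))
        p = max(p, np.nextafter(0.0, 1.0))
    return AssociationResult(region_id, float(beta[-1]), se, p, delta)


def lambda_gc(pvalues) -> float:
    """Genomic inflation factor: median observed chi-square(1) statistic
    over the null median (~0.4549)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


def bonferroni_threshold(alpha: float, m: int):
    """Per-test threshold alpha/m and its -log10 rounded to 3 dp."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    thr = alpha / m
    return thr, round(-math.log10(thr), 3)


def ld_r2(genotype_a, genotype_b) -> float:
    """Composite LD: squared Pearson correlation of dosage vectors."""
    a = np.asarray(genotype_a, dtype=float)
    b = np.asarray(genotype_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("genotype vectors must cover the same animals")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic genotype vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def manhattan_table(results: pd.DataFrame, gap: int = 1_000_000) -> pd.DataFrame:
    """Plot-ready table with cumulative genome coordinates.

    ``results`` needs columns chrom, pos, p_value (and optionally
    region_id).  Rows are ordered by chromosome (natural order) then
    position; chromosomes alternate between two color groups.
    """
    if len(results) == 0:
        return pd.DataFrame(
            columns=["region_id", "chrom", "pos", "p_value", "cum_pos",
                     "neglog10_p", "color_group"]
        )
    df = results.copy()
    df["chrom"] = df["chrom"].astype(str)
    df = df.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s
    ).reset_index(drop=True)
    offset = 0
    cum = np.empty(len(df))
    color = np.empty(len(df), dtype=int)
    chroms = sorted(df["chrom"].unique(), key=_chrom_sort_key)
    for k, ch in enumerate(chroms):
        mask = (df["chrom"] == ch).to_numpy()
        cum[mask] = df.loc[mask, "pos"].to_numpy() + offset
        color[mask] = k % 2
        offset = cum[mask].max() + gap
    df["cum_pos"] = cum
    df["neglog10_p"] = -np.log10(df["p_value"])
    df["color_group"] = color
    if "region_id" not in df.columns:
        df["region_id"] = [f"r{i}" for i in range(len(df))]
    return df


def manhattan_plot(table: pd.DataFrame, threshold_neglog10: float | None = None,
                   path=None):
    """Manhattan plot with alternating chromosome colors and a threshold line.

    Returns the matplotlib figure, or None for an empty table.
    """
    if len(table) == 0:
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    for group, col in ((0, "tab:blue"), (1, "tab:red")):
        sub = table[table["color_group"] == group]
        ax.scatter(sub["cum_pos"], sub["neglog10_p"], s=12, color=col)
    if threshold_neglog10 is not None:
        ax.axhline(threshold_neglog10, linestyle="--", color="grey")
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
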