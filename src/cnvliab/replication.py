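"""Replication and effect-size statistics for a candidate CNV.

Genotype-class contrasts on breeding values via least-squares means of a
Gaussian linear model, allele-frequency estimation from carrier counts, the
proportion of genetic variance explained by a biallelic locus, Mendelian
segregation chi-square tests, and multi-group comparisons (Tukey-Kramer or
Welch t-tests) for crossbreeding experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "EffectSummary",
    "lsmeans_contrast",
    "allele_freq",
    "variance_explained",
    "mendelian_chisq",
    "group_comparisons",
]


@dataclass(frozen=True)
class EffectSummary:
    """Least-squares means per genotype class and their contrast."""

    lsmeans: dict
    contrast: float          # second class minus first (e.g. carrier - wild)
    se: float
    t_statistic: float
    p_value: float
    df_resid: float
    variance_explained: float | None = None


def _dummy_code(series: pd.Series, name: str):
    levels = sorted(series.unique())
    cols = {f"{name}[{lev}]": (series == lev).to_numpy(float) for lev in levels[1:]}
    return levels, cols


def lsmeans_contrast(
    data: pd.DataFrame,
    genotype: str = "genotype",
    response: str = "response",
    covariates=(),
) -> EffectSummary:
    """Gaussian linear model LS-means and the genotype contrast.

    LS-means are the model-predicted genotype means averaged over the levels
    of every categorical covariate with equal weights.  The contrast is the
    difference between the second and first genotype level (sorted order,
    e.g. ``+/-`` minus ``+/+``) with a two-sided t-test.  A genotype class
    perfectly confounded with a covariate level raises an error naming the
    aliasing.
    """
    g_levels = sorted(data[genotype].unique())
    if len(g_levels) < 2:
        raise ValueError("need >= 2 genotype classes for a contrast")

    cols = {"intercept": np.ones(len(data))}
    _, gcols = _dummy_code(data[genotype], genotype)
    cols.update(gcols)
    cov_levels = {}
    for cov in covariates:
        cov_levels[cov], ccols = _dummy_code(data[cov], cov)
        cols.update(ccols)
    X = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name which covariate aliases the genotype (or another covariate)
        for cov in covariates:
            tab = pd.crosstab(data[genotype], data[cov])
            if ((tab > 0).sum(axis=0) == 1).any():
                raise ValueError(
                    f"genotype is confounded with a level of covariate {cov!r}"
                )
        raise ValueError("design matrix rank-deficient (aliased covariates)")

    fit = sm.OLS(data[response].to_numpy(float), X.to_numpy()).fit()
    names = list(X.columns)

    def lsmean_row(level):
        row = np.zeros(len(names))
        row[0] = 1.0
        key = f"{genotype}[{level}]"
        if key in names:
            row[names.index(key)] = 1.0
        for cov, levels in cov_levels.items():
            for lev in levels[1:]:
                row[names.index(f"{cov}[{lev}]")] = 1.0 / len(levels)
        return row

    rows = {lev: lsmean_row(lev) for lev in g_levels}
    lsmeans = {lev: float(r @ fit.params) for lev, r in rows.items()}
    c = rows[g_levels[1]] - rows[g_levels[0]]
    est = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov_params() @ c))
    if se == 0.0:
        tval, p = 0.0, 1.0
    else:
        tval = est / se
        p = float(2 * stats.t.sf(abs(tval), fit.df_resid))
    return EffectSummary(lsmeans, est, se, tval, p, float(fit.df_resid))


def allele_freq(carriers: int, homozygotes: int, n: int) -> float:
    """Risk-allele frequency from genotype counts: (het + 2*hom) / (2n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if carriers + homozygotes > n:
        raise ValueError("carriers + homozygotes cannot exceed n")
    return (carriers + 2 * homozygotes) / (2 * n)


def variance_explained(effect: float, freq: float, total_genetic_variance: float) -> float:
    """Proportion of genetic variance explained by a biallelic locus.

    Locus variance 2p(1-p)a^2 under additive allele-dosage coding; with no
    homozygous carriers observed, the carrier-coded effect is treated as the
    allele-substitution effect a.  Capped at 1 with a warning.
    """
    if not 0.0 < freq < 1.0:
        raise ValueError("frequency must lie in (0, 1)")
    if total_genetic_variance <= 0:
        raise ValueError("total genetic variance must be positive")
    prop = 2.0 * freq * (1.0 - freq) * effect**2 / total_genetic_variance
    if prop > 1.0:
        warnings.warn("locus variance exceeds total genetic variance; capped at 1",
                      stacklevel=2)
        prop = 1.0
    return prop


def mendelian_chisq(observed, expected_ratio=(1, 2, 3)):
    """Pearson goodness-of-fit test of genotype counts against a ratio.

    Returns ``(chi2, df, p)`` with df = classes - 1.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if (ratio <= 0).any():
        raise ValueError("expected ratio classes must be positive")
    if len(obs) != len(ratio):
        raise ValueError("observed and expected ratio lengths differ")
    expected = ratio / ratio.sum() * obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def group_comparisons(groups: dict, method: str = "tukey_kramer") -> pd.DataFrame:
    """Pairwise group comparisons for crossing experiments.

    ``tukey_kramer``: studentized-range test with the unequal-n correction
    (all pairs, family-wise adjusted p).  ``t_test``: two-sided Welch
    (unequal-variance) t-test per pair, unadjusted.  Returns a DataFrame
    with columns group1, group2, estimate, p_value.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs >= 2 observations")
    names = list(groups)
    if method == "tukey_kramer":
        values = np.concatenate([np.asarray(groups[g], float) for g in names])
        labels = np.concatenate([[g] * len(groups[g]) for g in names])
        res = pairwise_tukeyhsd(values, labels)
        out = pd.DataFrame(
            res.summary().data[1:],
            columns=[c.lower() for c in res.summary().data[0]],
        )
        return pd.DataFrame(
            {
                "group1": out["group1"],
                "group2": out["group2"],
                "estimate": out["meandiff"].astype(float),
                "p_value": np.asarray(res.pvalues, dtype=float),
            }
        )
    if method == "t_test":
        rows = []
        for g1, g2 in combinations(names, 2):
            a = np.asarray(groups[g1], float)
            b = np.asarray(groups[g2], float)
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                raise ValueError(f"zero variance in groups {g1!r}/{g2!r}")
            t, p = stats.ttest_ind(b, a, equal_var=False)
            rows.append((g1, g2, float(b.mean() - a.mean()), float(p)))
        return pd.DataFrame(rows, columns=["group1", "group2", "estimate", "p_value"])
    raise ValueError("method must be 'tukey_kramer' or 't_test'")
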