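"""Nonparametric comparison of per-subject model fits.

Friedman omnibus test on the subjects x models log-likelihood matrix,
paired Wilcoxon signed-rank tests with Bonferroni correction for the
pairwise model contrasts, unpaired rank-sum tests for group contrasts
on parameters, and Spearman agreement between real and simulated hit
proportions.

Statistic conventions: rank tests report the rank-sum statistic (the
scale on which values like "Z = 2613" at n > 200 subjects live) along
with the normal-approximation z-score, and rank-biserial correlations
as the effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_likelihood_matrix",
    "FriedmanResult",
    "friedman_test",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "MannWhitneyResult",
    "mann_whitney",
    "real_vs_simulated_agreement",
    "ComparisonReport",
    "compare_models",
]

MODEL_ORDER = ("random", "simple", "counterfactual")


def build_likelihood_matrix(
    fit_table: pd.DataFrame, penalized: bool = False
) -> pd.DataFrame:
    """Pivot a tidy fit table into a subjects x models log-likelihood matrix.

    With ``penalized=True`` the negated penalized objective is compared
    instead of the raw log-likelihood.
    """
    value = "penalized_nll" if penalized else "ll"
    mat = fit_table.pivot(index="subject_id", columns="model", values=value)
    if penalized:
        mat = -mat
    cols = [m for m in MODEL_ORDER if m in mat.columns]
    mat = mat[cols]
    if mat.isna().any().any():
        bad = mat.index[mat.isna().any(axis=1)].tolist()
        raise ValueError(f"missing model fits for subjects: {bad}")
    return mat


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    n_subjects: int
    ties_present: bool = False


def friedman_test(matrix: pd.DataFrame) -> FriedmanResult:
    """Friedman rank test across models within subjects.

    Within-subject midranks; the classic statistic
    ``chi2 = 12/(n k (k+1)) * sum(R_j^2) - 3 n (k+1)`` divided by the
    standard tie-correction factor; ``df = k - 1``.
    """
    data = np.asarray(matrix, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 models")
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n (k^3 - k))
    ties = 0.0
    ties_present = False
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        if (counts > 1).any():
            ties_present = True
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * (k**3 - k))
    if c > 0:
        chi2 /= c
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return FriedmanResult(chi2=float(chi2), df=df, p=p, n_subjects=n,
                          ties_present=ties_present)


@dataclass
class WilcoxonResult:
    """Paired signed-rank test with Bonferroni correction.

    ``w_pos``/``w_neg`` are the rank sums of positive and negative
    differences (``a - b``); ``rank_biserial = (W+ - W-) / (W+ + W-)``.
    """

    w_pos: float
    w_neg: float
    z: float
    p: float
    p_corrected: float
    rank_biserial: float
    n_used: int
    n_zero_dropped: int
    flagged: bool = False


def wilcoxon_signed_rank(a, b, n_comparisons: int = 1) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (flagged when any are).  P-values are
    exact for n <= 25 without ties, otherwise the normal approximation
    with continuity correction.  The Bonferroni-corrected p is
    ``min(1, p * n_comparisons)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    if n == 0:
        return WilcoxonResult(
            w_pos=math.nan, w_neg=math.nan, z=math.nan, p=math.nan,
            p_corrected=math.nan, rank_biserial=math.nan,
            n_used=0, n_zero_dropped=n_zero, flagged=True,
        )
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    total = w_pos + w_neg
    rb = (w_pos - w_neg) / total

    mu = n * (n + 1) / 4.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    w = min(w_pos, w_neg)
    z = (w_pos - mu - 0.5 * math.copysign(1.0, w_pos - mu)) / sigma if sigma > 0 else math.nan

    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(a[nonzero], b[nonzero], zero_method="wilcox",
                         correction=True, method=method)
    p = float(res.pvalue)
    return WilcoxonResult(
        w_pos=w_pos, w_neg=w_neg, z=float(z), p=p,
        p_corrected=min(1.0, p * n_comparisons),
        rank_biserial=float(rb), n_used=n, n_zero_dropped=n_zero,
        flagged=n_zero > 0,
    )


@dataclass
class MannWhitneyResult:
    """Unpaired rank-sum test with rank-biserial effect size.

    ``u`` is the Mann-Whitney U of the first group; the effect size is
    ``2 U / (n_a n_b) - 1``, positive when group a tends to exceed b.
    """

    u: float
    p: float
    rank_biserial: float
    n_a: int
    n_b: int


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney test with midrank tie handling."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    u = float(res.statistic)
    rb = 2.0 * u / (len(a) * len(b)) - 1.0
    return MannWhitneyResult(u=u, p=float(res.pvalue), rank_biserial=float(rb),
                             n_a=len(a), n_b=len(b))


def real_vs_simulated_agreement(
    real: Sequence[float],
    simulated: Sequence[float],
    groups: Optional[Sequence] = None,
) -> Dict[str, dict]:
    """Spearman agreement between real and simulated per-subject hit rates.

    Returns ``{"overall": {...}, "<group>": {...}}`` with ``rho``, ``p``
    and ``n`` per entry; constant vectors are flagged undefined.
    """
    real = np.asarray(real, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if real.shape != simulated.shape:
        raise ValueError("real and simulated vectors must align")

    def one(x, y):
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return {"rho": math.nan, "p": math.nan, "n": len(x), "flagged": True}
        r = stats.spearmanr(x, y)
        return {"rho": float(r.statistic), "p": float(r.pvalue), "n": len(x),
                "flagged": False}

    out = {"overall": one(real, simulated)}
    if groups is not None:
        groups = np.asarray(groups, dtype=object)
        for g in pd.unique(groups):
            sel = groups == g
            out[str(g)] = one(real[sel], simulated[sel])
    return out


@dataclass
class ComparisonReport:
    """Omnibus + pairwise model comparison on a cohort's fit table."""

    friedman: FriedmanResult
    pairwise: Dict[str, WilcoxonResult]
    medians: Dict[str, float]
    minima: Dict[str, float]
    maxima: Dict[str, float]
    penalized: bool

    def to_dict(self) -> dict:
        return {
            "friedman": {
                "chi2": self.friedman.chi2, "df": self.friedman.df,
                "p": self.friedman.p, "n_subjects": self.friedman.n_subjects,
            },
            "pairwise": {
                name: {
                    "w_pos": r.w_pos, "w_neg": r.w_neg, "z": r.z, "p": r.p,
                    "p_corrected": r.p_corrected,
                    "rank_biserial": r.rank_biserial, "n": r.n_used,
                }
                for name, r in self.pairwise.items()
            },
            "medians": self.medians,
            "minima": self.minima,
            "maxima": self.maxima,
            "penalized": self.penalized,
        }


def compare_models(fit_table: pd.DataFrame, penalized: bool = False) -> ComparisonReport:
    """Friedman omnibus plus Bonferroni-corrected pairwise Wilcoxon tests.

    Compares raw log-likelihoods by default (the two RL models have the
    same number of parameters and the random baseline has none), with
    penalized comparison available via ``penalized=True``.
    """
    mat = build_likelihood_matrix(fit_table, penalized=penalized)
    fr = friedman_test(mat)
    models = list(mat.columns)
    pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1:]]
    pairwise = {
        f"{a}_vs_{b}": wilcoxon_signed_rank(mat[a], mat[b], n_comparisons=len(pairs))
        for a, b in pairs
    }
    return ComparisonReport(
        friedman=fr,
        pairwise=pairwise,
        medians={m: float(mat[m].median()) for m in models},
        minima={m: float(mat[m].min()) for m in models},
        maxima={m: float(mat[m].max()) for m in models},
        penalized=penalized,
    )
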