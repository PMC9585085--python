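"""Behavioral dependent variables and their analyses.

Per-subject summaries (hit proportion and exact binomial test against
chance, win-stay/lose-shift repetition rates), pooled learning curves on
the hyperbolic within-block trial predictor ``hyp(x) = 1 - 1/(1 + x)``,
repetition conditioned on the subjective value of the previous feedback,
exclusion filters (response rate, anticipations), rating summaries, and
Spearman parameter-covariate correlation matrices with Benjamini-
Hochberg FDR control.

Pooled logistic fits use a binomial GLM with subject-clustered standard
errors in place of maximal random-effects mixed models: the per-subject
summaries and pooled fits capture the same directional effects without
the GLMM machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task import ANTICIPATION_CUTOFF_MS, ParticipantDataset

__all__ = [
    "BehaviorSummary",
    "LearningCurve",
    "ExclusionReport",
    "hyperbolic",
    "score_hits",
    "per_subject_binomial_test",
    "learning_curve",
    "repetition_table",
    "RepetitionSummary",
    "repetition_by_value",
    "apply_exclusions",
    "rating_summary",
    "RatingSummary",
    "correlate_parameters",
    "behavior_summary_table",
]

MAX_CURVE_INDEX = 19  # learning curves use the first 20 trials after reversal


def hyperbolic(x):
    """Saturating trial predictor ``y = 1 - 1/(1 + x)``; hyp(0) = 0."""
    x = np.asarray(x, dtype=float)
    return 1.0 - 1.0 / (1.0 + x)


def score_hits(dataset: ParticipantDataset):
    """Hit flags (choice of the currently optimal side) and hit proportion.

    Returns ``(flags, proportion)``; flags are NaN on invalid trials and
    the proportion is NaN (flagged by a warning) when no trial is valid.
    """
    df = dataset.trials
    valid = df["valid"].to_numpy(dtype=bool)
    flags = np.full(len(df), np.nan)
    flags[valid] = (
        df.loc[valid, "choice_side"].to_numpy() == df.loc[valid, "optimal_side"].to_numpy()
    ).astype(float)
    if not valid.any():
        warnings.warn(f"subject {dataset.subject_id}: no valid trials, hit proportion undefined")
        return flags, math.nan
    return flags, float(np.nanmean(flags))


def per_subject_binomial_test(dataset: ParticipantDataset) -> float:
    """Exact two-sided binomial test of the hit count against chance 0.5."""
    flags, _ = score_hits(dataset)
    k = int(np.nansum(flags))
    n = int(np.sum(~np.isnan(flags)))
    if n < 1:
        raise ValueError("binomial test requires at least one valid trial")
    return float(stats.binomtest(k, n, 0.5).pvalue)


@dataclass
class BehaviorSummary:
    """Per-subject behavioral dependent variables."""

    subject_id: str
    hit_proportion: float
    binomial_p: float
    repeat_after_avoidance: float  # win-stay
    repeat_after_approach: float   # 1 - lose-shift
    n_valid: int
    strategy_group: Optional[str] = None


@dataclass
class RepetitionSummary:
    """Repetition rates conditioned on the previous trial's feedback."""

    win_stay: float            # P(repeat | previous feedback = avoidance)
    repeat_after_approach: float
    lose_shift: float          # 1 - repeat_after_approach
    n_pairs_avoidance: int
    n_pairs_approach: int
    flagged: bool = False

    @property
    def n_pairs(self) -> int:
        return self.n_pairs_avoidance + self.n_pairs_approach


def repetition_table(dataset: ParticipantDataset) -> RepetitionSummary:
    """Response repetition split by previous feedback.

    A pair (t-1, t) is eligible when both trials are valid and
    consecutive; repetition means the same side was chosen on both.
    Pairs are counted across block boundaries (reversals are invisible
    to the subject at choice time).
    """
    df = dataset.trials
    valid = df["valid"].to_numpy(dtype=bool)
    choice = df["choice_side"].to_numpy(dtype=object)
    feedback = df["feedback"].to_numpy(dtype=object)
    rep = {"avoidance": [], "approach": []}
    for t in range(1, len(df)):
        if not (valid[t] and valid[t - 1]):
            continue
        rep[feedback[t - 1]].append(choice[t] == choice[t - 1])
    n_av, n_ap = len(rep["avoidance"]), len(rep["approach"])
    if n_av + n_ap == 0:
        warnings.warn(f"subject {dataset.subject_id}: no eligible repetition pairs")
        return RepetitionSummary(math.nan, math.nan, math.nan, 0, 0, flagged=True)
    win_stay = float(np.mean(rep["avoidance"])) if n_av else math.nan
    after_ap = float(np.mean(rep["approach"])) if n_ap else math.nan
    return RepetitionSummary(
        win_stay=win_stay,
        repeat_after_approach=after_ap,
        lose_shift=1.0 - after_ap if n_ap else math.nan,
        n_pairs_avoidance=n_av,
        n_pairs_approach=n_ap,
    )


def behavior_summary_table(cohort: Sequence[ParticipantDataset]) -> pd.DataFrame:
    """One BehaviorSummary row per subject, as a tidy table."""
    rows = []
    for ds in cohort:
        _, prop = score_hits(ds)
        rep = repetition_table(ds)
        rows.append({
            "subject_id": ds.subject_id,
            "strategy_group": ds.strategy_group,
            "hit_proportion": prop,
            "binomial_p": per_subject_binomial_test(ds) if ds.n_valid else np.nan,
            "repeat_after_avoidance": rep.win_stay,
            "repeat_after_approach": rep.repeat_after_approach,
            "win_stay": rep.win_stay,
            "lose_shift": rep.lose_shift,
            "n_valid": ds.n_valid,
        })
    return pd.DataFrame(rows)


@dataclass
class LearningCurve:
    """Pooled post-reversal learning curve on the hyperbolic predictor."""

    mean_hit_by_index: np.ndarray  # length 20, NaN where no data
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    n_observations: int
    degenerate: bool = False

    def predict(self, index) -> np.ndarray:
        eta = self.intercept + self.slope * hyperbolic(index)
        return 1.0 / (1.0 + np.exp(-np.asarray(eta)))


def _pool_curve_trials(cohort) -> pd.DataFrame:
    frames = []
    for ds in cohort:
        flags, _ = score_hits(ds)
        df = ds.trials[["within_block_index"]].copy()
        df["hit"] = flags
        df["subject_id"] = ds.subject_id
        frames.append(df[df["within_block_index"] <= MAX_CURVE_INDEX].dropna(subset=["hit"]))
    return pd.concat(frames, ignore_index=True)


def learning_curve(
    cohort: Union[ParticipantDataset, Sequence[ParticipantDataset]],
) -> LearningCurve:
    """Mean hit per within-block index 0-19 plus a pooled logistic fit.

    Fits ``hit ~ hyp(index)`` by binomial GLM with subject-clustered
    covariance.  When the pooled hits are constant (e.g. an oracle
    cohort) the fit is degenerate: the slope is 0 and the curve is the
    constant observed rate.
    """
    if isinstance(cohort, ParticipantDataset):
        cohort = [cohort]
    pooled = _pool_curve_trials(cohort)
    mean_by_index = np.full(MAX_CURVE_INDEX + 1, np.nan)
    g = pooled.groupby("within_block_index")["hit"].mean()
    mean_by_index[g.index.to_numpy(dtype=int)] = g.to_numpy()

    y = pooled["hit"].to_numpy()
    if y.size == 0 or np.ptp(y) == 0:
        rate = float(y.mean()) if y.size else math.nan
        eta = math.inf if rate == 1.0 else (-math.inf if rate == 0.0 else math.log(rate / (1 - rate)))
        return LearningCurve(
            mean_hit_by_index=mean_by_index,
            intercept=eta, slope=0.0,
            intercept_se=math.nan, slope_se=math.nan,
            n_observations=int(y.size), degenerate=True,
        )
    X = sm.add_constant(hyperbolic(pooled["within_block_index"].to_numpy()))
    model = sm.GLM(y, X, family=sm.families.Binomial())
    if pooled["subject_id"].nunique() > 1:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": pooled["subject_id"]})
    else:
        res = model.fit()
    return LearningCurve(
        mean_hit_by_index=mean_by_index,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        n_observations=int(y.size),
    )


def _subject_scenario_values(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean rating of each scenario class, rescaled to [0, 1]."""
    out = (
        ratings.groupby(["subject_id", "scenario"])["rating"].mean().rename("value")
        / 100.0
    ).reset_index()
    return out


@dataclass
class ValueRepetitionFit:
    """Pooled logistic fit of repetition on previous-feedback subjective value."""

    table: pd.DataFrame  # columns: subject_id, repetition, prev_value
    intercept: float
    slope: float
    slope_se: float
    n_observations: int
    degenerate: bool = False


def repetition_by_value(
    cohort: Union[ParticipantDataset, Sequence[ParticipantDataset]],
    ratings: pd.DataFrame,
) -> ValueRepetitionFit:
    """Repetition as a function of the subjective value of the previous feedback.

    Each eligible pair (t-1, t) carries the subject's mean rating (0-1
    scale, ratings divided by 100) of the scenario class received at
    t-1.  A missing (subject, scenario) rating raises an error naming
    the gap.  The pooled logistic fit is flagged degenerate when the
    value column is constant.
    """
    if isinstance(cohort, ParticipantDataset):
        cohort = [cohort]
    values = _subject_scenario_values(ratings)
    lookup = {(r.subject_id, r.scenario): r.value for r in values.itertuples()}
    rows = []
    for ds in cohort:
        df = ds.trials
        valid = df["valid"].to_numpy(dtype=bool)
        choice = df["choice_side"].to_numpy(dtype=object)
        feedback = df["feedback"].to_numpy(dtype=object)
        for t in range(1, len(df)):
            if not (valid[t] and valid[t - 1]):
                continue
            key = (ds.subject_id, feedback[t - 1])
            if key not in lookup:
                raise KeyError(
                    f"no rating for subject {ds.subject_id!r}, scenario {feedback[t - 1]!r}"
                )
            rows.append({
                "subject_id": ds.subject_id,
                "repetition": float(choice[t] == choice[t - 1]),
                "prev_value": lookup[key],
            })
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no eligible repetition pairs in the cohort")
    v = table["prev_value"].to_numpy()
    y = table["repetition"].to_numpy()
    if np.ptp(v) == 0 or np.ptp(y) == 0:
        return ValueRepetitionFit(
            table=table, intercept=math.nan, slope=0.0, slope_se=math.nan,
            n_observations=len(table), degenerate=True,
        )
    X = sm.add_constant(v)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    if table["subject_id"].nunique() > 1:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": table["subject_id"]})
    else:
        res = model.fit()
    return ValueRepetitionFit(
        table=table,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        n_observations=len(table),
    )


MIN_RESPONSE_RATE = 0.90
MAX_ANTICIPATION_SHARE = 0.15


@dataclass
class ExclusionReport:
    """Cohort-level exclusion decisions."""

    table: pd.DataFrame  # subject_id, response_rate, anticipation_share, reasons, retained

    @property
    def retained_ids(self) -> List[str]:
        return list(self.table.loc[self.table["retained"], "subject_id"])

    @property
    def excluded_ids(self) -> List[str]:
        return list(self.table.loc[~self.table["retained"], "subject_id"])


def apply_exclusions(cohort: Sequence[ParticipantDataset]) -> ExclusionReport:
    """Flag subjects with <90% valid responses or >15% anticipations.

    Anticipations are valid responses faster than 100 ms; their share is
    taken over valid responses only.  Retained iff no reason applies.
    """
    rows = []
    for ds in cohort:
        df = ds.trials
        valid = df["valid"].to_numpy(dtype=bool)
        n = len(df)
        rate = float(valid.sum() / n) if n else math.nan
        rt = df["rt_ms"].to_numpy(dtype=float)
        n_valid = int(valid.sum())
        anticipations = int(((rt < ANTICIPATION_CUTOFF_MS) & valid).sum())
        share = anticipations / n_valid if n_valid else math.nan
        reasons = []
        if rate < MIN_RESPONSE_RATE:
            reasons.append("low_response_rate")
        if n_valid and share > MAX_ANTICIPATION_SHARE:
            reasons.append("excess_anticipations")
        rows.append({
            "subject_id": ds.subject_id,
            "response_rate": rate,
            "anticipation_share": share,
            "reasons": ";".join(reasons),
            "retained": not reasons,
        })
    return ExclusionReport(table=pd.DataFrame(rows))


@dataclass
class RatingSummary:
    """Grand means of per-subject condition means on the 0-100 rating scale."""

    approach_mean: float
    avoidance_mean: float
    difference: float
    per_subject: pd.DataFrame


def rating_summary(ratings: pd.DataFrame) -> RatingSummary:
    """Approach/avoidance rating means, aggregated subject-first."""
    if ratings.empty:
        raise ValueError("rating table is empty")
    per_subject = (
        ratings.pivot_table(index="subject_id", columns="scenario", values="rating",
                            aggfunc="mean")
        .reset_index()
    )
    approach = float(per_subject["approach"].mean())
    avoidance = float(per_subject["avoidance"].mean())
    return RatingSummary(
        approach_mean=approach,
        avoidance_mean=avoidance,
        difference=avoidance - approach,
        per_subject=per_subject,
    )


def correlate_parameters(
    fit_table: pd.DataFrame,
    covariate_table: pd.DataFrame,
    fdr_scope: str = "matrix",
) -> pd.DataFrame:
    """Spearman correlations between fitted parameters and covariates.

    Both inputs are indexed (or keyed) by ``subject_id``; every numeric
    column of ``fit_table`` is correlated against every numeric column
    of ``covariate_table``.  P-values are Benjamini-Hochberg adjusted
    across the whole matrix by default (``fdr_scope="row"`` adjusts
    within each parameter instead).  Constant columns yield flagged
    undefined rows.
    """
    f = fit_table.set_index("subject_id") if "subject_id" in fit_table.columns else fit_table
    c = covariate_table.set_index("subject_id") if "subject_id" in covariate_table.columns else covariate_table
    common = f.index.intersection(c.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned subjects")
    f = f.loc[common].select_dtypes("number")
    c = c.loc[common].select_dtypes("number")
    rows = []
    for pname in f.columns:
        for cname in c.columns:
            x, y = f[pname].to_numpy(), c[cname].to_numpy()
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rows.append({"parameter": pname, "covariate": cname,
                             "rho": np.nan, "p": np.nan, "n": int(ok.sum()),
                             "flagged": True})
                continue
            res = stats.spearmanr(x[ok], y[ok])
            rows.append({"parameter": pname, "covariate": cname,
                         "rho": float(res.statistic), "p": float(res.pvalue),
                         "n": int(ok.sum()), "flagged": False})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    if fdr_scope == "matrix":
        ok = ~out["p"].isna()
        if ok.any():
            out.loc[ok, "p_fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    elif fdr_scope == "row":
        for pname in out["parameter"].unique():
            sel = (out["parameter"] == pname) & ~out["p"].isna()
            if sel.any():
                out.loc[sel, "p_fdr"] = multipletests(out.loc[sel, "p"], method="fdr_bh")[1]
    else:
        raise ValueError("fdr_scope must be 'matrix' or 'row'")
    return out
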