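"""Model-free behavioral analyses: exclusions, learning curves,
feature regressions with age moderation, and memory-test statistics.

Inference follows a two-stage summary-statistics scheme: stage 1 fits a
regression per subject (logistic for choice, linear for log response
time) on features z-scored across the entire dataset; stage 2 tests the
per-subject coefficients across subjects with one-sample t-tests (group
main effects) and regresses them on z-scored age (age moderation).  This
preserves the inferential targets of participant-level random slopes —
sign and age-dependence of each feature's effect — without a mixed-model
dependency; subject regressions hit by (quasi-)separation fall back to a
weak ridge penalty and are flagged.

All analyses operate on the long-format session table (one row per
trial, schema of :mod:`.task`).  Trials with no response or a response
faster than 200 ms are excluded first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as smapi
from scipy import optimize, stats

from .beliefs import trial_feature_table
from .likelihood import MIN_RT

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "learning_curves",
    "choice_feature_regression",
    "rt_feature_regression",
    "memory_accuracy",
    "zscore",
]

CHOICE_FEATURES = ["d_ev", "d_unc", "d_nov"]
RT_FEATURES = ["ev_chosen", "nov_chosen", "unc_chosen"]


@dataclass
class ExclusionReport:
    n_total: int
    n_missed: int
    n_fast: int
    per_subject: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return self.n_missed + self.n_fast

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_excluded


def apply_exclusions(dataset: pd.DataFrame) -> Tuple[pd.DataFrame, ExclusionReport]:
    """Drop missed trials and responses faster than 200 ms."""
    if "rt_sec" not in dataset.columns:
        raise ValueError("dataset needs an rt_sec column")
    missed = dataset["choice"] == "missed"
    fast = (~missed) & dataset["rt_sec"].notna() & (dataset["rt_sec"] < MIN_RT)
    per_subject = (
        pd.DataFrame(
            {
                "participant_id": dataset["participant_id"],
                "missed": missed,
                "fast": fast,
            }
        )
        .groupby("participant_id")
        .sum()
        .reset_index()
    )
    report = ExclusionReport(
        n_total=len(dataset),
        n_missed=int(missed.sum()),
        n_fast=int(fast.sum()),
        per_subject=per_subject,
    )
    return dataset.loc[~(missed | fast)].copy(), report


def zscore(x: np.ndarray) -> np.ndarray:
    """z-score with an informative error on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x, ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (x - np.nanmean(x)) / sd


def learning_curves(dataset: pd.DataFrame) -> dict:
    """Optimal-choice and reward proportions by within-block trial position.

    The optimal choice is the displayed option with the higher true reward
    probability; trials where the two options share a probability are
    flagged and excluded from the optimal-choice curve (but kept in the
    reward curve).  Returns curves split by difficulty and age group, plus
    per-subject slopes of optimal choice on trial position.
    """
    made = dataset["choice"].isin(["left", "right"])
    df = dataset.loc[made].copy()
    if df.empty:
        raise ValueError("no valid choice trials")
    tied = df["prob_left"] == df["prob_right"]
    if tied.any():
        logger.info("%d trials with tied probabilities excluded from optimal curve", tied.sum())
    chose_left = df["choice"] == "left"
    df["chose_optimal"] = np.where(
        df["prob_left"] > df["prob_right"], chose_left, ~chose_left
    )
    df["rewarded"] = df["outcome"] == "win"

    def _curve(frame: pd.DataFrame, col: str, keys: list) -> pd.DataFrame:
        g = frame.groupby(keys)[col]
        out = g.agg(["mean", "count"]).reset_index()
        out["se"] = np.sqrt(out["mean"] * (1 - out["mean"]) / out["count"].clip(lower=1))
        return out

    curves = {
        "optimal": _curve(df.loc[~tied], "chose_optimal", ["block_difficulty", "trial"]),
        "optimal_by_age": _curve(
            df.loc[~tied], "chose_optimal", ["age_group", "block_difficulty", "trial"]
        ),
        "reward": _curve(df, "rewarded", ["block_difficulty", "trial"]),
    }
    slopes = []
    for pid, chunk in df.loc[~tied].groupby("participant_id"):
        if chunk["trial"].nunique() < 2:
            continue
        slope = stats.linregress(chunk["trial"], chunk["chose_optimal"].astype(float)).slope
        slopes.append({"participant_id": pid, "optimal_slope": float(slope)})
    curves["subject_slopes"] = pd.DataFrame(slopes)
    curves["n_tied_excluded"] = int(tied.sum())
    return curves


def _logit_fit(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Logistic regression returning (coefs, standard errors, penalized?).

    Plain ML first; on failure or runaway coefficients (separation) the
    fit is redone with a weak ridge penalty on the non-intercept terms.
    """

    def nll(b: np.ndarray) -> float:
        z = X @ b
        # -sum[y log p + (1-y) log(1-p)] via softplus
        val = float(np.sum(np.logaddexp(0.0, z) - y * z))
        if ridge_l2 > 0:
            val += 0.5 * ridge_l2 * float(np.sum(b[1:] ** 2))
        return val

    ridge_l2 = ridge
    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS")
    coef = res.x
    penalized = False
    if ridge == 0.0 and (not res.success or np.max(np.abs(coef)) > 10.0):
        ridge_l2 = 1.0
        res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS")
        coef = res.x
        penalized = True
    p = 1.0 / (1.0 + np.exp(-(X @ coef)))
    w = p * (1 - p)
    h = X.T @ (X * w[:, None])
    if ridge_l2 > 0:
        h = h + ridge_l2 * np.diag([0.0] + [1.0] * (X.shape[1] - 1))
    try:
        se = np.sqrt(np.diag(np.linalg.inv(h)))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    return coef, se, penalized


def _stage2(
    coefs: pd.DataFrame, features: list, ages: np.ndarray
) -> pd.DataFrame:
    """Across-subject t-tests and age-moderation regressions per feature."""
    z_age = zscore(ages)
    rows = []
    for feat in features:
        vals = coefs[feat].to_numpy()
        if np.std(vals, ddof=1) == 0:
            raise ValueError(f"zero variance in subject coefficients for {feat!r}")
        t, p = stats.ttest_1samp(vals, 0.0)
        X = smapi.add_constant(z_age)
        ols = smapi.OLS(vals, X).fit()
        rows.append(
            {
                "feature": feat,
                "mean_coef": float(np.mean(vals)),
                "t": float(t),
                "dof": len(vals) - 1,
                "p": float(p),
                "age_slope": float(ols.params[1]),
                "age_slope_se": float(ols.bse[1]),
                "age_slope_p": float(ols.pvalues[1]),
            }
        )
    return pd.DataFrame(rows)


def _per_subject_features(dataset: pd.DataFrame, eta: float) -> pd.DataFrame:
    parts = []
    for pid, chunk in dataset.groupby("participant_id", sort=True):
        chunk = chunk.sort_values(["block", "trial"]).reset_index(drop=True)
        feats = trial_feature_table(chunk, eta=eta)
        feats["choice"] = chunk["choice"].to_numpy()
        feats["rt_sec"] = chunk["rt_sec"].to_numpy()
        parts.append(feats)
    return pd.concat(parts, ignore_index=True)


def choice_feature_regression(
    dataset: pd.DataFrame, eta: float = 1.0, min_trials: int = 20
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-1 per-subject logistic regressions of left choice on the
    z-scored expected-value, uncertainty and novelty differences between
    options, plus stage-2 group and age-moderation tests.

    Returns ``(subject_coefs, group_tests)``.  Exclusions must have been
    applied upstream; rows without a left/right choice are dropped here.
    Subjects with fewer than ``min_trials`` valid trials are skipped.
    """
    df = dataset.loc[dataset["choice"].isin(["left", "right"])]
    feats = _per_subject_features(df, eta)
    for col in CHOICE_FEATURES:
        feats[f"z_{col}"] = zscore(feats[col].to_numpy())
    feats["chose_left"] = (feats["choice"] == "left").astype(float)

    rows = []
    for pid, chunk in feats.groupby("participant_id", sort=False):
        if len(chunk) < min_trials:
            logger.info("%s: %d trials < %d; skipped", pid, len(chunk), min_trials)
            continue
        X = np.column_stack(
            [np.ones(len(chunk))] + [chunk[f"z_{c}"].to_numpy() for c in CHOICE_FEATURES]
        )
        coef, se, penalized = _logit_fit(X, chunk["chose_left"].to_numpy())
        rows.append(
            {
                "participant_id": pid,
                "age_years": float(chunk["age_years"].iloc[0]),
                "intercept": coef[0],
                **{f: coef[i + 1] for i, f in enumerate(CHOICE_FEATURES)},
                **{f"se_{f}": se[i + 1] for i, f in enumerate(CHOICE_FEATURES)},
                "penalized": penalized,
                "n_trials": len(chunk),
            }
        )
    subject_coefs = pd.DataFrame(rows)
    if len(subject_coefs) < 3:
        raise ValueError("need at least 3 subjects with enough trials")
    group_tests = _stage2(
        subject_coefs, CHOICE_FEATURES, subject_coefs["age_years"].to_numpy()
    )
    return subject_coefs, group_tests


def rt_feature_regression(
    dataset: pd.DataFrame, eta: float = 1.0, min_trials: int = 20
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject linear regressions of log response time on the z-scored
    chosen-option expected value, novelty and uncertainty, plus stage-2
    group and age-moderation tests.  Non-positive response times raise
    (they should have been excluded upstream)."""
    df = dataset.loc[dataset["choice"].isin(["left", "right"])]
    if (df["rt_sec"] <= 0).any() or df["rt_sec"].isna().any():
        raise ValueError("non-positive or missing response times; apply exclusions first")
    feats = _per_subject_features(df, eta)
    for col in RT_FEATURES:
        feats[f"z_{col}"] = zscore(feats[col].to_numpy())
    feats["log_rt"] = np.log(feats["rt_sec"].to_numpy(dtype=float))

    rows = []
    for pid, chunk in feats.groupby("participant_id", sort=False):
        if len(chunk) < min_trials:
            logger.info("%s: %d trials < %d; skipped", pid, len(chunk), min_trials)
            continue
        X = smapi.add_constant(
            np.column_stack([chunk[f"z_{c}"].to_numpy() for c in RT_FEATURES])
        )
        ols = smapi.OLS(chunk["log_rt"].to_numpy(), X).fit()
        rows.append(
            {
                "participant_id": pid,
                "age_years": float(chunk["age_years"].iloc[0]),
                "intercept": float(ols.params[0]),
                **{f: float(ols.params[i + 1]) for i, f in enumerate(RT_FEATURES)},
                **{f"se_{f}": float(ols.bse[i + 1]) for i, f in enumerate(RT_FEATURES)},
                "n_trials": len(chunk),
            }
        )
    subject_coefs = pd.DataFrame(rows)
    if len(subject_coefs) < 3:
        raise ValueError("need at least 3 subjects with enough trials")
    group_tests = _stage2(subject_coefs, RT_FEATURES, subject_coefs["age_years"].to_numpy())
    return subject_coefs, group_tests


def memory_accuracy(
    memory: pd.DataFrame,
    ages: Optional[Mapping[str, float]] = None,
    chance: float = 0.2,
) -> dict:
    """Memory-test accuracy against the five-alternative chance level.

    Returns per-subject accuracies, a one-sample t-test of subject
    accuracy against ``chance`` (0.2), and — when ``ages`` maps
    participant ids to ages — a trial-level logistic regression of
    correctness on z-scored age.
    """
    if memory.empty:
        raise ValueError("empty memory table")
    correct = (memory["response_id"] == memory["correct_id"]).astype(float)
    per_subject = (
        pd.DataFrame({"participant_id": memory["participant_id"], "correct": correct})
        .groupby("participant_id")["correct"]
        .agg(accuracy="mean", n_probes="count")
        .reset_index()
    )
    acc = per_subject["accuracy"].to_numpy()
    t, p = stats.ttest_1samp(acc, chance)
    out = {
        "per_subject": per_subject,
        "mean_accuracy": float(np.mean(acc)),
        "t": float(t),
        "dof": len(acc) - 1,
        "p": float(p),
        "chance": chance,
    }
    if ages is not None:
        age = memory["participant_id"].map(dict(ages)).to_numpy(dtype=float)
        glm = smapi.GLM(
            correct.to_numpy(), smapi.add_constant(zscore(age)),
            family=smapi.families.Binomial(),
        ).fit()
        out["age_coef"] = float(glm.params[1])
        out["age_p"] = float(glm.pvalues[1])
    return out
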