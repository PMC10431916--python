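"""Model recovery and model-simulation summaries.

Model recovery asks whether the six choice models are identifiable on
this task: datasets are simulated from each model (reusing each subject's
exact trial sequence and per-subject parameters), every dataset is refit
with the full two-level procedure, and the winners are aggregated into a
confusion matrix P(fitted best model | simulated model) and its Bayes
inverse P(simulated model | fitted best model).  Winners are recorded two
ways — by each replicate's exceedance probabilities and by per-subject
responsibility argmax — since either aggregation is defensible.

The similar-expected-value summary is the model-simulation diagnostic:
restricted to trials where the two options' expected values differ by
less than 0.05 (so value cannot drive the choice), it reports the
proportion of choices of the more novel and of the more uncertain option.
A familiarity-gated uncertainty-averse agent chooses the more novel
option above chance yet the more uncertain option below chance; a pure
novelty-bias agent chooses both above chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import beliefs as bf
from .fitting import HBIConfig, hbi_fit
from .likelihood import compile_session
from .models import get_model
from .task import SessionData, TaskStructure, simulate_agent

logger = logging.getLogger(__name__)

__all__ = [
    "RecoveryConfig",
    "ConfusionMatrices",
    "simulate_from_fits",
    "model_recovery",
    "similar_ev_summary",
]


@dataclass(frozen=True)
class RecoveryConfig:
    """Scale and model sets for a recovery run."""

    simulate_models: tuple[str, ...]
    fit_models: tuple[str, ...]
    n_replicates: int = 50
    seed: int = 0
    hbi: HBIConfig = field(default_factory=HBIConfig)

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.simulate_models or not self.fit_models:
            raise ValueError("model sets must be non-empty")


@dataclass
class ConfusionMatrices:
    """Recovery outcome tables (rows = simulated model)."""

    confusion: pd.DataFrame  # replicate-level exceedance winners
    subject_confusion: pd.DataFrame  # mean proportion of subjects best fit
    inversion: pd.DataFrame  # Bayes inverse of `confusion`, uniform sim prior
    winners: pd.DataFrame  # one row per (simulated model, replicate)


def _param_row(table: pd.DataFrame, pid: str, names: Sequence[str]) -> Dict[str, float]:
    row = table.loc[table["participant_id"] == pid]
    if row.empty:
        raise KeyError(f"no parameters for participant {pid!r}")
    out = {}
    for p in names:
        col = p if p in row.columns else f"true_{p}"
        if col not in row.columns:
            raise KeyError(f"parameter column {p!r} missing from table")
        out[p] = float(row[col].iloc[0])
    return out


def simulate_from_fits(
    param_table: pd.DataFrame,
    model: str,
    tasks: Mapping[str, TaskStructure],
    n_reps: int,
    seed: int,
    ages: Optional[Mapping[str, float]] = None,
) -> List[List[SessionData]]:
    """Simulate ``n_reps`` replicate datasets from per-subject parameters.

    Each replicate reuses every subject's exact trial sequence (their
    ``TaskStructure``); only choices and outcomes are resampled.
    ``param_table`` needs a ``participant_id`` column plus the model's
    parameters (bare or ``true_``-prefixed columns).
    """
    spec = get_model(model)
    root = np.random.SeedSequence(seed)
    replicates: List[List[SessionData]] = []
    for _ in range(n_reps):
        dataset = []
        for pid, task in tasks.items():
            params = _param_row(param_table, pid, spec.param_names)
            sub_seed = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
            dataset.append(
                simulate_agent(
                    task,
                    spec,
                    params,
                    seed=sub_seed,
                    participant_id=pid,
                    age_years=float((ages or {}).get(pid, 25.0)),
                )
            )
        replicates.append(dataset)
    return replicates


def model_recovery(
    config: RecoveryConfig,
    params_by_model: Mapping[str, pd.DataFrame],
    tasks: Mapping[str, TaskStructure],
) -> ConfusionMatrices:
    """Simulate-from-model / fit-all-models identifiability analysis.

    For every simulated model and replicate, a dataset is generated via
    :func:`simulate_from_fits` and refit hierarchically over
    ``config.fit_models``; the replicate's winner is the model with the
    highest exceedance probability.  Replicates whose fit fails are logged
    and excluded from the aggregation.
    """
    config.validate()
    sim_models = [get_model(m).name for m in config.simulate_models]
    fit_models = [get_model(m).name for m in config.fit_models]
    rows = []
    subj_rows = []
    root = np.random.SeedSequence(config.seed)
    for sim_model in sim_models:
        if sim_model not in params_by_model:
            raise KeyError(f"no parameter table for simulated model {sim_model!r}")
        for rep in range(config.n_replicates):
            rep_seed = int(root.spawn(1)[0].generate_state(1)[0] % 2**31)
            dataset = simulate_from_fits(
                params_by_model[sim_model], sim_model, tasks, n_reps=1, seed=rep_seed
            )[0]
            try:
                compiled = [compile_session(s.trials, s.participant_id) for s in dataset]
                result = hbi_fit(compiled, fit_models, config.hbi)
            except Exception:
                logger.exception(
                    "recovery fit failed (sim=%s replicate=%d); excluded", sim_model, rep
                )
                continue
            winner = result.models[int(np.argmax(result.xp))]
            rows.append({"simulated": sim_model, "replicate": rep, "winner": winner})
            best = np.argmax(result.responsibilities, axis=1)
            for j, m in enumerate(result.models):
                subj_rows.append(
                    {
                        "simulated": sim_model,
                        "replicate": rep,
                        "fitted": m,
                        "proportion_subjects": float(np.mean(best == j)),
                    }
                )

    winners = pd.DataFrame(rows)
    confusion = pd.DataFrame(0.0, index=sim_models, columns=fit_models)
    for sim_model, chunk in winners.groupby("simulated"):
        counts = chunk["winner"].value_counts(normalize=True)
        for m, v in counts.items():
            confusion.loc[sim_model, m] = v
    subject_confusion = (
        pd.DataFrame(subj_rows)
        .groupby(["simulated", "fitted"])["proportion_subjects"]
        .mean()
        .unstack()
        .reindex(index=sim_models, columns=fit_models)
        .fillna(0.0)
        if subj_rows
        else pd.DataFrame(index=sim_models, columns=fit_models, dtype=float)
    )
    # Bayes inversion under a uniform prior over simulated models
    col_mass = confusion.sum(axis=0)
    inversion = confusion.div(col_mass.replace(0.0, np.nan), axis=1)
    return ConfusionMatrices(
        confusion=confusion,
        subject_confusion=subject_confusion,
        inversion=inversion,
        winners=winners,
    )


def similar_ev_summary(
    sessions: Sequence[SessionData],
    eta: float = 1.0,
    source: str = "empirical",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choice proportions on similar-expected-value trials.

    Restricts each subject to valid-choice trials where ``|dEV| < 0.05``
    and, separately for the novelty and uncertainty proportions, to trials
    where the two options' feature values differ (ties drop out of the
    denominator).  Subjects with zero qualifying trials are excluded from
    the group mean with a log note.

    Returns ``(per_subject, by_group)``; the group table reports mean and
    standard error across subjects, per age group.
    """
    rows = []
    for session in sessions:
        feats = bf.trial_feature_table(session.trials, eta=eta)
        choices = session.trials["choice"].to_numpy()
        made = (choices == "left") | (choices == "right")
        sim = feats["similar_ev"].to_numpy() & made
        chose_left = choices == "left"
        out = {
            "participant_id": session.participant_id,
            "age_years": session.age_years,
            "age_group": session.age_group,
            "source": source,
            "n_similar_ev": int(sim.sum()),
        }
        for feat, col in (("novel", "d_nov"), ("uncertain", "d_unc")):
            d = feats[col].to_numpy()
            mask = sim & (d != 0.0)
            if mask.sum() == 0:
                logger.info(
                    "%s: no similar-EV trials with distinct %s features; excluded",
                    session.participant_id, feat,
                )
                out[f"p_choose_more_{feat}"] = np.nan
                out[f"n_{feat}"] = 0
            else:
                chose_more = np.where(d[mask] > 0, chose_left[mask], ~chose_left[mask])
                out[f"p_choose_more_{feat}"] = float(np.mean(chose_more))
                out[f"n_{feat}"] = int(mask.sum())
        rows.append(out)
    per_subject = pd.DataFrame(rows)

    group_rows = []
    for (grp, src), chunk in per_subject.groupby(["age_group", "source"]):
        row = {"age_group": grp, "source": src, "n_subjects": len(chunk)}
        for feat in ("novel", "uncertain"):
            vals = chunk[f"p_choose_more_{feat}"].dropna()
            row[f"p_choose_more_{feat}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"se_{feat}"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        group_rows.append(row)
    return per_subject, pd.DataFrame(group_rows)
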