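"""Fast per-session likelihood replay for the choice models.

A participant's session is pre-compiled once into flat arrays
(:class:`CompiledSession`): within-block option indices, choice/outcome
codes, first-appearance flags and presentation counts.  Everything that
does not depend on model parameters — in particular each option's
familiarity on each trial, which is a function of presentation counts
only — is computed at compile time.  The sequential belief replay itself
(discounted win/loss sums, utilities, softmax log-probabilities) runs in a
numba kernel, since hierarchical fitting and model recovery evaluate it
millions of times.

Excluded trials (missed responses, responses faster than 200 ms)
contribute no likelihood term, but any outcome that was revealed still
updates beliefs — the participant saw the feedback.  The recency discount
advances with every displayed trial of a block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .beliefs import novelty
from .models import ModelSpec, transform_params

#: responses faster than this (seconds) are excluded from likelihoods
MIN_RT = 0.2

__all__ = ["MIN_RT", "CompiledSession", "compile_session", "session_nll", "make_objective"]


@dataclass(frozen=True)
class CompiledSession:
    """Array form of one participant's session, ready for replay."""

    participant_id: str
    n_trials: int
    new_block: np.ndarray  # bool, block boundary before this trial
    block_of: np.ndarray  # int32, block row index per trial
    left: np.ndarray  # int8, within-block option index of left stimulus
    right: np.ndarray  # int8, within-block option index of right stimulus
    choice: np.ndarray  # int8, 0 left / 1 right / -1 missed
    outcome: np.ndarray  # int8, 1 win / 0 loss / -1 none
    valid: np.ndarray  # bool, trial enters the likelihood
    fam_left: np.ndarray  # float64, familiarity of left option pre-trial
    fam_right: np.ndarray  # float64
    debut: np.ndarray  # bool (n_blocks, 3), first-ever task appearance

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def compile_session(trials: pd.DataFrame, participant_id: str = "") -> CompiledSession:
    """Compile one participant's ordered trial table into replay arrays.

    Works from the session CSV schema alone: block option sets, debut
    flags and presentation counts are all reconstructed from the stimulus
    id columns, so empirical data conforming to the schema compile
    identically to simulated data.
    """
    n = len(trials)
    if n == 0:
        raise ValueError("empty session")
    blocks = trials["block"].to_numpy()
    if not (np.diff(blocks) >= 0).all():
        raise ValueError("trials must be grouped by block in order")

    block_ids = pd.unique(blocks)
    block_row = {b: i for i, b in enumerate(block_ids)}
    stim_l = trials["stim_left"].to_numpy()
    stim_r = trials["stim_right"].to_numpy()

    block_stims: dict = {}
    for b in block_ids:
        mask = blocks == b
        stims = list(pd.unique(np.concatenate([stim_l[mask], stim_r[mask]])))
        if len(stims) > 3:
            raise ValueError(f"block {b} shows {len(stims)} stimuli; expected <= 3")
        block_stims[b] = stims

    seen_blocks: set = set()
    debut = np.zeros((len(block_ids), 3), dtype=bool)
    for b in block_ids:
        for k, s in enumerate(block_stims[b]):
            debut[block_row[b], k] = s not in seen_blocks
        seen_blocks.update(block_stims[b])

    new_block = np.zeros(n, dtype=bool)
    block_of = np.zeros(n, dtype=np.int32)
    left = np.zeros(n, dtype=np.int8)
    right = np.zeros(n, dtype=np.int8)
    choice = np.zeros(n, dtype=np.int8)
    outcome = np.zeros(n, dtype=np.int8)
    valid = np.zeros(n, dtype=bool)
    fam_l = np.zeros(n)
    fam_r = np.zeros(n)

    counts: dict = {}
    prev_block = None
    choices = trials["choice"].to_numpy()
    outcomes = trials["outcome"].to_numpy()
    rts = (
        trials["rt_sec"].to_numpy(dtype=float)
        if "rt_sec" in trials.columns
        else np.full(n, np.nan)
    )
    for t in range(n):
        b = blocks[t]
        new_block[t] = b != prev_block
        prev_block = b
        block_of[t] = block_row[b]
        idx = block_stims[b].index
        left[t] = idx(stim_l[t])
        right[t] = idx(stim_r[t])
        choice[t] = {"left": 0, "right": 1, "missed": -1}[choices[t]]
        outcome[t] = {"win": 1, "loss": 0, "none": -1}[outcomes[t]]
        valid[t] = choice[t] >= 0 and not (np.isfinite(rts[t]) and rts[t] < MIN_RT)
        fam_l[t] = 1.0 - novelty(counts.get(stim_l[t], 0))
        fam_r[t] = 1.0 - novelty(counts.get(stim_r[t], 0))
        counts[stim_l[t]] = counts.get(stim_l[t], 0) + 1
        counts[stim_r[t]] = counts.get(stim_r[t], 0) + 1

    return CompiledSession(
        participant_id=participant_id
        or str(trials["participant_id"].iloc[0] if "participant_id" in trials else ""),
        n_trials=n,
        new_block=new_block,
        block_of=block_of,
        left=left,
        right=right,
        choice=choice,
        outcome=outcome,
        valid=valid,
        fam_left=fam_l,
        fam_right=fam_r,
        debut=debut,
    )


@njit(cache=True)
def _replay_nll(
    beta_sm,
    eta,
    nov_bias,
    w_unc,
    has_nov,
    has_unc,
    gated,
    new_block,
    block_of,
    left,
    right,
    choice,
    outcome,
    valid,
    fam_left,
    fam_right,
    debut,
):  # pragma: no cover - exercised via session_nll
    n = new_block.shape[0]
    a0 = np.ones(3)
    b0 = np.ones(3)
    win = np.zeros(3)
    loss = np.zeros(3)
    nll = 0.0
    for t in range(n):
        if new_block[t]:
            b = block_of[t]
            for k in range(3):
                win[k] = 0.0
                loss[k] = 0.0
                a0[k] = 1.0
                b0[k] = 1.0
                if has_nov and debut[b, k]:
                    if nov_bias >= 0.0:
                        a0[k] = 1.0 + nov_bias
                    else:
                        b0[k] = 1.0 - nov_bias
        i = left[t]
        j = right[t]
        # utilities of the two displayed options
        ai = a0[i] + win[i]
        bi = b0[i] + loss[i]
        si = ai + bi
        vl = ai / si
        aj = a0[j] + win[j]
        bj = b0[j] + loss[j]
        sj = aj + bj
        vr = aj / sj
        if has_unc:
            wl = w_unc
            wr = w_unc
            if gated:
                wl *= fam_left[t]
                wr *= fam_right[t]
            vl += wl * ai * bi / (si * si * (si + 1.0))
            vr += wr * aj * bj / (sj * sj * (sj + 1.0))
        if valid[t]:
            x = beta_sm * (vl - vr)
            if choice[t] == 1:
                x = -x
            # -log sigmoid(x), overflow-safe
            if x >= 0.0:
                nll += np.log1p(np.exp(-x))
            else:
                nll += -x + np.log1p(np.exp(x))
        # recency discount advances every trial; only an observed outcome
        # of the chosen option appends, with weight eta
        for k in range(3):
            win[k] *= eta
            loss[k] *= eta
        if choice[t] >= 0 and outcome[t] >= 0:
            c = i if choice[t] == 0 else j
            if outcome[t] == 1:
                win[c] += eta
            else:
                loss[c] += eta
    return nll


def session_nll(
    x: np.ndarray, model: ModelSpec, session: CompiledSession
) -> float:
    """Negative log likelihood of a session at unconstrained parameters ``x``."""
    if session.n_valid == 0:
        raise ValueError("session has no valid choices")
    p = transform_params(x, model)
    return float(
        _replay_nll(
            p["beta_sm"],
            p["eta"],
            p.get("novelty_bias", 0.0),
            p.get("w_unc", 0.0),
            model.has_novelty_bias,
            model.has_uncertainty,
            model.gated,
            session.new_block,
            session.block_of,
            session.left,
            session.right,
            session.choice,
            session.outcome,
            session.valid,
            session.fam_left,
            session.fam_right,
            session.debut,
        )
    )


def make_objective(
    model: ModelSpec,
    session: CompiledSession,
    prior_mean: Optional[np.ndarray] = None,
    prior_var: Optional[np.ndarray] = None,
):
    """Return ``f(x)`` = negative log posterior (or likelihood) over
    unconstrained parameters.

    With a Gaussian prior the objective includes the prior's normalization
    constants, so ``-f(x*)`` enters the Laplace evidence directly.
    """
    if prior_mean is None:

        def nll_only(x: np.ndarray) -> float:
            return session_nll(np.asarray(x, dtype=float), model, session)

        return nll_only

    mu = np.asarray(prior_mean, dtype=float)
    var = np.asarray(prior_var, dtype=float)
    if mu.shape != (model.n_params,) or var.shape != (model.n_params,):
        raise ValueError("prior shape does not match model dimension")
    if np.any(var <= 0):
        raise ValueError("prior variances must be positive")
    log_norm = 0.5 * float(np.sum(np.log(2.0 * np.pi * var)))

    def neg_log_post(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        nll = session_nll(x, model, session)
        return nll + 0.5 * float(np.sum((x - mu) ** 2 / var)) + log_norm

    return neg_log_post
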