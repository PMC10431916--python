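"""Forgetful beta-Bernoulli learner and trial-wise choice-option features.

Each bandit option is represented by a beta belief over its reward
probability whose hyperparameters are recency-weighted win and loss
histories:

    alpha = 1 + sum_{t=0}^{T-1} eta^(T-t) * W_t
    beta  = 1 + sum_{t=0}^{T-1} eta^(T-t) * L_t

where ``T`` is the current trial index within the block, ``W_t``/``L_t``
indicate a win/loss outcome observed for that option on trial ``t``, and
``eta`` in [0, 1] geometrically discounts older outcomes.  ``eta = 1``
recovers exact conjugate beta-Bernoulli counting; smaller values weight
recent outcomes more heavily ("forgetting").

From the belief we derive, per option and trial:

- expected value ``Q``: the beta mean,
- uncertainty ``U``: the beta variance,
- novelty: the variance of ``Beta(n_seen + 1, 1)`` where ``n_seen`` is the
  option's lifetime presentation count (never reset across blocks),
- familiarity ``F = 1 - novelty``.

Beliefs reset at every block boundary (reward probabilities are
re-randomized per block); presentation counts persist for the whole
session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: two options count as having "similar expected value" when the absolute
#: difference of their beta means is strictly below this threshold
SIMILAR_EV_THRESHOLD = 0.05

__all__ = [
    "SIMILAR_EV_THRESHOLD",
    "BeliefState",
    "update_beliefs",
    "expected_value",
    "uncertainty",
    "novelty",
    "familiarity",
    "trial_feature_table",
]


def update_beliefs(history: Sequence[int], T: int, eta: float) -> tuple[float, float]:
    """Evaluate the recency-weighted beta hyperparameters from an outcome history.

    Parameters
    ----------
    history
        Win/loss indicators for trials ``0 .. T-1`` of the current block on
        which this option's outcome was observed: ``1`` for a win, ``0`` for
        a loss, ``None`` for trials where no outcome accrued to this option.
    T
        Current within-block trial index; must equal ``len(history)``.
    eta
        Recency weight in ``[0, 1]``.

    Returns
    -------
    (alpha, beta)
        Beta hyperparameters, each ``>= 1``.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    if len(history) != T:
        raise ValueError(f"history length {len(history)} != T = {T}")
    alpha = 1.0
    beta = 1.0
    for t, outcome in enumerate(history):
        if outcome is None:
            continue
        w = eta ** (T - t)
        if outcome:
            alpha += w
        else:
            beta += w
    return alpha, beta


def expected_value(alpha: float, beta: float) -> float:
    """Mean of the beta belief: ``Q = alpha / (alpha + beta)``."""
    _check_positive(alpha, beta)
    return alpha / (alpha + beta)


def uncertainty(alpha: float, beta: float) -> float:
    """Variance of the beta belief: ``alpha*beta / ((alpha+beta)^2 (alpha+beta+1))``."""
    _check_positive(alpha, beta)
    s = alpha + beta
    return alpha * beta / (s * s * (s + 1.0))


def novelty(encounters: int) -> float:
    """Novelty of an option seen ``encounters`` times: ``Var[Beta(encounters+1, 1)]``.

    Maximal (1/12) for a never-seen option and strictly decreasing in the
    presentation count; independent of reward history.
    """
    if encounters < 0:
        raise ValueError(f"encounter count must be >= 0, got {encounters}")
    return uncertainty(encounters + 1.0, 1.0)


def familiarity(novelty_value: float) -> float:
    """Familiarity gate ``F = 1 - novelty``."""
    return 1.0 - novelty_value


def _check_positive(alpha: float, beta: float) -> None:
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"beta hyperparameters must be positive, got ({alpha}, {beta})")


@dataclass
class BeliefState:
    """Running belief state over the options of the current block.

    Maintains, per block stimulus, incrementally discounted win/loss sums
    (``alpha = alpha0 + win_sum`` etc., where ``alpha0``/``beta0`` are the
    block-start hyperparameters, possibly inflated by a novelty bias), plus
    session-global presentation counts.

    The discount advances with every trial of the block for *all* options;
    only the chosen option's history receives the new outcome, entering
    with weight ``eta``.
    """

    eta: float = 1.0
    encounters: Dict[Hashable, int] = field(default_factory=dict)
    _win: Dict[Hashable, float] = field(default_factory=dict)
    _loss: Dict[Hashable, float] = field(default_factory=dict)
    _alpha0: Dict[Hashable, float] = field(default_factory=dict)
    _beta0: Dict[Hashable, float] = field(default_factory=dict)

    def start_block(
        self,
        stimuli: Iterable[Hashable],
        init: Optional[Mapping[Hashable, tuple[float, float]]] = None,
    ) -> None:
        """Reset beliefs for a new block.

        ``init`` optionally maps a stimulus to block-start hyperparameters
        ``(alpha0, beta0)``; stimuli not listed start at ``(1, 1)``.
        """
        self._win = {}
        self._loss = {}
        self._alpha0 = {}
        self._beta0 = {}
        for s in stimuli:
            a0, b0 = (init or {}).get(s, (1.0, 1.0))
            self._win[s] = 0.0
            self._loss[s] = 0.0
            self._alpha0[s] = a0
            self._beta0[s] = b0
            self.encounters.setdefault(s, 0)

    def hyperparameters(self, stimulus: Hashable) -> tuple[float, float]:
        return (
            self._alpha0[stimulus] + self._win[stimulus],
            self._beta0[stimulus] + self._loss[stimulus],
        )

    def ev(self, stimulus: Hashable) -> float:
        return expected_value(*self.hyperparameters(stimulus))

    def unc(self, stimulus: Hashable) -> float:
        return uncertainty(*self.hyperparameters(stimulus))

    def nov(self, stimulus: Hashable) -> float:
        return novelty(self.encounters.get(stimulus, 0))

    def record_trial(
        self,
        shown: Sequence[Hashable],
        chosen: Optional[Hashable],
        win: Optional[bool],
    ) -> None:
        """Advance one trial: discount all block options, append the chosen
        option's observed outcome (if any), and count presentations.

        ``chosen is None`` marks a missed trial; ``win is None`` marks a
        choice whose outcome was not revealed.  Presentation counts
        increment for every displayed stimulus regardless of choice.
        """
        for s in self._win:
            self._win[s] *= self.eta
            self._loss[s] *= self.eta
        if chosen is not None and win is not None:
            if win:
                self._win[chosen] += self.eta
            else:
                self._loss[chosen] += self.eta
        for s in shown:
            self.encounters[s] = self.encounters.get(s, 0) + 1


def trial_feature_table(trials: pd.DataFrame, eta: float = 1.0) -> pd.DataFrame:
    """Per-trial option features for one participant's session.

    Features for a trial are computed from beliefs *before* that trial's
    outcome; beliefs reset at block boundaries while presentation counts
    accumulate globally.  The left-minus-right differences ``d_ev``,
    ``d_unc`` and ``d_nov`` feed the choice regressions; the chosen-option
    columns feed the response-time regressions.  ``similar_ev`` flags
    trials with ``|d_ev| < 0.05`` (strict).

    Parameters
    ----------
    trials
        One participant's trial table in the session CSV schema
        (``block``, ``trial``, ``stim_left``, ``stim_right``, ``choice``,
        ``outcome`` columns at minimum), ordered by block then trial.
    eta
        Recency weight used to replay beliefs; the model-free analyses use
        ``eta = 1`` (pure counting).
    """
    required = {"block", "trial", "stim_left", "stim_right", "choice", "outcome"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    order = trials[["block", "trial"]].to_numpy()
    if not (np.diff(order[:, 0] * 10_000 + order[:, 1]) > 0).all():
        raise ValueError("trials must be strictly ordered by (block, trial)")

    state = BeliefState(eta=eta)
    rows = []
    current_block = None
    for rec in trials.itertuples(index=False):
        if rec.block != current_block:
            block_stims = trials.loc[
                trials["block"] == rec.block, ["stim_left", "stim_right"]
            ]
            stimuli = pd.unique(block_stims.to_numpy().ravel())
            state.start_block(stimuli)
            current_block = rec.block
        left, right = rec.stim_left, rec.stim_right
        f = {
            "block": rec.block,
            "trial": rec.trial,
            "ev_left": state.ev(left),
            "ev_right": state.ev(right),
            "unc_left": state.unc(left),
            "unc_right": state.unc(right),
            "nov_left": state.nov(left),
            "nov_right": state.nov(right),
        }
        f["d_ev"] = f["ev_left"] - f["ev_right"]
        f["d_unc"] = f["unc_left"] - f["unc_right"]
        f["d_nov"] = f["nov_left"] - f["nov_right"]
        f["similar_ev"] = bool(abs(f["d_ev"]) < SIMILAR_EV_THRESHOLD)
        if rec.choice == "left":
            chosen: Optional[Hashable] = left
        elif rec.choice == "right":
            chosen = right
        else:
            chosen = None
        side = "left" if chosen is left or chosen == left else "right"
        if chosen is None:
            f["ev_chosen"] = f["unc_chosen"] = f["nov_chosen"] = np.nan
        else:
            f["ev_chosen"] = f[f"ev_{side}"]
            f["unc_chosen"] = f[f"unc_{side}"]
            f["nov_chosen"] = f[f"nov_{side}"]
        rows.append(f)
        win = {"win": True, "loss": False}.get(rec.outcome)
        state.record_trial((left, right), chosen, win)
    table = pd.DataFrame(rows)
    for col in ("participant_id", "age_years", "age_group"):
        if col in trials.columns:
            table.insert(0, col, trials[col].to_numpy())
    return table
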