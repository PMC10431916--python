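"""The three-option explore-exploit task: structure, agents, cohorts.

The task has 10 blocks of 15 two-alternative choice trials.  Each block
draws on three stimuli ("hiding spots") with reward probabilities that are
a fresh random permutation of the block's difficulty triple — (0.8, 0.5,
0.2) on easy blocks, (0.7, 0.5, 0.3) on hard blocks — so learned values
never carry over between blocks.  Block 1 shows three never-seen stimuli;
every later block reuses two previously seen stimuli and introduces
exactly one new one, decoupling stimulus *novelty* (how often an option
has ever been displayed) from reward *uncertainty* (all options start
every block equally unknown).

Agents are simulated from any of the six choice models
(:mod:`.models`): on each trial utilities are computed from the agent's
beliefs, a choice is drawn from the softmax, and the outcome is drawn
from the chosen option's true reward probability.  Response times are
generated log-normally with configurable effects of the chosen option's
expected value (faster), novelty (slower) and uncertainty (slower), and a
small fraction of trials is injected as missed or implausibly fast
responses to exercise downstream exclusion logic.

A cohort mirrors the study design: 30 children (8-12 y), 30 adolescents
(13-17 y) and 62 adults (18-27 y), each group with its own generating
model and parameter distribution, plus a five-alternative surprise memory
test probing each block's best option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import beliefs as bf
from . import models as cm

__all__ = [
    "TaskConfig",
    "Block",
    "TaskStructure",
    "SessionData",
    "RTParams",
    "GroupSpec",
    "CohortConfig",
    "default_cohort_config",
    "age_group_of",
    "generate_task",
    "simulate_agent",
    "generate_cohort",
    "generate_memory_test",
    "task_from_session",
]

SESSION_COLUMNS = [
    "participant_id",
    "age_years",
    "age_group",
    "block",
    "block_difficulty",
    "trial",
    "stim_left",
    "stim_right",
    "prob_left",
    "prob_right",
    "choice",
    "outcome",
    "rt_sec",
]

MEMORY_COLUMNS = [
    "participant_id",
    "block",
    "option_1",
    "option_2",
    "option_3",
    "option_4",
    "option_5",
    "correct_id",
    "response_id",
]


@dataclass(frozen=True)
class TaskConfig:
    """Geometry of one task session."""

    n_blocks: int = 10
    trials_per_block: int = 15
    n_options_per_block: int = 3
    easy_probs: Tuple[float, float, float] = (0.8, 0.5, 0.2)
    hard_probs: Tuple[float, float, float] = (0.7, 0.5, 0.3)
    n_easy: int = 5
    stimulus_pool_size: int = 14
    response_deadline: float = 4.0
    #: "random": each trial's option pair drawn uniformly from the three
    #: possible pairs (reproduces the broad lifetime-presentation spread);
    #: "balanced": every pair shown trials_per_block // 3 times
    pair_scheduling: str = "random"

    def validate(self) -> None:
        if self.pair_scheduling not in ("random", "balanced"):
            raise ValueError(f"unknown pair_scheduling {self.pair_scheduling!r}")
        if self.n_options_per_block != 3:
            raise ValueError("the task uses exactly 3 options per block")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        if not 0 <= self.n_easy <= self.n_blocks:
            raise ValueError("n_easy must lie in [0, n_blocks]")
        for p in (*self.easy_probs, *self.hard_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reward probability {p} outside [0, 1]")
        # one new stimulus per block after the first
        if self.stimulus_pool_size < self.n_blocks + 2:
            raise ValueError(
                f"stimulus pool of {self.stimulus_pool_size} cannot supply one "
                f"new stimulus per block ({self.n_blocks + 2} needed)"
            )
        if self.response_deadline <= 0:
            raise ValueError("response deadline must be positive")


@dataclass(frozen=True)
class Block:
    index: int
    difficulty: str  # "easy" | "hard"
    stimuli: Tuple[str, str, str]
    probs: Tuple[float, float, float]  # aligned with stimuli
    trials: Tuple[Tuple[str, str], ...]  # (left stimulus, right stimulus)

    def prob_of(self, stimulus: str) -> float:
        return self.probs[self.stimuli.index(stimulus)]

    @property
    def best_stimulus(self) -> str:
        return self.stimuli[int(np.argmax(self.probs))]


@dataclass(frozen=True)
class TaskStructure:
    blocks: Tuple[Block, ...]
    unused_stimuli: Tuple[str, ...]
    config: TaskConfig = field(default_factory=TaskConfig)
    seed: Optional[int] = None

    @property
    def shown_stimuli(self) -> Tuple[str, ...]:
        out: List[str] = []
        for b in self.blocks:
            for s in b.stimuli:
                if s not in out:
                    out.append(s)
        return tuple(out)


@dataclass
class SessionData:
    """One participant's trial table plus optional memory-test table."""

    participant_id: str
    age_years: float
    trials: pd.DataFrame
    memory: Optional[pd.DataFrame] = None

    @property
    def age_group(self) -> str:
        return age_group_of(self.age_years)


def age_group_of(age_years: float) -> str:
    if age_years < 13.0:
        return "children"
    if age_years < 18.0:
        return "adolescents"
    return "adults"


def generate_task(config: TaskConfig, seed: int) -> TaskStructure:
    """Generate one randomized task session skeleton.

    Deterministic given ``seed``.  Difficulty labels (``n_easy`` easy, the
    rest hard) are shuffled across blocks; each block's probability triple
    is randomly assigned to its three stimuli.  Within a block each of the
    three option pairs appears ``trials_per_block // 3`` times (remainder
    trials drawn at random), in shuffled order, with random left/right
    placement.  Reused stimuli are drawn uniformly without replacement
    from all previously shown stimuli, which spreads lifetime presentation
    counts over a broad range.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    width = len(str(config.stimulus_pool_size - 1))
    pool = [f"stim_{i:0{width}d}" for i in range(config.stimulus_pool_size)]
    pool = list(rng.permutation(pool))

    difficulties = ["easy"] * config.n_easy + ["hard"] * (config.n_blocks - config.n_easy)
    rng.shuffle(difficulties)

    pairs_per_block = config.trials_per_block // 3
    remainder = config.trials_per_block - 3 * pairs_per_block
    all_pairs = [(0, 1), (0, 2), (1, 2)]

    seen: List[str] = []
    fresh = iter(pool)
    blocks: List[Block] = []
    for b in range(config.n_blocks):
        if b == 0:
            stimuli = [next(fresh) for _ in range(3)]
        else:
            reused = [seen[i] for i in rng.choice(len(seen), size=2, replace=False)]
            stimuli = reused + [next(fresh)]
        stimuli = list(rng.permutation(stimuli))
        seen.extend(s for s in stimuli if s not in seen)

        triple = config.easy_probs if difficulties[b] == "easy" else config.hard_probs
        probs = tuple(float(p) for p in rng.permutation(triple))

        if config.pair_scheduling == "balanced":
            pair_idx = all_pairs * pairs_per_block + [
                all_pairs[i] for i in rng.choice(3, size=remainder, replace=False)
            ]
            rng.shuffle(pair_idx)
        else:
            pair_idx = [
                all_pairs[i]
                for i in rng.integers(0, 3, size=config.trials_per_block)
            ]
        trials = []
        for i, j in pair_idx:
            if rng.random() < 0.5:
                i, j = j, i
            trials.append((stimuli[i], stimuli[j]))

        blocks.append(
            Block(
                index=b + 1,
                difficulty=difficulties[b],
                stimuli=tuple(stimuli),
                probs=probs,
                trials=tuple(trials),
            )
        )

    unused = tuple(s for s in pool if s not in seen)
    return TaskStructure(blocks=tuple(blocks), unused_stimuli=unused, config=config, seed=seed)


@dataclass(frozen=True)
class RTParams:
    """Log-normal response-time generator coefficients.

    ``log RT = intercept + b_ev*EV + b_nov*novelty + b_unc*U + N(0, sd)``
    over the chosen option's features.  Default signs mirror the fitted
    directions in this task family: higher expected value speeds
    responses, higher novelty and uncertainty slow them.
    """

    intercept: float = -0.35  # exp(-0.35) ~ 0.70 s median
    b_ev: float = -0.4
    b_nov: float = 3.0
    b_unc: float = 3.0
    sd: float = 0.25


def simulate_agent(
    task: TaskStructure,
    model: cm.ModelSpec,
    params: Mapping[str, float],
    seed: int,
    participant_id: str = "sim",
    age_years: float = 25.0,
    rt_params: RTParams = RTParams(),
    miss_rate: float = 0.0,
    fast_rate: float = 0.0,
) -> SessionData:
    """Simulate one agent playing a task under a choice model.

    On each trial the two displayed options' utilities are computed from
    the agent's current beliefs, the choice is sampled from the softmax
    probability, and the outcome is Bernoulli from the chosen stimulus's
    true reward probability.  Beliefs reset at block starts (with
    novelty-biased initialization of debuting stimuli where the model has
    one); presentation counts persist across blocks.  ``miss_rate`` /
    ``fast_rate`` inject missed trials (no choice, no outcome) and
    fast-guess trials (RT < 200 ms, outcome still shown).
    """
    for name in model.param_names:
        if name not in params:
            raise ValueError(f"model {model.name} requires parameter {name!r}")
    cm.inverse_transform(params, model)  # range validation
    rng = np.random.default_rng(seed)
    state = bf.BeliefState(eta=params["eta"])
    deadline = task.config.response_deadline

    rows = []
    for block in task.blocks:
        init = {
            s: cm.initial_hyperparameters(model, params, state.encounters.get(s, 0) == 0)
            for s in block.stimuli
        }
        state.start_block(block.stimuli, init)
        for t, (left, right) in enumerate(block.trials, start=1):
            feats = {}
            for side, stim in (("left", left), ("right", right)):
                q = state.ev(stim)
                u = state.unc(stim)
                f = bf.familiarity(state.nov(stim))
                feats[side] = (q, u, f, cm.option_utility(model, q, u, f, params))
            p_left = cm.choice_probability(feats["left"][3], feats["right"][3], params["beta_sm"])

            missed = rng.random() < miss_rate
            if missed:
                choice, outcome, rt = "missed", "none", np.nan
                chosen_stim, win = None, None
            else:
                choice = "left" if rng.random() < p_left else "right"
                chosen_stim = left if choice == "left" else right
                win = rng.random() < block.prob_of(chosen_stim)
                outcome = "win" if win else "loss"
                if rng.random() < fast_rate:
                    rt = float(rng.uniform(0.05, 0.19))
                else:
                    q, u, f, _ = feats[choice]
                    log_rt = (
                        rt_params.intercept
                        + rt_params.b_ev * q
                        + rt_params.b_nov * (1.0 - f)
                        + rt_params.b_unc * u
                        + rng.normal(0.0, rt_params.sd)
                    )
                    rt = float(np.clip(np.exp(log_rt), MIN_SIM_RT, deadline))
            rows.append(
                {
                    "participant_id": participant_id,
                    "age_years": age_years,
                    "age_group": age_group_of(age_years),
                    "block": block.index,
                    "block_difficulty": block.difficulty,
                    "trial": t,
                    "stim_left": left,
                    "stim_right": right,
                    "prob_left": block.prob_of(left),
                    "prob_right": block.prob_of(right),
                    "choice": choice,
                    "outcome": outcome,
                    "rt_sec": rt,
                }
            )
            state.record_trial((left, right), chosen_stim, win)
    return SessionData(
        participant_id=participant_id,
        age_years=age_years,
        trials=pd.DataFrame(rows, columns=SESSION_COLUMNS),
    )


MIN_SIM_RT = 0.25  # floor for generated regular responses, above the exclusion cut


@dataclass(frozen=True)
class GroupSpec:
    """Generating model and parameter distribution for one age group."""

    name: str
    age_range: Tuple[float, float]
    n_subjects: int
    model: str
    param_means: Mapping[str, float]
    param_sds: Mapping[str, float]

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"group {self.name}: n_subjects must be >= 1")
        spec = cm.get_model(self.model)
        for p in spec.param_names:
            if p not in self.param_means:
                raise ValueError(f"group {self.name}: missing mean for {p!r}")
            if self.param_sds.get(p, 0.0) < 0:
                raise ValueError(f"group {self.name}: SD for {p!r} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    groups: Tuple[GroupSpec, ...]
    task: TaskConfig = field(default_factory=TaskConfig)
    rt_params: RTParams = field(default_factory=RTParams)
    miss_rate: float = 0.006
    fast_rate: float = 0.004
    memory_accuracy: float = 0.25

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for g in self.groups:
            g.validate()
        self.task.validate()


def default_cohort_config() -> CohortConfig:
    """Study-design cohort: 30 children generated from the novelty-bias
    model (optimistic initialization, N ~ 1.49), 30 adolescents and 62
    adults from the familiarity-gated uncertainty model (uncertainty
    weight ~ -0.15)."""
    fam_gate = {
        "model": "familiarity_gate",
        "param_means": {"beta_sm": 6.0, "eta": 0.7, "w_unc": -0.15},
        "param_sds": {"beta_sm": 1.0, "eta": 0.05, "w_unc": 0.1},
    }
    return CohortConfig(
        groups=(
            GroupSpec(
                name="children",
                age_range=(8.0, 13.0),
                n_subjects=30,
                model="novelty_bias",
                param_means={"beta_sm": 6.0, "eta": 0.7, "novelty_bias": 1.49},
                param_sds={"beta_sm": 1.0, "eta": 0.05, "novelty_bias": 0.5},
            ),
            GroupSpec(name="adolescents", age_range=(13.0, 18.0), n_subjects=30, **fam_gate),
            GroupSpec(name="adults", age_range=(18.0, 28.0), n_subjects=62, **fam_gate),
        )
    )


def _draw_params(spec: cm.ModelSpec, group: GroupSpec, rng: np.random.Generator) -> Dict[str, float]:
    params: Dict[str, float] = {}
    for p in spec.param_names:
        v = rng.normal(group.param_means[p], group.param_sds.get(p, 0.0))
        if p == "beta_sm":
            v = float(np.clip(v, 0.1, cm.BETA_SM_MAX - 0.1))
        elif p == "eta":
            v = float(np.clip(v, 0.01, 0.99))
        params[p] = float(v)
    return params


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[List[SessionData], pd.DataFrame]:
    """Generate a full synthetic cohort plus its ground-truth parameter table.

    Each subject gets an independent task randomization, parameters drawn
    from their group's distribution (``beta_sm``/``eta`` truncated to
    their open ranges), a simulated session with injected missed/fast
    trials, and a simulated memory test.
    """
    config.validate()
    root = np.random.SeedSequence(seed)
    sessions: List[SessionData] = []
    truth_rows = []
    counter = 0
    for group in config.groups:
        spec = cm.get_model(group.model)
        for _ in range(group.n_subjects):
            counter += 1
            pid = f"sub_{counter:03d}"
            s_task, s_par, s_sim, s_age, s_mem = [
                int(c.generate_state(1)[0] % 2**31) for c in root.spawn(5)
            ]
            rng = np.random.default_rng(s_par)
            age = float(np.random.default_rng(s_age).uniform(*group.age_range))
            params = _draw_params(spec, group, rng)
            task = generate_task(config.task, s_task)
            session = simulate_agent(
                task,
                spec,
                params,
                seed=s_sim,
                participant_id=pid,
                age_years=age,
                rt_params=config.rt_params,
                miss_rate=config.miss_rate,
                fast_rate=config.fast_rate,
            )
            memory = generate_memory_test(
                task, seed=s_mem, accuracy=config.memory_accuracy
            )
            memory.insert(0, "participant_id", pid)
            session.memory = memory
            sessions.append(session)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "age_years": age,
                    "age_group": age_group_of(age),
                    "group": group.name,
                    "model": spec.name,
                    **{f"true_{k}": v for k, v in params.items()},
                }
            )
    return sessions, pd.DataFrame(truth_rows)


def generate_memory_test(
    task: TaskStructure, seed: int, accuracy: float = 0.25
) -> pd.DataFrame:
    """Simulate the five-alternative surprise memory test.

    One probe per block.  The array holds the block's best option (the
    correct answer), the block's two other options, one previously shown
    stimulus from a different block, and one never-shown stimulus.  The
    simulated responder picks the correct option with probability
    ``accuracy`` and otherwise uniformly among the four distractors.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if not task.unused_stimuli:
        raise ValueError("no never-shown stimulus available for the memory array")
    if len(task.blocks) < 2:
        raise ValueError("memory array needs an old stimulus from a different block")
    rng = np.random.default_rng(seed)
    rows = []
    for block in task.blocks:
        others = [
            s
            for b in task.blocks
            if b.index != block.index
            for s in b.stimuli
            if s not in block.stimuli
        ]
        if not others:
            raise ValueError(f"block {block.index}: no old stimulus from another block")
        old = others[rng.integers(len(others))]
        new = task.unused_stimuli[rng.integers(len(task.unused_stimuli))]
        options = list(rng.permutation(list(block.stimuli) + [old, new]))
        correct = block.best_stimulus
        if rng.random() < accuracy:
            response = correct
        else:
            distractors = [o for o in options if o != correct]
            response = distractors[rng.integers(4)]
        rows.append(
            {
                "block": block.index,
                **{f"option_{i+1}": o for i, o in enumerate(options)},
                "correct_id": correct,
                "response_id": response,
            }
        )
    return pd.DataFrame(rows)


def task_from_session(trials: pd.DataFrame) -> TaskStructure:
    """Reconstruct a task skeleton (stimuli, probabilities, trial pairings)
    from a session's trial table, e.g. to reuse a participant's exact trial
    sequence when simulating agents from fitted parameters."""
    blocks = []
    for b, chunk in trials.groupby("block", sort=True):
        chunk = chunk.sort_values("trial")
        stim_prob: Dict[str, float] = {}
        for rec in chunk.itertuples(index=False):
            stim_prob[rec.stim_left] = float(rec.prob_left)
            stim_prob[rec.stim_right] = float(rec.prob_right)
        stimuli = tuple(stim_prob)
        if len(stimuli) > 3:
            raise ValueError(f"block {b} shows more than 3 stimuli")
        blocks.append(
            Block(
                index=int(b),
                difficulty=str(chunk["block_difficulty"].iloc[0]),
                stimuli=stimuli,
                probs=tuple(stim_prob[s] for s in stimuli),
                trials=tuple(
                    (rec.stim_left, rec.stim_right) for rec in chunk.itertuples(index=False)
                ),
            )
        )
    return TaskStructure(blocks=tuple(blocks), unused_stimuli=(), config=TaskConfig(), seed=None)
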