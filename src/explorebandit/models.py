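"""The six reinforcement-learning choice models and their parameterization.

All models share the forgetful beta-Bernoulli learner (:mod:`.beliefs`) and
a softmax choice rule

    p(choose 1) = 1 / (1 + exp(beta_sm * (V2 - V1)))

with inverse temperature ``beta_sm``.  They differ in how an option's
utility ``V`` is assembled from its expected value ``Q``, uncertainty ``U``
and familiarity ``F``:

===========================  ==========================  ==============
model                        utility                     free parameters
===========================  ==========================  ==============
baseline                     V = Q                       beta_sm, eta
novelty_bias                 V = Q (biased init)         + N
uncertainty_bias             V = Q + w_U * U             + w_U
novelty_uncertainty_bias     V = Q + w_U * U             + N, w_U
familiarity_gate             V = Q + F * U * w_U         + w_U
novelty_familiarity_gate     V = Q + F * U * w_U         + N, w_U
===========================  ==========================  ==============

The novelty bias ``N`` inflates a stimulus's block-start hyperparameters on
its first-ever appearance in the task: ``alpha0 = 1 + N`` when ``N >= 0``
(optimistic initialization) or ``beta0 = 1 + |N|`` when ``N < 0``
(pessimistic).  The uncertainty weight ``w_U`` is signed (negative =
uncertainty aversion); the familiarity gate ``F = 1 - novelty`` makes
uncertainty count more for familiar options.

For Gaussian-prior fitting, parameters live in an unconstrained space:
``beta_sm = 20 * sigmoid(x)``, ``eta = sigmoid(x)``; ``N`` and ``w_U`` map
by identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
from scipy.special import expit, log_expit, logit

BETA_SM_MAX = 20.0

__all__ = [
    "BETA_SM_MAX",
    "ModelSpec",
    "MODELS",
    "MODEL_NAMES",
    "CLI_ALIASES",
    "get_model",
    "transform_params",
    "inverse_transform",
    "initial_hyperparameters",
    "option_utility",
    "choice_probability",
    "log_choice_probability",
]


@dataclass(frozen=True)
class ModelSpec:
    """Identity and parameterization of one choice-model variant."""

    name: str
    has_novelty_bias: bool
    has_uncertainty: bool
    gated: bool

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["beta_sm", "eta"]
        if self.has_novelty_bias:
            names.append("novelty_bias")
        if self.has_uncertainty:
            names.append("w_unc")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


MODELS: Dict[str, ModelSpec] = {
    m.name: m
    for m in (
        ModelSpec("baseline", False, False, False),
        ModelSpec("novelty_bias", True, False, False),
        ModelSpec("uncertainty_bias", False, True, False),
        ModelSpec("novelty_uncertainty_bias", True, True, False),
        ModelSpec("familiarity_gate", False, True, True),
        ModelSpec("novelty_familiarity_gate", True, True, True),
    )
}
MODEL_NAMES: tuple[str, ...] = tuple(MODELS)

# stable short names for command-line use
CLI_ALIASES: Dict[str, str] = {
    "baseline": "baseline",
    "novelty": "novelty_bias",
    "uncertainty": "uncertainty_bias",
    "novelty-uncertainty": "novelty_uncertainty_bias",
    "fam-gate": "familiarity_gate",
    "novelty-fam-gate": "novelty_familiarity_gate",
}


def get_model(name: str) -> ModelSpec:
    """Look up a model by canonical name or CLI alias."""
    key = CLI_ALIASES.get(name, name)
    try:
        return MODELS[key]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; expected one of {sorted(MODELS)} "
            f"or aliases {sorted(CLI_ALIASES)}"
        ) from None


def transform_params(x: Sequence[float], model: ModelSpec) -> Dict[str, float]:
    """Map an unconstrained vector to constrained parameters.

    ``beta_sm = 20 * sigmoid(x0)`` in (0, 20); ``eta = sigmoid(x1)`` in
    (0, 1); ``novelty_bias`` and ``w_unc`` pass through unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_params,):
        raise ValueError(
            f"{model.name} expects {model.n_params} parameters, got shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite unconstrained parameters: {x}")
    params = {"beta_sm": BETA_SM_MAX * expit(x[0]), "eta": expit(x[1])}
    i = 2
    if model.has_novelty_bias:
        params["novelty_bias"] = x[i]
        i += 1
    if model.has_uncertainty:
        params["w_unc"] = x[i]
    return params


def inverse_transform(params: Mapping[str, float], model: ModelSpec) -> np.ndarray:
    """Map constrained parameters back to the unconstrained space.

    Boundary values (``beta_sm`` in {0, 20}, ``eta`` in {0, 1}) have no
    finite image and raise.
    """
    beta_sm = params["beta_sm"]
    eta = params["eta"]
    if not 0.0 < beta_sm < BETA_SM_MAX:
        raise ValueError(f"beta_sm must lie strictly in (0, {BETA_SM_MAX}), got {beta_sm}")
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must lie strictly in (0, 1), got {eta}")
    x = [logit(beta_sm / BETA_SM_MAX), logit(eta)]
    if model.has_novelty_bias:
        x.append(params["novelty_bias"])
    if model.has_uncertainty:
        x.append(params["w_unc"])
    return np.asarray(x, dtype=float)


def initial_hyperparameters(
    model: ModelSpec, params: Mapping[str, float], debut: bool
) -> tuple[float, float]:
    """Block-start beta hyperparameters for one stimulus.

    Every option starts a block at ``(1, 1)`` except a stimulus making its
    first-ever task appearance under a novelty-bias model, which starts at
    ``(1 + N, 1)`` for ``N >= 0`` or ``(1, 1 + |N|)`` for ``N < 0``.  A
    previously seen stimulus always reinitializes at ``(1, 1)``.
    """
    if model.has_novelty_bias and debut:
        n = params["novelty_bias"]
        if n >= 0:
            return 1.0 + n, 1.0
        return 1.0, 1.0 - n
    return 1.0, 1.0


def option_utility(
    model: ModelSpec,
    q: float,
    u: float,
    f: float,
    params: Mapping[str, float],
) -> float:
    """Utility ``V`` of one option given its belief features.

    Baseline and novelty-bias models use ``V = Q``; the separable
    uncertainty models add ``w_U * U``; the familiarity-gated models add
    ``F * U * w_U``.
    """
    v = q
    if model.has_uncertainty:
        w = params["w_unc"]
        if model.gated:
            w = w * f
        v = v + w * u
    return v


def choice_probability(v1: float, v2: float, beta_sm: float) -> float:
    """Softmax probability of choosing option 1 over option 2."""
    return float(expit(beta_sm * (np.asarray(v1) - np.asarray(v2))))


def log_choice_probability(v1: float, v2: float, beta_sm: float) -> float:
    """Overflow-safe ``log p(choose option 1)``."""
    return float(log_expit(beta_sm * (np.asarray(v1) - np.asarray(v2))))
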