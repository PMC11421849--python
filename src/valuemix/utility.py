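"""Utility models and the softmax choice rule for two-attribute options.

Each option carries a reward magnitude ``X`` and a reward probability ``P``,
both rescaled to [0, 1].  Five candidate models map (X, P) to a scalar
utility:

* ``EV``       multiplicative (expected value): ``U = X * P``
* ``AU``       additive (weighted sum): ``U = gamma * X + (1 - gamma) * P``
* ``EV+DN``    expected value divisively normalised by the summed EV of the
               option set: ``U_i = EV_i / sum_j EV_j``
* ``COMP``     composite mixture of EV and AU governed by the integration
               coefficient eta: ``U = eta * EV + (1 - eta) * AU``
* ``PROSPECT`` power utility on magnitude with one-parameter Prelec
               probability weighting: ``U = X**alpha * exp(-(-ln P)**delta)``

Choice between two chooseable options is a softmax with inverse temperature
theta; the third (distractor) option never enters the softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "Option",
    "UtilityParams",
    "ev_utility",
    "au_utility",
    "dn_utility",
    "composite_utility",
    "prospect_prelec_utility",
    "choice_prob_softmax",
    "pair_utilities",
]

#: Canonical model identifiers used in configs and outputs.
MODEL_NAMES = ("EV", "AU", "EV+DN", "COMP", "PROSPECT")

#: Free parameters of each model, in optimisation order.
PARAM_NAMES = {
    "EV": ("theta",),
    "AU": ("gamma", "theta"),
    "EV+DN": ("theta",),
    "COMP": ("eta", "gamma", "theta"),
    "PROSPECT": ("alpha", "delta", "theta"),
}

#: Box bounds for every free parameter.  theta is unbounded above in
#: principle; 100 exceeds typical cohort-level inverse temperatures by an
#: order of magnitude while keeping the optimiser stable.
PARAM_BOUNDS = {
    "eta": (0.0, 1.0),
    "gamma": (0.0, 1.0),
    "theta": (0.0, 100.0),
    "alpha": (1e-3, 5.0),
    "delta": (1e-3, 5.0),
}


@dataclass(frozen=True)
class Option:
    """One choice stimulus: magnitude X and probability P, both in [0, 1]."""

    X: float
    P: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.X <= 1.0):
            raise ValueError(f"magnitude X={self.X} outside [0, 1]")
        if not (0.0 <= self.P <= 1.0):
            raise ValueError(f"probability P={self.P} outside [0, 1]")


@dataclass
class UtilityParams:
    """Model identity plus its free parameters.

    Parameters not used by ``model`` may be left as None and are ignored.
    ``validate()`` raises on any bound violation of the parameters the model
    actually uses.
    """

    model: str
    eta: Optional[float] = None
    gamma: Optional[float] = None
    theta: Optional[float] = None
    alpha: Optional[float] = None
    delta: Optional[float] = None

    def validate(self) -> "UtilityParams":
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODEL_NAMES}")
        for name in PARAM_NAMES[self.model]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"model {self.model} requires parameter {name}")
            lo, hi = PARAM_BOUNDS[name]
            if not (lo <= value <= hi):
                raise ValueError(f"parameter {name}={value} outside [{lo}, {hi}]")
        return self

    def to_vector(self) -> np.ndarray:
        """Free parameters as an array in canonical order."""
        self.validate()
        return np.array([getattr(self, n) for n in PARAM_NAMES[self.model]], dtype=float)

    @classmethod
    def from_vector(cls, model: str, vector: Sequence[float]) -> "UtilityParams":
        names = PARAM_NAMES[model]
        if len(vector) != len(names):
            raise ValueError(f"model {model} expects {len(names)} parameters, got {len(vector)}")
        return cls(model=model, **dict(zip(names, map(float, vector))))


def ev_utility(option: Option) -> float:
    """Multiplicative (expected value) utility X * P."""
    return option.X * option.P


def au_utility(option: Option, gamma: float) -> float:
    """Additive utility gamma * X + (1 - gamma) * P.

    gamma is the magnitude/probability weighing ratio in [0, 1].
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError(f"gamma={gamma} outside [0, 1]")
    return gamma * option.X + (1.0 - gamma) * option.P


def dn_utility(options: Sequence[Option]) -> np.ndarray:
    """Divisively normalised expected values: U_i = EV_i / sum_j EV_j.

    Normalises over exactly the options passed in.  Model fitting passes the
    two chooseable options only, so N=2 in practice.
    """
    if len(options) < 2:
        raise ValueError("dn_utility requires at least 2 options")
    evs = np.array([ev_utility(o) for o in options], dtype=float)
    total = evs.sum()
    if total <= 0.0:
        raise ValueError("degenerate normalisation denominator: all EVs zero")
    return evs / total


def composite_utility(option: Option, eta: float, gamma: float) -> float:
    """Mixture of EV and AU: U = eta * (X*P) + (1-eta) * (gamma*X + (1-gamma)*P).

    eta is the integration coefficient: 1 recovers the multiplicative rule,
    0 the additive rule.
    """
    if not (0.0 <= eta <= 1.0):
        raise ValueError(f"eta={eta} outside [0, 1]")
    return eta * ev_utility(option) + (1.0 - eta) * au_utility(option, gamma)


def prospect_prelec_utility(option: Option, alpha: float, delta: float) -> float:
    """Prospect-style utility: X**alpha weighted by the one-parameter Prelec
    probability distortion w(P) = exp(-(-ln P)**delta).

    alpha = delta = 1 reduces to EV.  P = 0 maps to utility 0 by continuity.
    """
    if alpha <= 0.0 or delta <= 0.0:
        raise ValueError("alpha and delta must be positive")
    if option.P == 0.0 or option.X == 0.0:
        return 0.0
    weight = np.exp(-((-np.log(option.P)) ** delta))
    return float(option.X**alpha * weight)


def choice_prob_softmax(utilities: Sequence[float], theta: float) -> np.ndarray:
    """Softmax choice probabilities over a pair of utilities.

    p(choice = i) = exp(theta * U_i) / sum_j exp(theta * U_j), computed in a
    max-subtracted form so large theta * U cannot overflow.
    """
    if theta < 0:
        raise ValueError("inverse temperature theta must be >= 0")
    u = np.asarray(utilities, dtype=float)
    if u.shape != (2,):
        raise ValueError("choice_prob_softmax expects exactly two utilities")
    z = theta * u
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def pair_utilities(
    model: str,
    vector: np.ndarray,
    x1: np.ndarray,
    p1: np.ndarray,
    x2: np.ndarray,
    p2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorised utilities of the two chooseable options on every trial.

    Returns (u1, u2, theta).  This is the hot path of maximum-likelihood
    fitting; it mirrors the scalar functions above exactly.
    """
    if model == "EV":
        (theta,) = vector
        u1, u2 = x1 * p1, x2 * p2
    elif model == "AU":
        gamma, theta = vector
        u1 = gamma * x1 + (1.0 - gamma) * p1
        u2 = gamma * x2 + (1.0 - gamma) * p2
    elif model == "EV+DN":
        (theta,) = vector
        ev1, ev2 = x1 * p1, x2 * p2
        total = ev1 + ev2
        if np.any(total <= 0.0):
            raise ValueError("degenerate normalisation denominator: all EVs zero")
        u1, u2 = ev1 / total, ev2 / total
    elif model == "COMP":
        eta, gamma, theta = vector
        u1 = eta * x1 * p1 + (1.0 - eta) * (gamma * x1 + (1.0 - gamma) * p1)
        u2 = eta * x2 * p2 + (1.0 - eta) * (gamma * x2 + (1.0 - gamma) * p2)
    elif model == "PROSPECT":
        alpha, delta, theta = vector
        with np.errstate(divide="ignore"):
            w1 = np.where(p1 > 0, np.exp(-((-np.log(np.maximum(p1, 1e-300))) ** delta)), 0.0)
            w2 = np.where(p2 > 0, np.exp(-((-np.log(np.maximum(p2, 1e-300))) ** delta)), 0.0)
        u1 = np.where(x1 > 0, x1**alpha, 0.0) * w1
        u2 = np.where(x2 > 0, x2**alpha, 0.0) * w2
    else:
        raise ValueError(f"unknown model {model!r}")
    return u1, u2, float(theta)
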