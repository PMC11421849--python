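"""Synthetic task designs and simulated choice agents.

The generator emulates the structure of the two-attribute gambling task the
analyses assume: per participant, 150 distractor trials (three options, the
third unchooseable) and 150 two-option control trials whose (H, L) attribute
conditions are drawn from the distractor trials, so every distractor trial
has at least one matched control condition (the many-to-one structure the
matched-trial analysis requires).  Choices are drawn from a softmax over
model-defined utilities of the two chooseable options; a small fraction of
distractor trials can be replaced by erroneous choices of the unchooseable
distractor, to exercise the downstream exclusion filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import DISTRACTOR, TWO_OPTION, ChoiceDataset
from .utility import PARAM_NAMES, UtilityParams, pair_utilities

__all__ = [
    "DEFAULT_ATTRIBUTE_GRID",
    "TaskDesign",
    "SyntheticCohortSpec",
    "generate_task_design",
    "simulate_agent_choices",
    "generate_cohort",
]

#: Default attribute grid: 10 evenly spaced levels per attribute on
#: [0.1, 1.0].  Avoids degenerate zero-utility options while spanning the
#: unit interval the utilities are defined on.
DEFAULT_ATTRIBUTE_GRID = tuple(
    (float(x), float(p))
    for x in np.round(np.linspace(0.1, 1.0, 10), 10)
    for p in np.round(np.linspace(0.1, 1.0, 10), 10)
)


@dataclass
class TaskDesign:
    """Ordered trial specifications without choices.

    ``trials`` has columns ``trial_type, x1, p1, x2, p2, x3, p3``; distractor
    trials carry three options, two-option trials two (x3/p3 NaN).
    """

    trials: pd.DataFrame
    design_id: str = "design"
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def generate_task_design(
    n_distractor: int,
    n_two_option: int,
    attribute_grid: Sequence[tuple[float, float]] = DEFAULT_ATTRIBUTE_GRID,
    seed: int = 0,
    design_id: str = "design",
) -> TaskDesign:
    """Generate a task design with the matched-trial guarantee.

    Distractor trials draw three distinct grid points; two-option trials
    re-sample (with replacement) the chooseable pairs of the distractor
    trials, so every distractor trial's (H, L) condition occurs in at least
    one two-option trial and the number of unique two-option conditions is
    at most ``n_two_option``.
    """
    grid = list(attribute_grid)
    if not grid:
        raise ValueError("empty attribute grid")
    for x, p in grid:
        if not (0.0 <= x <= 1.0 and 0.0 <= p <= 1.0):
            raise ValueError(f"grid value ({x}, {p}) outside [0, 1]")
    if n_distractor > 0 and n_two_option == 0:
        raise ValueError("unmatched design: distractor trials require two-option trials")
    rng = _rng(seed, 0)
    rows = []
    grid_arr = np.array(grid, dtype=float)
    # pool of chooseable (H, L) pairs shared by the two trial types; its size
    # is capped at n_two_option so every pair used on a distractor trial can
    # be covered by at least one two-option control trial
    n_pool = min(n_distractor, n_two_option) if n_distractor > 0 else n_two_option
    pool = []
    for _ in range(max(n_pool, 0)):
        k = rng.choice(len(grid_arr), size=2, replace=len(grid_arr) < 2)
        (x1, p1), (x2, p2) = grid_arr[k]
        pool.append((x1, p1, x2, p2))
    used = []
    seen = set()
    for _ in range(n_distractor):
        x1, p1, x2, p2 = pool[int(rng.integers(0, len(pool)))]
        k = rng.choice(len(grid_arr))
        x3, p3 = grid_arr[k]
        rows.append((DISTRACTOR, x1, p1, x2, p2, x3, p3))
        key = (x1, p1, x2, p2)
        if key not in seen:
            seen.add(key)
            used.append(key)
    if n_two_option > 0:
        if used:
            # cover every pair a distractor trial uses once, then resample
            # with replacement: unique control conditions <= n_two_option
            # and the matching stage never finds zero matches
            extra = n_two_option - len(used)
            idx = rng.integers(0, len(used), size=max(extra, 0))
            chosen_pairs = used + [used[i] for i in idx]
        else:
            chosen_pairs = pool
        for x1, p1, x2, p2 in chosen_pairs:
            rows.append((TWO_OPTION, x1, p1, x2, p2, np.nan, np.nan))
    trials = pd.DataFrame(
        rows, columns=["trial_type", "x1", "p1", "x2", "p2", "x3", "p3"]
    )
    # interleave deterministically so trial order mixes the two types
    if len(trials):
        order = rng.permutation(len(trials))
        trials = trials.iloc[order].reset_index(drop=True)
    return TaskDesign(trials=trials, design_id=design_id, seed=seed)


def simulate_agent_choices(
    design: TaskDesign,
    params: UtilityParams,
    distractor_choice_rate: float = 0.0,
    seed: int = 0,
    distractor_bias: float = 0.0,
) -> ChoiceDataset:
    """Simulate one agent's choices on a task design.

    Choices are drawn between the two chooseable options with softmax
    probabilities under ``params``; the distractor never enters the softmax.
    On distractor trials, with probability ``distractor_choice_rate`` the
    recorded choice is replaced by the (unchooseable) distractor, emulating
    the occasional erroneous distractor choices real participants make.

    ``distractor_bias`` (default 0 = off) adds ``bias * (U_D - U_H)`` to the
    log-odds of choosing the higher-utility option on distractor trials,
    producing agents whose relative accuracy depends on the distractor —
    the positive/negative controls for the distractor regression.
    """
    params.validate()
    if not (0.0 <= distractor_choice_rate < 1.0):
        raise ValueError("distractor_choice_rate must lie in [0, 1)")
    t = design.trials
    vector = params.to_vector()
    x1 = t["x1"].to_numpy(float)
    p1 = t["p1"].to_numpy(float)
    x2 = t["x2"].to_numpy(float)
    p2 = t["p2"].to_numpy(float)
    u1, u2, theta = pair_utilities(params.model, vector, x1, p1, x2, p2)
    z1 = theta * (u1 - u2)
    is_distractor = (t["trial_type"] == DISTRACTOR).to_numpy()
    if distractor_bias != 0.0 and is_distractor.any():
        x3 = t["x3"].to_numpy(float)
        p3 = t["p3"].to_numpy(float)
        ud = np.where(is_distractor, _option_utility(params.model, vector, x3, p3), 0.0)
        uh = np.maximum(u1, u2)
        sign = np.where(u1 >= u2, 1.0, -1.0)
        z1 = z1 + np.where(is_distractor, sign * distractor_bias * (ud - uh), 0.0)
    prob1 = 1.0 / (1.0 + np.exp(-np.clip(z1, -700, 700)))
    rng = _rng(seed, 1)
    chosen = np.where(rng.random(len(t)) < prob1, 1, 2)
    if distractor_choice_rate > 0.0:
        slip = rng.random(len(t)) < distractor_choice_rate
        chosen = np.where(is_distractor & slip, 3, chosen)
    trials = t.copy()
    trials["chosen"] = chosen.astype(int)
    return ChoiceDataset(
        participant_id=f"{design.design_id}-agent",
        trials=trials,
        meta={"true_params": params, "seed": seed, "distractor_bias": distractor_bias},
    )


def _option_utility(model: str, vector: np.ndarray, x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Single-option utility for the bias term (EV+DN falls back to EV here,
    since normalisation is only defined over an option set)."""
    if model in ("EV", "EV+DN"):
        return x * p
    if model == "AU":
        gamma = vector[0]
        return gamma * x + (1 - gamma) * p
    if model == "COMP":
        eta, gamma = vector[0], vector[1]
        return eta * x * p + (1 - eta) * (gamma * x + (1 - gamma) * p)
    if model == "PROSPECT":
        alpha, delta = vector[0], vector[1]
        with np.errstate(divide="ignore"):
            w = np.where(p > 0, np.exp(-((-np.log(np.maximum(p, 1e-300))) ** delta)), 0.0)
        return np.where(x > 0, x**alpha, 0.0) * w
    raise ValueError(f"unknown model {model!r}")


@dataclass
class SyntheticCohortSpec:
    """Conditions under which a synthetic cohort is generated.

    Parameter laws are (low, high) uniform ranges; a degenerate range
    (low == high) is a point mass.  Defaults follow the study conditions:
    150 distractor + 150 two-option trials per participant and a small
    nonzero rate of erroneous distractor choices.
    """

    n_participants: int
    n_distractor_trials: int = 150
    n_two_option_trials: int = 150
    generative_model: str = "COMP"
    eta_range: tuple[float, float] = (0.0, 1.0)
    gamma_range: tuple[float, float] = (0.4, 0.4)
    theta_range: tuple[float, float] = (9.6, 9.6)
    alpha_range: tuple[float, float] = (0.8, 0.8)
    delta_range: tuple[float, float] = (1.0, 1.0)
    distractor_choice_rate: float = 0.02
    attribute_grid: Sequence[tuple[float, float]] = DEFAULT_ATTRIBUTE_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.distractor_choice_rate < 1.0):
            raise ValueError("distractor_choice_rate must lie in [0, 1)")
        for name in ("eta_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name}=({lo}, {hi}) outside [0, 1]")
        lo, hi = self.theta_range
        if not (0.0 <= lo <= hi):
            raise ValueError("theta_range must be nonnegative and ordered")


def generate_cohort(
    spec: SyntheticCohortSpec,
    distractor_bias_fn=None,
) -> list[tuple[ChoiceDataset, UtilityParams]]:
    """Generate a cohort of simulated participants with known parameters.

    Each participant gets a fresh task design and parameters sampled from
    the spec's ranges; the generating parameters are returned alongside the
    dataset.  ``distractor_bias_fn(params) -> float`` optionally couples the
    distractor sensitivity of each agent to its parameters (used for
    positive-control cohorts); default no bias.
    """
    if spec.n_participants < 0:
        raise ValueError("n_participants must be >= 0")
    rng = _rng(spec.seed, 2)
    out = []
    for i in range(spec.n_participants):
        design = generate_task_design(
            spec.n_distractor_trials,
            spec.n_two_option_trials,
            spec.attribute_grid,
            seed=int(rng.integers(0, 2**31 - 1)),
            design_id=f"sim{i:03d}",
        )
        params = _sample_params(spec, rng)
        bias = float(distractor_bias_fn(params)) if distractor_bias_fn else 0.0
        ds = simulate_agent_choices(
            design,
            params,
            distractor_choice_rate=spec.distractor_choice_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            distractor_bias=bias,
        )
        ds.participant_id = f"sim{i:03d}"
        out.append((ds, params))
    return out


def _sample_params(spec: SyntheticCohortSpec, rng: np.random.Generator) -> UtilityParams:
    def draw(lo_hi):
        lo, hi = lo_hi
        return float(lo if lo == hi else rng.uniform(lo, hi))

    values = {
        "eta": draw(spec.eta_range),
        "gamma": draw(spec.gamma_range),
        "theta": draw(spec.theta_range),
        "alpha": draw(spec.alpha_range),
        "delta": draw(spec.delta_range),
    }
    used = {n: values[n] for n in PARAM_NAMES[spec.generative_model]}
    return UtilityParams(model=spec.generative_model, **used).validate()
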