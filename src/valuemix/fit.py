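"""Maximum-likelihood fitting of softmax choice models.

The central objects follow the statsmodels convention: a
:class:`SoftmaxChoiceModel` is built from a participant's trial table and
``fit()`` returns a :class:`SoftmaxChoiceResults` carrying the estimates,
log-likelihood, per-start diagnostics and a ``summary()`` table.  Fitting
uses only the two-option trials, so the estimated integration style is
independent of any distractor effect; trials on which the distractor (or
nothing) was chosen are excluded beforehand.

The likelihood is Bernoulli over the per-trial choice indicator:
``LL = sum_t [pe log pm + (1 - pe) log(1 - pm)]`` with ``pe`` the empirical
choice of option 1 and ``pm`` its softmax probability.  Optimisation is
bounded L-BFGS-B from at least 10 random starting points (step/optimality
tolerances 1e-10, at most 5000 evaluations/iterations per start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import DISTRACTOR, MISSED, TWO_OPTION, ChoiceDataset
from .utility import MODEL_NAMES, PARAM_BOUNDS, PARAM_NAMES, UtilityParams, pair_utilities

__all__ = [
    "PROB_CLAMP",
    "trial_inclusion_filter",
    "negative_log_likelihood",
    "SoftmaxChoiceModel",
    "SoftmaxChoiceResults",
    "CVResult",
    "fit_mle",
    "fivefold_cv",
    "cross_fit_recovery",
]

#: model probabilities are clamped to [PROB_CLAMP, 1 - PROB_CLAMP] inside the
#: log: a saturated softmax (large theta * dU) would otherwise produce log(0).
PROB_CLAMP = 1e-9


def trial_inclusion_filter(dataset: ChoiceDataset) -> ChoiceDataset:
    """Drop trials on which the distractor or nothing was chosen.

    Returns a new dataset containing only trials where one of the two
    chooseable options was picked; removal counts are recorded in
    ``meta['n_excluded_distractor_choices']`` and ``meta['n_excluded_missed']``.
    """
    t = dataset.trials
    d_chosen = (t["chosen"] == 3).sum()
    missed = (t["chosen"] == MISSED).sum()
    keep = t["chosen"].isin((1, 2))
    meta = dict(dataset.meta)
    meta["n_excluded_distractor_choices"] = int(d_chosen)
    meta["n_excluded_missed"] = int(missed)
    return ChoiceDataset(
        participant_id=dataset.participant_id,
        trials=t[keep].reset_index(drop=True),
        meta=meta,
    )


def _two_option_arrays(dataset: ChoiceDataset) -> tuple[np.ndarray, ...]:
    t = dataset.trials
    t = t[(t["trial_type"] == TWO_OPTION) & t["chosen"].isin((1, 2))]
    if len(t) == 0:
        raise ValueError(f"no usable trials for participant {dataset.participant_id!r}")
    return (
        t["x1"].to_numpy(float),
        t["p1"].to_numpy(float),
        t["x2"].to_numpy(float),
        t["p2"].to_numpy(float),
        (t["chosen"].to_numpy(int) == 1).astype(float),
    )


def _nll_arrays(model: str, vector: np.ndarray, arrays) -> float:
    x1, p1, x2, p2, pe = arrays
    u1, u2, theta = pair_utilities(model, vector, x1, p1, x2, p2)
    z = np.clip(theta * (u1 - u2), -700, 700)
    pm1 = 1.0 / (1.0 + np.exp(-z))
    p_choice = np.where(pe > 0.5, pm1, 1.0 - pm1)
    p_choice = np.clip(p_choice, PROB_CLAMP, 1.0 - PROB_CLAMP)
    return float(-np.log(p_choice).sum())


def negative_log_likelihood(
    model: str, params: UtilityParams, dataset: ChoiceDataset
) -> float:
    """Negative Bernoulli log-likelihood of a model on two-option trials.

    ``pe`` is the per-trial binary indicator of the empirical choice; the
    model probability ``pm`` is the softmax over the two chooseable options'
    utilities.  Distractor-choice and missed trials must already be
    excluded; distractor trials never contribute.
    """
    params.validate()
    if params.model != model:
        raise ValueError(f"params are for model {params.model!r}, not {model!r}")
    return _nll_arrays(model, params.to_vector(), _two_option_arrays(dataset))


class SoftmaxChoiceModel:
    """Softmax choice model over a participant's two-option trials.

    Parameters
    ----------
    dataset : ChoiceDataset
        Trial table; only two-option trials with a valid choice enter the
        likelihood.  Distractor-choice / missed trials are filtered here.
    model : str
        One of ``EV, AU, EV+DN, COMP, PROSPECT``.
    """

    def __init__(self, dataset: ChoiceDataset, model: str = "COMP"):
        if model not in MODEL_NAMES:
            raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
        self.model = model
        self.dataset = trial_inclusion_filter(dataset)
        self.arrays = _two_option_arrays(self.dataset)
        self.nobs = len(self.arrays[0])
        self.param_names = PARAM_NAMES[model]
        self.bounds = [PARAM_BOUNDS[n] for n in self.param_names]

    @classmethod
    def from_dataframe(
        cls, trials: pd.DataFrame, model: str = "COMP", participant_id: str = "p0"
    ) -> "SoftmaxChoiceModel":
        return cls(ChoiceDataset(participant_id=participant_id, trials=trials), model=model)

    def nll(self, params) -> float:
        """Negative log-likelihood at ``params`` (UtilityParams or vector)."""
        if isinstance(params, UtilityParams):
            params.validate()
            vector = params.to_vector()
        else:
            vector = np.asarray(params, dtype=float)
        return _nll_arrays(self.model, vector, self.arrays)

    def _random_starts(self, n_starts: int, rng: np.random.Generator) -> np.ndarray:
        starts = np.empty((n_starts, len(self.param_names)))
        for j, name in enumerate(self.param_names):
            lo, hi = PARAM_BOUNDS[name]
            if name == "theta":
                # log-uniform starts on [0.1, 50] cover plausible sensitivities
                starts[:, j] = np.exp(rng.uniform(np.log(0.1), np.log(50.0), size=n_starts))
            else:
                starts[:, j] = rng.uniform(lo, hi, size=n_starts)
        return starts

    def fit(self, n_starts: int = 10, seed: int = 0) -> "SoftmaxChoiceResults":
        """Multi-start bounded MLE; returns the best solution across starts.

        Ties between starts (LL equal to 1e-12) keep the earliest start.
        Deterministic given ``seed``.
        """
        if n_starts < 10:
            raise ValueError("n_starts must be >= 10 to guard against local optima")
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
        starts = self._random_starts(n_starts, rng)
        records = []
        best = None
        for i, s in enumerate(starts):
            res = minimize(
                lambda v: _nll_arrays(self.model, v, self.arrays),
                s,
                method="L-BFGS-B",
                bounds=self.bounds,
                options={"maxfun": 5000, "maxiter": 5000, "ftol": 1e-10, "gtol": 1e-10},
            )
            records.append(
                {
                    "start": s.copy(),
                    "end": res.x.copy(),
                    "nll": float(res.fun),
                    "success": bool(res.success),
                }
            )
            if res.success and (best is None or res.fun < records[best]["nll"] - 1e-12):
                best = i
        if best is None:
            raise RuntimeError(
                f"all {n_starts} optimisation starts failed for model {self.model}"
            )
        params = UtilityParams.from_vector(self.model, records[best]["end"])
        return SoftmaxChoiceResults(
            model=self,
            params=params,
            nll=records[best]["nll"],
            n_starts=n_starts,
            converged=True,
            starts=records,
            seed=seed,
        )

    def cross_validate(
        self, n_folds: int = 5, n_starts: int = 10, seed: int = 0
    ) -> "CVResult":
        """K-fold cross-validation of the held-out log-likelihood.

        Trials are partitioned into ``n_folds`` random, near-equal folds
        (assignment depends only on the data size and seed); the model is
        refitted on the remaining folds and evaluated on each held-out fold
        once.  Returns per-fold held-out LLs plus their mean and sum.
        """
        n = self.nobs
        if n < n_folds:
            raise ValueError(f"need at least {n_folds} trials for {n_folds}-fold CV, have {n}")
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        arrays = self.arrays
        fold_ll = []
        assignments = np.empty(n, dtype=int)
        for k, hold in enumerate(folds):
            assignments[hold] = k
            train_idx = np.setdiff1d(perm, hold, assume_unique=False)
            train = tuple(a[train_idx] for a in arrays)
            test = tuple(a[hold] for a in arrays)
            sub = object.__new__(SoftmaxChoiceModel)
            sub.model = self.model
            sub.dataset = self.dataset
            sub.arrays = train
            sub.nobs = len(train[0])
            sub.param_names = self.param_names
            sub.bounds = self.bounds
            fit = sub.fit(n_starts=n_starts, seed=int(rng.integers(0, 2**31 - 1)))
            fold_ll.append(-_nll_arrays(self.model, fit.params.to_vector(), test))
        fold_ll = np.array(fold_ll)
        return CVResult(
            model_name=self.model,
            fold_assignments=assignments,
            fold_log_likelihoods=fold_ll,
            mean_log_likelihood=float(fold_ll.mean()),
            total_log_likelihood=float(fold_ll.sum()),
        )


@dataclass
class SoftmaxChoiceResults:
    """MLE output for one participant and one model."""

    model: SoftmaxChoiceModel
    params: UtilityParams
    nll: float
    n_starts: int
    converged: bool
    starts: list
    seed: int

    @property
    def llf(self) -> float:
        """Maximised log-likelihood (<= 0)."""
        return -self.nll

    @property
    def n_trials_used(self) -> int:
        return self.model.nobs

    def summary(self) -> str:
        lines = [
            f"Softmax choice model: {self.params.model}",
            f"participant: {self.model.dataset.participant_id}",
            f"trials used: {self.n_trials_used}   starts: {self.n_starts}",
            f"log-likelihood: {self.llf:.4f}",
            "-" * 38,
        ]
        for name in self.model.param_names:
            lines.append(f"{name:>8s}  {getattr(self.params, name):10.4f}")
        return "\n".join(lines)

    def simulate(self, design, distractor_choice_rate: float = 0.0, seed: int = 0):
        """Simulate choices on a design from the fitted parameters."""
        from .simulate import simulate_agent_choices

        return simulate_agent_choices(
            design, self.params, distractor_choice_rate=distractor_choice_rate, seed=seed
        )


@dataclass
class CVResult:
    """Cross-validated held-out log-likelihoods for one participant/model."""

    model_name: str
    fold_assignments: np.ndarray
    fold_log_likelihoods: np.ndarray
    mean_log_likelihood: float
    total_log_likelihood: float


def fit_mle(
    model: str, dataset: ChoiceDataset, n_starts: int = 10, seed: int = 0
) -> SoftmaxChoiceResults:
    """Functional wrapper: multi-start MLE of ``model`` on a dataset."""
    return SoftmaxChoiceModel(dataset, model=model).fit(n_starts=n_starts, seed=seed)


def fivefold_cv(
    model: str, dataset: ChoiceDataset, seed: int = 0, n_starts: int = 10
) -> CVResult:
    """Functional wrapper: fivefold cross-validation of ``model``."""
    return SoftmaxChoiceModel(dataset, model=model).cross_validate(
        n_folds=5, n_starts=n_starts, seed=seed
    )


def cross_fit_recovery(
    models: Sequence[str],
    cohort: Sequence[ChoiceDataset],
    seed: int = 0,
    n_starts: int = 10,
    use_cv: bool = True,
) -> pd.DataFrame:
    """Simulate-and-cross-fit model recovery confusion matrix.

    For every dataset and every generating model: fit the model, simulate
    behaviour from its best-fitting parameters on the same trial schedule,
    refit all candidate models to the simulation, and record which model
    wins (highest cross-validated held-out LL, or full-data LL when
    ``use_cv`` is False).  Returns a K x K count matrix, rows = generating
    model, columns = winning model.
    """
    models = list(models)
    if len(models) < 1:
        raise ValueError("need at least one model")
    from .simulate import simulate_agent_choices

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    confusion = pd.DataFrame(0, index=models, columns=models, dtype=int)
    for ds in cohort:
        from .simulate import TaskDesign

        design = TaskDesign(
            trials=ds.trials.drop(columns=["chosen"]).reset_index(drop=True),
            design_id=ds.participant_id,
        )
        for gen in models:
            fit = fit_mle(gen, ds, n_starts=n_starts, seed=int(rng.integers(0, 2**31 - 1)))
            sim = simulate_agent_choices(
                design, fit.params, seed=int(rng.integers(0, 2**31 - 1))
            )
            scores = {}
            for cand in models:
                s = int(rng.integers(0, 2**31 - 1))
                if use_cv:
                    scores[cand] = fivefold_cv(
                        cand, sim, seed=s, n_starts=n_starts
                    ).total_log_likelihood
                else:
                    scores[cand] = fit_mle(cand, sim, n_starts=n_starts, seed=s).llf
            winner = max(models, key=lambda m: scores[m])
            confusion.loc[gen, winner] += 1
    return confusion
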