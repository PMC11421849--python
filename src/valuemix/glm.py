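"""Distractor-effect logistic regressions with matched control trials.

Relative choice accuracy (choosing the higher-value chooseable option HV
over the lower-value one LV) is regressed on z-scored value terms.  On each
trial type separately (GLM1):

    logit(accuracy) = b0 + b1 z(HV-LV) + b2 z(DV-HV) + b3 z(HV-LV)z(DV-HV)

and on both trial types jointly (GLM2), adding a trial-type indicator T
(0 = two-option control, 1 = distractor trial) and the T-products of every
base term.  Because the distractor is absent on control trials, each control
condition inherits a *hypothetical* distractor from the distractor trials
that share its (HV, LV) attribute condition; conditions matched by several
control trials enter once with the occurrence count as observation weight
(binomial response: HV-choices out of count).

Variants: ``glm2_sum`` adds a z(HV+LV) term; ``glm2_sumT_dv`` additionally
adds its T-product and replaces DV-HV by DV to limit collinearity;
``glm2_composite`` defines all values with the composite utility model
instead of expected value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import DISTRACTOR, TWO_OPTION, ChoiceDataset
from .fit import trial_inclusion_filter
from .utility import UtilityParams

__all__ = [
    "GLM_VARIANTS",
    "RoleAssignment",
    "MatchTable",
    "GLMDesign",
    "GLMResult",
    "assign_option_roles",
    "match_trials",
    "build_glm_design",
    "fit_weighted_logistic",
    "participant_glm",
]

GLM_VARIANTS = (
    "glm1_distractor",
    "glm1_two_option",
    "glm2",
    "glm2_sum",
    "glm2_sumT_dv",
    "glm2_composite",
)

_KEY_DECIMALS = 10  # attribute values are grid levels; rounding kills float fuzz


@dataclass
class RoleAssignment:
    """Per-trial HV/LV/DV labels and accuracy under a value rule.

    ``table`` columns: trial_type, hv_x, hv_p, lv_x, lv_p, dv_x, dv_p
    (NaN on two-option rows), hv, lv, dv (values; dv NaN on two-option
    rows), accuracy (1 = HV chosen), included (H or L chosen).
    """

    table: pd.DataFrame
    value_rule: str
    n_ties: int = 0


def _values(rule: str, params: Optional[UtilityParams], x: np.ndarray, p: np.ndarray):
    if rule == "EV":
        return x * p
    if rule == "COMP":
        if params is None:
            raise ValueError("COMP value rule requires fitted composite parameters")
        params.validate()
        eta, gamma = params.eta, params.gamma
        return eta * x * p + (1.0 - eta) * (gamma * x + (1.0 - gamma) * p)
    raise ValueError(f"unknown value rule {rule!r}; expected 'EV' or 'COMP'")


def assign_option_roles(
    dataset: ChoiceDataset,
    value_rule: str = "EV",
    params: Optional[UtilityParams] = None,
) -> RoleAssignment:
    """Label each trial's chooseable options as HV/LV and the third as DV.

    Accuracy is 1 iff the HV option was chosen.  Value ties between the two
    chooseable options are broken by listed option order (first option is
    HV) and counted in ``n_ties``.
    """
    t = dataset.trials
    x1, p1 = t["x1"].to_numpy(float), t["p1"].to_numpy(float)
    x2, p2 = t["x2"].to_numpy(float), t["p2"].to_numpy(float)
    x3, p3 = t["x3"].to_numpy(float), t["p3"].to_numpy(float)
    v1 = _values(value_rule, params, x1, p1)
    v2 = _values(value_rule, params, x2, p2)
    is_distractor = (t["trial_type"] == DISTRACTOR).to_numpy()
    with np.errstate(invalid="ignore"):
        v3 = np.where(is_distractor, _values(value_rule, params, x3, p3), np.nan)
    first_is_hv = v1 >= v2
    n_ties = int((v1 == v2).sum())
    hv_x = np.where(first_is_hv, x1, x2)
    hv_p = np.where(first_is_hv, p1, p2)
    lv_x = np.where(first_is_hv, x2, x1)
    lv_p = np.where(first_is_hv, p2, p1)
    hv = np.where(first_is_hv, v1, v2)
    lv = np.where(first_is_hv, v2, v1)
    chosen = t["chosen"].to_numpy(int)
    hv_index = np.where(first_is_hv, 1, 2)
    included = (chosen == 1) | (chosen == 2)
    accuracy = (chosen == hv_index).astype(float)
    table = pd.DataFrame(
        {
            "trial_type": t["trial_type"].to_numpy(),
            "hv_x": hv_x,
            "hv_p": hv_p,
            "lv_x": lv_x,
            "lv_p": lv_p,
            "dv_x": np.where(is_distractor, x3, np.nan),
            "dv_p": np.where(is_distractor, p3, np.nan),
            "hv": hv,
            "lv": lv,
            "dv": v3,
            "accuracy": accuracy,
            "included": included,
        }
    )
    return RoleAssignment(table=table, value_rule=value_rule, n_ties=n_ties)


@dataclass
class MatchTable:
    """Distractor-to-control matching on the (HV, LV) attribute condition.

    ``distractor_map`` maps each included distractor-trial row index to its
    condition key; ``controls`` has one row per unique matched two-option
    condition: hv/lv attributes and values, the hypothetical dv inherited
    from the (first) matched distractor trial, successes (HV choices among
    matched control trials) and weight (their count).
    """

    distractor_map: dict
    controls: pd.DataFrame
    n_unmatched_distractor: int
    n_unmatched_two_option: int


def _condition_key(row) -> tuple:
    return tuple(np.round([row.hv_x, row.hv_p, row.lv_x, row.lv_p], _KEY_DECIMALS))


def match_trials(roles: RoleAssignment) -> MatchTable:
    """Match every distractor trial to control trials sharing its (HV, LV).

    Matching is exact on the (X, P) pairs of HV and LV.  Distractor trials
    with no matching control condition are dropped and counted; if *no*
    distractor trial matches, the designs do not correspond and an error is
    raised.  Only included trials (H or L chosen) contribute.
    """
    t = roles.table[roles.table["included"]]
    two = t[t["trial_type"] == TWO_OPTION]
    dis = t[t["trial_type"] == DISTRACTOR]
    groups: dict[tuple, list] = {}
    for row in two.itertuples():
        groups.setdefault(_condition_key(row), []).append(row.Index)
    distractor_map = {}
    control_rows: dict[tuple, dict] = {}
    n_unmatched = 0
    for row in dis.itertuples():
        key = _condition_key(row)
        if key not in groups:
            n_unmatched += 1
            continue
        distractor_map[row.Index] = key
        if key not in control_rows:
            matched = two.loc[groups[key]]
            control_rows[key] = {
                "hv_x": row.hv_x,
                "hv_p": row.hv_p,
                "lv_x": row.lv_x,
                "lv_p": row.lv_p,
                "hv": row.hv,
                "lv": row.lv,
                "dv": row.dv,
                "dv_x": row.dv_x,
                "dv_p": row.dv_p,
                "successes": float(matched["accuracy"].sum()),
                "weight": int(len(matched)),
            }
    if dis.shape[0] > 0 and not distractor_map:
        raise ValueError("designs do not correspond: no distractor trial has a matched control")
    matched_keys = set(control_rows)
    n_unmatched_two = int(
        sum(len(v) for k, v in groups.items() if k not in matched_keys)
    )
    controls = pd.DataFrame(list(control_rows.values()))
    return MatchTable(
        distractor_map=distractor_map,
        controls=controls,
        n_unmatched_distractor=n_unmatched,
        n_unmatched_two_option=n_unmatched_two,
    )


@dataclass
class GLMDesign:
    """Weighted logistic design: named columns, binomial response, weights."""

    exog: pd.DataFrame
    successes: np.ndarray
    trials: np.ndarray
    variant: str
    meta: dict = field(default_factory=dict)


def _weighted_z(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    mean = np.average(x, weights=w)
    var = np.sum(w * (x - mean) ** 2) / (w.sum() - 1.0)
    if var <= 0:
        raise ValueError("degenerate regressor: zero variance")
    return (x - mean) / np.sqrt(var)


def build_glm_design(
    roles: RoleAssignment,
    matches: Optional[MatchTable],
    variant: str = "glm2",
    control_rows: str = "aggregated",
) -> GLMDesign:
    """Construct the design matrix for one GLM variant.

    Base value terms are z-scored (weighted, sample denominator) over the
    rows entering this fit; interaction and T-product columns are formed
    from the z-scored terms and not re-standardised.  ``control_rows``:
    ``aggregated`` (default) enters each unique matched control condition
    once with its occurrence count as weight; ``per_trial`` enters matched
    control trials individually (sensitivity variant).
    """
    if variant not in GLM_VARIANTS:
        raise ValueError(f"unknown GLM variant {variant!r}")
    needs_matches = variant != "glm1_distractor"
    if needs_matches and matches is None:
        raise ValueError(f"variant {variant} requires a MatchTable (hypothetical DV)")

    t = roles.table[roles.table["included"]]
    dis = t[t["trial_type"] == DISTRACTOR]
    if matches is not None:
        dis = dis.loc[[i for i in dis.index if i in matches.distractor_map]]

    blocks = []
    if variant != "glm1_two_option":
        blocks.append(
            pd.DataFrame(
                {
                    "hv": dis["hv"].to_numpy(),
                    "lv": dis["lv"].to_numpy(),
                    "dv": dis["dv"].to_numpy(),
                    "successes": dis["accuracy"].to_numpy(),
                    "weight": 1.0,
                    "T": 1.0,
                }
            )
        )
    if variant != "glm1_distractor":
        c = matches.controls
        if len(c) == 0:
            raise ValueError("no matched control conditions")
        if control_rows == "aggregated":
            blocks.append(
                pd.DataFrame(
                    {
                        "hv": c["hv"].to_numpy(),
                        "lv": c["lv"].to_numpy(),
                        "dv": c["dv"].to_numpy(),
                        "successes": c["successes"].to_numpy(),
                        "weight": c["weight"].to_numpy(float),
                        "T": 0.0,
                    }
                )
            )
        elif control_rows == "per_trial":
            two = t[t["trial_type"] == TWO_OPTION]
            key_to_dv = {
                _condition_key(r): r.dv for r in c.itertuples()
            }
            rows = []
            for r in two.itertuples():
                key = _condition_key(r)
                if key in key_to_dv:
                    rows.append((r.hv, r.lv, key_to_dv[key], r.accuracy, 1.0, 0.0))
            blocks.append(
                pd.DataFrame(
                    rows, columns=["hv", "lv", "dv", "successes", "weight", "T"]
                )
            )
        else:
            raise ValueError(f"unknown control_rows mode {control_rows!r}")

    rows = pd.concat(blocks, ignore_index=True)
    if variant in ("glm1_distractor", "glm1_two_option"):
        rows["T"] = 0.0  # single trial type; no T block

    w = rows["weight"].to_numpy(float)
    hv = rows["hv"].to_numpy(float)
    lv = rows["lv"].to_numpy(float)
    dv = rows["dv"].to_numpy(float)
    T = rows["T"].to_numpy(float)

    z = {}
    z["z(HV-LV)"] = _weighted_z(hv - lv, w)
    if variant == "glm2_sumT_dv":
        z["z(DV)"] = _weighted_z(dv, w)
        dv_term = "z(DV)"
    else:
        z["z(DV-HV)"] = _weighted_z(dv - hv, w)
        dv_term = "z(DV-HV)"
    if variant in ("glm2_sum", "glm2_sumT_dv"):
        z["z(HV+LV)"] = _weighted_z(hv + lv, w)

    cols = {"const": np.ones(len(rows))}
    cols["z(HV-LV)"] = z["z(HV-LV)"]
    cols[dv_term] = z[dv_term]
    inter = f"z(HV-LV){dv_term}"
    cols[inter] = z["z(HV-LV)"] * z[dv_term]
    if variant in ("glm2_sum", "glm2_sumT_dv"):
        cols["z(HV+LV)"] = z["z(HV+LV)"]
    if variant.startswith("glm2"):
        cols["T"] = T
        cols["z(HV-LV)T"] = z["z(HV-LV)"] * T
        cols[f"{dv_term}T"] = z[dv_term] * T
        cols[f"{inter}T"] = cols[inter] * T
        if variant == "glm2_sumT_dv":
            cols["z(HV+LV)T"] = z["z(HV+LV)"] * T

    exog = pd.DataFrame(cols)
    if len(exog) <= len(exog.columns):
        raise ValueError(
            f"too few rows ({len(exog)}) for {len(exog.columns)} design columns"
        )
    return GLMDesign(
        exog=exog,
        successes=rows["successes"].to_numpy(float),
        trials=w,
        variant=variant,
        meta={
            "n_rows": len(rows),
            "n_distractor_rows": int((T == 1).sum()),
            "n_control_rows": int((T == 0).sum()) if variant != "glm1_distractor" else 0,
        },
    )


@dataclass
class GLMResult:
    """Fitted weighted logistic regression: one row per design column."""

    table: pd.DataFrame  # term, beta, se, t, p
    deviance: float
    n_rows: int
    separated: bool
    converged: bool
    variant: str
    meta: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in variant {self.variant}")
        return float(row["beta"].iloc[0])

    def summary(self) -> str:
        lines = [
            f"Weighted logistic GLM ({self.variant}); rows={self.n_rows}, "
            f"deviance={self.deviance:.3f}"
            + ("  [SEPARATION]" if self.separated else ""),
            f"{'term':>22s} {'beta':>9s} {'se':>8s} {'t':>8s} {'p':>10s}",
        ]
        for r in self.table.itertuples():
            lines.append(
                f"{r.term:>22s} {r.beta:9.4f} {r.se:8.4f} {r.t:8.3f} {r.p:10.3g}"
            )
        return "\n".join(lines)


def fit_weighted_logistic(design: GLMDesign) -> GLMResult:
    """Maximum-likelihood logistic fit of a GLMDesign.

    Observation weights are realised as binomial denominators (successes
    out of ``trials`` per row).  Perfect separation is flagged rather than
    raised; coefficients of a separated fit are reported but marked
    non-converged.
    """
    endog = np.column_stack([design.successes, design.trials - design.successes])
    if np.any(endog < 0):
        raise ValueError("successes exceed trials in some row")
    separated = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(endog, design.exog, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200)
        except Exception:  # fitting itself blew up: treat as separation
            separated = True
            res = model.fit_regularized(alpha=1e-6, maxiter=200)
        for warn in caught:
            if "separation" in str(warn.message).lower() or "converge" in str(
                warn.message
            ).lower():
                separated = True
    params = np.asarray(res.params, dtype=float)
    if hasattr(res, "bse"):
        se = np.asarray(res.bse, dtype=float)
        tvals = np.asarray(res.tvalues, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
        deviance = float(res.deviance)
    else:  # regularized fallback carries no covariance
        se = np.full_like(params, np.nan)
        tvals = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
        deviance = np.nan
    if np.any(np.abs(params) > 15) or np.any(~np.isfinite(se)):
        separated = True
    if separated:
        converged = False
    table = pd.DataFrame(
        {
            "term": list(design.exog.columns),
            "beta": params,
            "se": se,
            "t": tvals,
            "p": pvals,
        }
    )
    return GLMResult(
        table=table,
        deviance=deviance,
        n_rows=len(design.exog),
        separated=separated,
        converged=converged,
        variant=design.variant,
        meta=dict(design.meta),
    )


def participant_glm(
    dataset: ChoiceDataset,
    variant: str = "glm2",
    value_rule: str = "EV",
    params: Optional[UtilityParams] = None,
    control_rows: str = "aggregated",
) -> GLMResult:
    """Full per-participant pipeline: filter, roles, matching, design, fit."""
    if variant == "glm2_composite":
        value_rule = "COMP"
    filtered = trial_inclusion_filter(dataset)
    roles = assign_option_roles(filtered, value_rule=value_rule, params=params)
    matches = None
    if variant != "glm1_distractor":
        matches = match_trials(roles)
    design = build_glm_design(roles, matches, variant=variant, control_rows=control_rows)
    result = fit_weighted_logistic(design)
    result.meta.update(
        {
            "participant_id": dataset.participant_id,
            "n_excluded_distractor_choices": filtered.meta.get(
                "n_excluded_distractor_choices", 0
            ),
            "n_excluded_missed": filtered.meta.get("n_excluded_missed", 0),
            "n_ties": roles.n_ties,
            "n_unmatched_distractor": matches.n_unmatched_distractor if matches else 0,
        }
    )
    return result
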