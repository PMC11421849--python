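"""Random-effects Bayesian model selection across participants.

Given a participants x models matrix of log model evidences, the
random-effects scheme treats the model identity of each participant as
drawn from a population multinomial with Dirichlet-distributed frequencies.
A variational loop alternates between per-participant posterior model
probabilities and the Dirichlet concentration update until convergence:

    u_nk  proportional to  exp(ln E_nk + psi(alpha_k) - psi(sum alpha))
    alpha_k = alpha0 + sum_n u_nk

Exceedance probability (EP) is the posterior probability that model k is
the most frequent in the population, estimated by Monte-Carlo sampling of
the Dirichlet posterior.  The Bayes omnibus risk (BOR) is the posterior
probability that all models are equally frequent, from the free-energy
comparison of the null equal-frequency model against the fitted one;
protected EP shrinks EP toward uniform by the BOR:
``pxp = ep * (1 - bor) + bor / K``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "BMSResult",
    "rfx_bms",
    "exceedance_probability",
    "protected_exceedance_probability",
    "bayes_omnibus_risk",
]


@dataclass
class BMSResult:
    """Cohort-level model-selection output."""

    models: list
    alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    protected_exceedance_probability: np.ndarray
    bayes_omnibus_risk: float
    participant_posteriors: np.ndarray
    prior_alpha: float
    n_iterations: int

    def summary(self) -> str:
        lines = [
            f"Random-effects BMS over {self.participant_posteriors.shape[0]} participants",
            f"Bayes omnibus risk: {self.bayes_omnibus_risk:.4f}",
            f"{'model':>10s} {'alpha':>8s} {'freq':>7s} {'EP':>7s} {'pxp':>7s}",
        ]
        for i, m in enumerate(self.models):
            lines.append(
                f"{m:>10s} {self.alpha[i]:8.3f} {self.expected_frequency[i]:7.3f} "
                f"{self.exceedance_probability[i]:7.3f} "
                f"{self.protected_exceedance_probability[i]:7.3f}"
            )
        return "\n".join(lines)


def _vb_dirichlet(L: np.ndarray, prior_alpha: float, tol: float, max_iter: int):
    n, k = L.shape
    alpha = np.full(k, prior_alpha, dtype=float)
    u = np.full((n, k), 1.0 / k)
    for it in range(1, max_iter + 1):
        ln_u = L + digamma(alpha) - digamma(alpha.sum())
        ln_u = ln_u - logsumexp(ln_u, axis=1, keepdims=True)
        u = np.exp(ln_u)
        alpha_new = prior_alpha + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u, it


def rfx_bms(
    log_evidence: np.ndarray,
    prior_alpha: float = 1.0,
    models=None,
    n_samples: int = 1_000_000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BMSResult:
    """Random-effects BMS on a participants x models log-evidence matrix."""
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[0] < 1 or L.shape[1] < 2:
        raise ValueError("log_evidence must be a participants x models matrix with >= 2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("log_evidence contains non-finite values")
    if prior_alpha <= 0:
        raise ValueError("prior_alpha must be positive")
    k = L.shape[1]
    if models is None:
        models = [f"M{i + 1}" for i in range(k)]
    alpha, u, n_iter = _vb_dirichlet(L, prior_alpha, tol, max_iter)
    ep = exceedance_probability(alpha, n_samples=n_samples, seed=seed)
    bor = _bor_from_parts(L, alpha, u, prior_alpha)
    pxp = protected_exceedance_probability(ep, bor)
    return BMSResult(
        models=list(models),
        alpha=alpha,
        expected_frequency=alpha / alpha.sum(),
        exceedance_probability=ep,
        protected_exceedance_probability=pxp,
        bayes_omnibus_risk=bor,
        participant_posteriors=u,
        prior_alpha=prior_alpha,
        n_iterations=n_iter,
    )


def exceedance_probability(
    alpha: np.ndarray, n_samples: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo P(r_k > r_j for all j != k) under Dirichlet(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(6,)))
    counts = np.zeros(len(alpha), dtype=np.int64)
    # sample in blocks to bound memory at large n_samples
    block = 200_000
    remaining = int(n_samples)
    while remaining > 0:
        m = min(block, remaining)
        samples = rng.dirichlet(alpha, size=m)
        winners = np.argmax(samples, axis=1)
        counts += np.bincount(winners, minlength=len(alpha))
        remaining -= m
    return counts / float(n_samples)


def protected_exceedance_probability(ep: np.ndarray, bor: float) -> np.ndarray:
    """pxp = ep * (1 - bor) + bor / K."""
    ep = np.asarray(ep, dtype=float)
    if not (0.0 <= bor <= 1.0):
        raise ValueError(f"Bayes omnibus risk {bor} outside [0, 1]")
    if abs(ep.sum() - 1.0) > 1e-6:
        raise ValueError("exceedance probabilities must sum to 1")
    k = len(ep)
    return ep * (1.0 - bor) + bor / k


def bayes_omnibus_risk(log_evidence: np.ndarray, bms: BMSResult) -> float:
    """Posterior probability that all model frequencies are equal.

    Free-energy comparison of the null (equal frequencies) model,
    ``F0 = sum_n [logsumexp(L_n) - ln K]``, against the fitted Dirichlet
    model's variational free energy F1; ``bor = 1 / (1 + exp(F1 - F0))``.
    """
    L = np.asarray(log_evidence, dtype=float)
    return _bor_from_parts(L, bms.alpha, bms.participant_posteriors, bms.prior_alpha)


def _bor_from_parts(
    L: np.ndarray, alpha: np.ndarray, u: np.ndarray, prior_alpha: float
) -> float:
    n, k = L.shape
    f0 = float(np.sum(logsumexp(L, axis=1) - np.log(k)))
    psi = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_u = -np.where(u > 0, u * np.log(u), 0.0).sum()
    e_joint = float(np.sum(u * (L + psi[None, :])))
    alpha0 = np.full(k, prior_alpha)
    # KL-related Dirichlet terms of the variational free energy
    dir_terms = (
        gammaln(alpha0.sum())
        - gammaln(alpha0).sum()
        - gammaln(alpha.sum())
        + gammaln(alpha).sum()
        + float(np.sum((alpha0 - alpha) * psi))
    )
    f1 = e_joint + ent_u + dir_terms
    # logistic of the free-energy difference, computed stably
    d = f1 - f0
    if d > 700:
        return 0.0
    if d < -700:
        return 1.0
    return float(1.0 / (1.0 + np.exp(d)))
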