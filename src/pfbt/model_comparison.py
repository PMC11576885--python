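"""Fixed- and random-effects comparison of model variants across participants.

Fixed effects sums per-participant log evidences and reports pairwise Bayes
factors.  Random effects treats the model identity as a random variable per
participant with unknown population frequencies ``r ~ Dirichlet(alpha0)``,
estimated by the variational scheme of Stephan et al. (2009).  Exceedance
probabilities (the probability that a model's frequency is the largest) are
computed by Monte Carlo over the posterior Dirichlet, and protected
exceedance probabilities (Rigoux et al. 2014) discount them by the Bayes
omnibus risk (BOR) — the posterior probability that all models are equally
frequent — via ``PXP = EP * (1 - BOR) + BOR / K``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp


@dataclass(frozen=True)
class ComparisonResult:
    model_names: tuple[str, ...]
    summed_log_evidence: np.ndarray
    log_bayes_factors: np.ndarray          # [i, j] = summed logE_i - summed logE_j
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    bayes_omnibus_risk: float
    protected_exceedance_probabilities: np.ndarray
    best_model_counts: np.ndarray
    dirichlet_alpha: np.ndarray


def _validate_evidence(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.ndim != 2:
        raise ValueError("evidence matrix must be 2-D (participants x models)")
    if E.shape[1] < 2:
        raise ValueError("model comparison requires at least 2 models")
    if not np.all(np.isfinite(E)):
        raise ValueError("evidence matrix must be finite")
    return E


def fixed_effects_compare(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Summed log evidences per model and the pairwise log Bayes factor matrix."""
    E = _validate_evidence(E)
    sums = E.sum(axis=0)
    log_bf = sums[:, None] - sums[None, :]
    return sums, log_bf


def random_effects_bms(
    E: np.ndarray,
    alpha0: np.ndarray | None = None,
    n_mc: int = 1_000_000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Random-effects Bayesian model selection.

    Returns ``(expected_frequencies, exceedance_probabilities, BOR,
    protected_exceedance_probabilities, dirichlet_alpha)``.
    """
    E = _validate_evidence(E)
    n, K = E.shape
    alpha0 = np.ones(K) if alpha0 is None else np.asarray(alpha0, dtype=float)

    alpha = alpha0.copy()
    for it in range(max_iter):
        log_u = E + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError(
            f"variational iteration did not converge in {max_iter} steps; "
            f"final alpha = {alpha}"
        )

    r = alpha / alpha.sum()
    ep = _exceedance_mc(alpha, n_mc=n_mc, seed=seed)
    bor = _bayes_omnibus_risk(E, alpha0, alpha, g)
    pxp = ep * (1.0 - bor) + bor / K
    return r, ep, bor, pxp, alpha


def _exceedance_mc(alpha: np.ndarray, n_mc: int, seed: int) -> np.ndarray:
    """Exceedance probabilities by Monte Carlo over Dirichlet(alpha)."""
    rng = np.random.default_rng(seed)
    K = len(alpha)
    counts = np.zeros(K)
    chunk = 200_000
    remaining = n_mc
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.gamma(shape=alpha, size=(m, K))
        counts += np.bincount(np.argmax(draws, axis=1), minlength=K)
        remaining -= m
    return counts / n_mc


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL( Dir(alpha) || Dir(alpha0) )."""
    asum, a0sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(asum) - gammaln(alpha).sum()
        - gammaln(a0sum) + gammaln(alpha0).sum()
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(asum)))
    )


def _bayes_omnibus_risk(
    E: np.ndarray, alpha0: np.ndarray, alpha: np.ndarray, g: np.ndarray
) -> float:
    """Posterior probability that model frequencies are all equal.

    Compares the free energy of the random-frequencies model (from the
    converged variational posterior) against the exact log evidence of the
    null in which every model is equally frequent.
    """
    n, K = E.shape
    # F1: variational free energy of the alternative
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_g = -np.nansum(g * np.where(g > 0, np.log(g), 0.0))
    f1 = (
        float(np.sum(g * (E + e_log_r)))
        + ent_g
        - _dirichlet_kl(alpha, alpha0)
    )
    # F0: exact under uniform frequencies r_k = 1/K
    f0 = float(np.sum(logsumexp(E - np.log(K), axis=1)))
    return float(1.0 / (1.0 + np.exp(f1 - f0)))


def best_model_frequency(
    E: np.ndarray, n_params: np.ndarray | None = None
) -> np.ndarray:
    """Count how often each model has the highest evidence across participants.

    Ties are broken toward the model with fewer free parameters (the
    simpler, nested variant) and logged.
    """
    E = _validate_evidence(E) if np.asarray(E).shape[1] >= 2 else np.asarray(E, float)
    n, K = E.shape
    if n_params is None:
        n_params = np.arange(K)  # fall back to column order as complexity order
    n_params = np.asarray(n_params)
    counts = np.zeros(K, dtype=int)
    for row in E:
        best = np.flatnonzero(row == row.max())
        if len(best) > 1:
            import logging
            best = best[np.argsort(n_params[best], kind="stable")]
            logging.getLogger(__name__).info(
                "evidence tie between models %s; assigned to simplest", list(best)
            )
        counts[best[0]] += 1
    return counts


def compare_models(
    E: np.ndarray,
    model_names: tuple[str, ...] | None = None,
    n_params: np.ndarray | None = None,
    alpha0: np.ndarray | None = None,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> ComparisonResult:
    """Full fixed- plus random-effects comparison of an evidence matrix."""
    E = _validate_evidence(E)
    K = E.shape[1]
    names = model_names or tuple(f"model_{k}" for k in range(K))
    sums, log_bf = fixed_effects_compare(E)
    r, ep, bor, pxp, alpha = random_effects_bms(E, alpha0=alpha0, n_mc=n_mc, seed=seed)
    counts = best_model_frequency(E, n_params=n_params)
    return ComparisonResult(
        model_names=tuple(names),
        summed_log_evidence=sums,
        log_bayes_factors=log_bf,
        expected_frequencies=r,
        exceedance_probabilities=ep,
        bayes_omnibus_risk=bor,
        protected_exceedance_probabilities=pxp,
        best_model_counts=counts,
        dirichlet_alpha=alpha,
    )
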