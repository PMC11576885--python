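"""MAP fitting of the dual-agent learner to probe responses.

The likelihood of a probability report is a Beta density whose mode equals
the probed agent's model-derived belief and whose variance is the
choice-noise parameter ``tau``.  Parameters are mapped to the real line by
scaled logistic transforms and fitted in that unconstrained space under
independent Gaussian priors, by quasi-Newton maximisation of the log
posterior from multiple restarts.  Per-participant model evidence is the
Laplace approximation at the MAP (with a BIC fallback when the curvature
is not positive definite), which trades goodness of fit against model
complexity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, gammaln, logit

from .agent_model import (
    BELIEF_EPS,
    TAU_MAX,
    TAU_MIN,
    BeliefTrajectory,
    ModelParams,
    ModelSpec,
    ResponseSet,
    _simulate_kernel,
    sequence_arrays,
)
from .task_design import TaskSequence

logger = logging.getLogger(__name__)

RESPONSE_EPS = 1e-4           # reports of exactly 0/1 are clamped inward
MAX_BETA_VARIANCE = 1.0 / 12.0  # variance of the uniform limit (shapes a = b = 1)


class BetaInfeasibleError(ValueError):
    """No Beta distribution with shapes >= 1 has the requested mode and variance."""


# ---------------------------------------------------------------------------
# Beta(mode, variance) -> shape parameters
# ---------------------------------------------------------------------------

def _beta_variance(mode: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Variance of Beta with given mode and concentration s = a + b (s > 2)."""
    a = 1.0 + mode * (s - 2.0)
    b = 1.0 + (1.0 - mode) * (s - 2.0)
    return a * b / ((a + b) ** 2 * (a + b + 1.0))


def beta_shapes_from_mode_variance(
    mode: float | np.ndarray, variance: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve for Beta shapes (a, b) with the given mode and variance.

    Parameterised by concentration ``s = a + b`` with ``a = 1 + mode (s-2)``,
    under which the mode constraint holds by construction and the variance
    is strictly decreasing in ``s`` from 1/12 at the uniform limit ``s = 2``.
    A unique solution with a, b >= 1 therefore exists iff
    ``0 < variance < 1/12``; it is found by vectorised bisection to ~1e-12.
    """
    mode = np.atleast_1d(np.asarray(mode, dtype=float))
    variance = np.broadcast_to(np.asarray(variance, dtype=float), mode.shape).copy()
    if np.any((mode < BELIEF_EPS - 1e-12) | (mode > 1.0 - BELIEF_EPS + 1e-12)):
        raise ValueError("mode must be interior (within [eps, 1 - eps])")
    if np.any(variance <= 0.0) or np.any(variance >= MAX_BETA_VARIANCE):
        bad_v = variance[(variance <= 0.0) | (variance >= MAX_BETA_VARIANCE)][0]
        bad_m = mode[(variance <= 0.0) | (variance >= MAX_BETA_VARIANCE)][0]
        raise BetaInfeasibleError(
            f"no interior Beta solution with shapes >= 1 for "
            f"(mode={bad_m:.6g}, variance={bad_v:.6g}); variance must be in (0, 1/12)"
        )

    lo = np.full(mode.shape, 2.0 + 1e-12)
    hi = np.full(mode.shape, 4.0)
    # grow the upper bracket until the variance there is below the target
    for _ in range(64):
        over = _beta_variance(mode, hi) > variance
        if not over.any():
            break
        hi[over] *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_wide = _beta_variance(mode, mid) > variance  # variance too big -> s too small
        lo = np.where(too_wide, mid, lo)
        hi = np.where(too_wide, hi, mid)
    s = 0.5 * (lo + hi)
    a = 1.0 + mode * (s - 2.0)
    b = 1.0 + (1.0 - mode) * (s - 2.0)
    return a, b


def _beta_logpdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (
        (a - 1.0) * np.log(x)
        + (b - 1.0) * np.log1p(-x)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
    )


def beta_mode_loglik(responses: np.ndarray, modes: np.ndarray, tau: float) -> float:
    """Sum of log Beta densities with per-probe modes and common variance tau.

    Infeasible variances (>= 1/12, cannot occur for tau <= 0.08) are shrunk
    to the feasible maximum and logged, keeping the likelihood defined.
    """
    if len(responses) == 0:
        return 0.0
    v = float(tau)
    if v >= MAX_BETA_VARIANCE:
        logger.warning(
            "variance %.4g infeasible for a modal Beta; shrunk to %.4g",
            v, MAX_BETA_VARIANCE - 1e-9,
        )
        v = MAX_BETA_VARIANCE - 1e-9
    x = np.clip(np.asarray(responses, dtype=float), RESPONSE_EPS, 1.0 - RESPONSE_EPS)
    m = np.clip(np.asarray(modes, dtype=float), BELIEF_EPS, 1.0 - BELIEF_EPS)
    a, b = beta_shapes_from_mode_variance(m, v)
    return float(np.sum(_beta_logpdf(x, a, b)))


def response_loglik(
    responses: ResponseSet,
    trajectory: BeliefTrajectory,
    params: ModelParams,
    seq: TaskSequence,
) -> float:
    """Log likelihood of probe responses given a belief trajectory."""
    if len(responses) != seq.n_probes:
        raise ValueError(
            f"responses ({len(responses)}) not aligned to probes ({seq.n_probes})"
        )
    modes = trajectory.beliefs_at_probes(seq)
    return beta_mode_loglik(responses.response, modes, params.tau)


# ---------------------------------------------------------------------------
# Parameter transforms and priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamTransform:
    """Strictly monotone scaled-logistic map from the real line onto (lo, hi)."""

    name: str
    lo: float
    hi: float

    def forward(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.lo + (self.hi - self.lo) * expit(x)

    def inverse(self, y: float | np.ndarray) -> float | np.ndarray:
        return logit((np.asarray(y, dtype=float) - self.lo) / (self.hi - self.lo))


TRANSFORMS: dict[str, ParamTransform] = {
    "alpha": ParamTransform("alpha", 0.0, 1.0),
    "alpha_other": ParamTransform("alpha_other", 0.0, 1.0),
    "delta": ParamTransform("delta", 0.0, 1.0),
    "tau": ParamTransform("tau", TAU_MIN, TAU_MAX),
    "lambda_self": ParamTransform("lambda_self", -1.0, 1.0),
    "lambda_other": ParamTransform("lambda_other", -1.0, 1.0),
    "lambda_sym": ParamTransform("lambda_sym", -1.0, 1.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors over unconstrained parameters.

    The default N(0, 1) on every transformed parameter centres alpha and
    delta at 0.5, tau at mid-range, and both leakage weights at 0
    (agent-specific updating).
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.sds.values()):
            raise ValueError("prior SDs must be positive")

    def mean(self, name: str) -> float:
        return self.means.get(name, 0.0)

    def sd(self, name: str) -> float:
        return self.sds.get(name, 1.0)

    def logpdf(self, names: Sequence[str], x: np.ndarray) -> float:
        mu = np.array([self.mean(n) for n in names])
        sd = np.array([self.sd(n) for n in names])
        z = (x - mu) / sd
        return float(np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * np.log(2 * np.pi)))


def params_from_unconstrained(x: np.ndarray, spec: ModelSpec) -> ModelParams:
    """Map an unconstrained vector to natural-scale parameters under a spec."""
    names = spec.free_parameter_names
    nat = {n: float(TRANSFORMS[n].forward(xi)) for n, xi in zip(names, x)}
    lam_s = lam_o = 0.0
    if spec.leakage_pattern == "unrestricted":
        lam_s, lam_o = nat["lambda_self"], nat["lambda_other"]
    elif spec.leakage_pattern == "symmetric":
        lam_s = lam_o = nat["lambda_sym"]
    return ModelParams(
        alpha=nat["alpha"],
        delta=nat["delta"],
        tau=nat["tau"],
        lambda_self=lam_s,
        lambda_other=lam_o,
        alpha_other=nat.get("alpha_other"),
    )


def unconstrained_from_params(params: ModelParams, spec: ModelSpec) -> np.ndarray:
    """Inverse of :func:`params_from_unconstrained` (exact for conforming params)."""
    params = spec.constrain(params)
    vals = {
        "alpha": params.alpha,
        "alpha_other": params.effective_alpha_other,
        "delta": params.delta,
        "tau": params.tau,
        "lambda_self": params.lambda_self,
        "lambda_other": params.lambda_other,
        "lambda_sym": params.lambda_self,
    }
    return np.array(
        [float(TRANSFORMS[n].inverse(vals[n])) for n in spec.free_parameter_names]
    )


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    n_restarts: int = 10
    tol: float = 1e-6
    seed: int = 0
    max_iter: int = 500
    grad_norm_warn: float = 1e-2


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    map_params: ModelParams
    map_unconstrained: np.ndarray
    log_posterior: float
    log_likelihood: float
    log_evidence: float
    hessian_logdet: float
    n_restarts_used: int
    converged: bool
    used_bic_fallback: bool
    n_probes: int

    @property
    def n_free_params(self) -> int:
        return self.spec.n_free_params


def _make_neg_log_posterior(
    seq: TaskSequence, responses: ResponseSet, spec: ModelSpec, prior: PriorSpec
) -> Callable[[np.ndarray], float]:
    outcomes, codes = sequence_arrays(seq)
    pos = seq.probe_positions()
    is_self = seq.probe_agents() == "self"
    resp = np.clip(responses.response, RESPONSE_EPS, 1.0 - RESPONSE_EPS)
    names = spec.free_parameter_names

    def neg_log_post(x: np.ndarray) -> float:
        params = params_from_unconstrained(x, spec)
        if len(resp):
            bs, bo, _, _ = _simulate_kernel(
                outcomes, codes,
                params.alpha_self, params.effective_alpha_other,
                params.delta, params.lambda_self, params.lambda_other,
                0.5, 0.5,
            )
            modes = np.where(is_self, bs[pos], bo[pos])
            ll = beta_mode_loglik(resp, modes, params.tau)
        else:
            ll = 0.0
        lp = prior.logpdf(names, x)
        return -(ll + lp)

    return neg_log_post


def fit_map(
    seq: TaskSequence,
    responses: ResponseSet,
    spec: ModelSpec | None = None,
    prior: PriorSpec | None = None,
    opts: FitOptions | None = None,
) -> FitResult:
    """Fit one model variant to one participant's responses by MAP.

    Runs quasi-Newton (L-BFGS-B, numerical gradients) optimisation of the
    log posterior in unconstrained space from the prior mean plus
    ``n_restarts - 1`` random prior draws, and keeps the best optimum.
    Deterministic given ``opts.seed``.
    """
    spec = spec or ModelSpec()
    prior = prior or PriorSpec()
    opts = opts or FitOptions()
    if len(responses) != seq.n_probes:
        raise ValueError("responses not aligned to the sequence's probes")

    names = spec.free_parameter_names
    neg_log_post = _make_neg_log_posterior(seq, responses, spec, prior)
    rng = np.random.default_rng(opts.seed)
    mu = np.array([prior.mean(n) for n in names])
    sd = np.array([prior.sd(n) for n in names])

    starts = [mu]
    for _ in range(max(opts.n_restarts - 1, 0)):
        starts.append(rng.normal(mu, sd))

    best = None
    n_ok = 0
    failures = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                neg_log_post, x0, method="L-BFGS-B",
                options={"maxiter": opts.max_iter, "ftol": opts.tol, "gtol": opts.tol},
            )
        except (FloatingPointError, ValueError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective at optimum")
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {len(starts)} restarts failed: {failures[:3]}")

    x_map = np.asarray(best.x, dtype=float)
    grad_norm = float(np.max(np.abs(np.atleast_1d(best.jac))))
    converged = bool(best.success) and grad_norm < opts.grad_norm_warn
    log_post = -float(best.fun)
    map_params = params_from_unconstrained(x_map, spec)
    log_prior = prior.logpdf(names, x_map)
    log_lik = log_post - log_prior

    hess = _numerical_hessian(neg_log_post, x_map)
    log_ev, logdet, used_bic = _evidence_from_curvature(
        log_post, log_lik, hess, n_obs=max(len(responses), 1)
    )

    return FitResult(
        spec=spec,
        map_params=map_params,
        map_unconstrained=x_map,
        log_posterior=log_post,
        log_likelihood=log_lik,
        log_evidence=log_ev,
        hessian_logdet=logdet,
        n_restarts_used=n_ok,
        converged=converged,
        used_bic_fallback=used_bic,
        n_probes=len(responses),
    )


def _numerical_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    d = len(x)
    H = np.empty((d, d))
    h = step * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            fpp = f(x + ei + ej); fpm = f(x + ei - ej)
            fmp = f(x - ei + ej); fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def laplace_log_evidence(
    log_posterior_at_map: float, curvature: np.ndarray
) -> float:
    """Laplace approximation to the log marginal likelihood.

    ``curvature`` is the Hessian of the *negative* log posterior at the MAP
    (positive definite at a proper maximum).  Exact when prior and
    likelihood are Gaussian in the fitted coordinates.
    """
    curvature = np.atleast_2d(curvature)
    d = curvature.shape[0]
    sign, logdet = np.linalg.slogdet(curvature)
    if sign <= 0:
        raise np.linalg.LinAlgError("curvature is not positive definite")
    return log_posterior_at_map + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet


def _evidence_from_curvature(
    log_post: float, log_lik: float, hess: np.ndarray, n_obs: int
) -> tuple[float, float, bool]:
    d = hess.shape[0]
    try:
        # positive definiteness via Cholesky; slogdet alone can pass indefinite H
        np.linalg.cholesky(hess)
        log_ev = laplace_log_evidence(log_post, hess)
        _, logdet = np.linalg.slogdet(hess)
        return float(log_ev), float(logdet), False
    except np.linalg.LinAlgError:
        logger.warning(
            "curvature not positive definite; falling back to BIC-based evidence"
        )
        log_ev = log_lik - 0.5 * d * np.log(n_obs)
        return float(log_ev), float("nan"), True


def log_model_evidence(fit: FitResult, dim: int | None = None) -> float:
    """Per-participant log model evidence recorded on a fit."""
    if dim is not None and dim != fit.n_free_params:
        raise ValueError(
            f"dim {dim} does not match the fitted model's {fit.n_free_params} parameters"
        )
    return fit.log_evidence


__all__ = [
    "BetaInfeasibleError",
    "FitOptions",
    "FitResult",
    "ParamTransform",
    "PriorSpec",
    "TRANSFORMS",
    "beta_mode_loglik",
    "beta_shapes_from_mode_variance",
    "fit_map",
    "laplace_log_evidence",
    "log_model_evidence",
    "params_from_unconstrained",
    "response_loglik",
    "unconstrained_from_params",
]
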