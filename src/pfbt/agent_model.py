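"""Dual-agent belief updating with leakage, and response simulation.

The learner maintains two beliefs about the probability of the next binary
outcome: ``B_Self`` (its own belief) and ``B_Other`` (its representation of
the other agent's belief).  Both follow an error-driven update with memory
decay toward chance level::

    B_Self  <- B_Self  + a_Self  * (PE_Self  + lambda_Other * PE_Other) + delta * (0.5 - B_Self)
    B_Other <- B_Other + a_Other * (PE_Other + lambda_Self  * PE_Self)  + delta * (0.5 - B_Other)

Prediction errors are agent-specific: ``PE_Self = outcome - B_Self`` except
on decoy trials (where Self knows the outcome is fake, so ``PE_Self = 0``),
and ``PE_Other = outcome - B_Other`` except on privileged trials (where the
other agent does not see the outcome, so ``PE_Other = 0``).  The leakage
parameters ``lambda_Self`` (idiocentric: own surprise generalised to the
other) and ``lambda_Other`` (allocentric: the other's surprise adopted as
one's own) live in [-1, 1]; at zero, updating is fully agent-specific.

Probe responses are simulated from a Beta distribution whose mode is the
probed agent's current belief and whose variance is the choice-noise
parameter ``tau``; at the upper bound tau = 0.08 the Beta is near-uniform
(random responding).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .task_design import SamplingTrial, TaskSequence

TAU_MIN = 0.001
TAU_MAX = 0.08
BELIEF_EPS = 1e-4  # Beta modes must be interior; beliefs are clamped into [eps, 1-eps]
INITIAL_BELIEF = 0.5

LEAKAGE_PATTERNS = ("unrestricted", "symmetric", "zero")
LEARNING_RATE_PATTERNS = ("shared", "per_agent")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the dual-agent learner.

    ``alpha`` is the Self learning rate; ``alpha_other`` defaults to it
    (shared learning rates).  ``delta`` is memory decay toward 0.5, ``tau``
    the Beta response variance, ``lambda_self``/``lambda_other`` the
    idiocentric/allocentric leakage weights.
    """

    alpha: float
    delta: float
    tau: float
    lambda_self: float
    lambda_other: float
    alpha_other: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha out of [0, 1]: {self.alpha}")
        if self.alpha_other is not None and not 0.0 <= self.alpha_other <= 1.0:
            raise ValueError(f"alpha_other out of [0, 1]: {self.alpha_other}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta out of [0, 1]: {self.delta}")
        if not TAU_MIN <= self.tau <= TAU_MAX:
            raise ValueError(f"tau out of [{TAU_MIN}, {TAU_MAX}]: {self.tau}")
        for name in ("lambda_self", "lambda_other"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [-1, 1]: {v}")

    @property
    def alpha_self(self) -> float:
        return self.alpha

    @property
    def effective_alpha_other(self) -> float:
        return self.alpha if self.alpha_other is None else self.alpha_other


@dataclass(frozen=True)
class ModelSpec:
    """One of the six model variants: leakage pattern x learning-rate pattern."""

    leakage_pattern: Literal["unrestricted", "symmetric", "zero"] = "unrestricted"
    learning_rate_pattern: Literal["shared", "per_agent"] = "shared"

    def __post_init__(self) -> None:
        if self.leakage_pattern not in LEAKAGE_PATTERNS:
            raise ValueError(f"unknown leakage_pattern {self.leakage_pattern!r}")
        if self.learning_rate_pattern not in LEARNING_RATE_PATTERNS:
            raise ValueError(
                f"unknown learning_rate_pattern {self.learning_rate_pattern!r}"
            )

    @property
    def name(self) -> str:
        return f"{self.leakage_pattern}-{self.learning_rate_pattern}"

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        names = ["alpha"]
        if self.learning_rate_pattern == "per_agent":
            names.append("alpha_other")
        names += ["delta", "tau"]
        if self.leakage_pattern == "unrestricted":
            names += ["lambda_self", "lambda_other"]
        elif self.leakage_pattern == "symmetric":
            names.append("lambda_sym")
        return tuple(names)

    @property
    def n_free_params(self) -> int:
        return len(self.free_parameter_names)

    def constrain(self, params: ModelParams) -> ModelParams:
        """Apply the variant's constraint pattern to a parameter set."""
        p = params
        if self.leakage_pattern == "zero":
            p = replace(p, lambda_self=0.0, lambda_other=0.0)
        elif self.leakage_pattern == "symmetric":
            lam = p.lambda_self
            p = replace(p, lambda_other=lam)
        if self.learning_rate_pattern == "shared":
            p = replace(p, alpha_other=None)
        return p


MODEL_SET: tuple[ModelSpec, ...] = tuple(
    ModelSpec(lp, ap) for lp in LEAKAGE_PATTERNS for ap in LEARNING_RATE_PATTERNS
)


@dataclass(frozen=True)
class BeliefState:
    b_self: float
    b_other: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.b_self <= 1.0 and 0.0 <= self.b_other <= 1.0):
            raise ValueError("beliefs must be in [0, 1]")


@dataclass(frozen=True)
class BeliefUpdateRecord:
    trial_index: int
    pe_self: float
    pe_other: float
    state_after: BeliefState


@dataclass(frozen=True)
class BeliefTrajectory:
    """Per-trial beliefs and prediction errors along one task sequence.

    Arrays are aligned to sampling trials: ``b_self[i]`` is the Self belief
    *after* the update on sampling trial ``i + 1``.
    """

    b_self: np.ndarray
    b_other: np.ndarray
    pe_self: np.ndarray
    pe_other: np.ndarray
    initial_state: BeliefState

    def __len__(self) -> int:
        return len(self.b_self)

    def records(self) -> Iterator[BeliefUpdateRecord]:
        for i in range(len(self)):
            yield BeliefUpdateRecord(
                trial_index=i + 1,
                pe_self=float(self.pe_self[i]),
                pe_other=float(self.pe_other[i]),
                state_after=BeliefState(float(self.b_self[i]), float(self.b_other[i])),
            )

    def beliefs_at_probes(self, seq: TaskSequence) -> np.ndarray:
        """The probed agent's belief at each probe of ``seq``."""
        pos = seq.probe_positions()
        agents = seq.probe_agents()
        out = np.where(agents == "self", self.b_self[pos], self.b_other[pos])
        return out.astype(float)


def prediction_errors(state: BeliefState, trial: SamplingTrial) -> tuple[float, float]:
    """Agent-specific prediction errors, zeroed for the unobserving agent."""
    pe_self = 0.0 if trial.trial_type == "decoy" else trial.outcome - state.b_self
    pe_other = 0.0 if trial.trial_type == "privileged" else trial.outcome - state.b_other
    return pe_self, pe_other


def update_beliefs(
    state: BeliefState,
    trial: SamplingTrial,
    params: ModelParams,
    spec: ModelSpec | None = None,
) -> BeliefUpdateRecord:
    """One belief update; decay applies on every trial, beliefs clipped to [0, 1]."""
    if spec is not None:
        params = spec.constrain(params)
    pe_s, pe_o = prediction_errors(state, trial)
    a_s = params.alpha_self
    a_o = params.effective_alpha_other
    b_s = state.b_self + a_s * (pe_s + params.lambda_other * pe_o) + params.delta * (
        0.5 - state.b_self
    )
    b_o = state.b_other + a_o * (pe_o + params.lambda_self * pe_s) + params.delta * (
        0.5 - state.b_other
    )
    b_s = min(max(b_s, 0.0), 1.0)
    b_o = min(max(b_o, 0.0), 1.0)
    return BeliefUpdateRecord(
        trial_index=trial.index,
        pe_self=pe_s,
        pe_other=pe_o,
        state_after=BeliefState(b_s, b_o),
    )


# trial-type integer codes for the fast kernel
_TYPE_CODE = {"shared": 0, "privileged": 1, "decoy": 2}


def _simulate_kernel(
    outcomes: list[float],
    type_codes: list[int],
    a_s: float,
    a_o: float,
    delta: float,
    lam_s: float,
    lam_o: float,
    b_s: float,
    b_o: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sequential belief recursion on plain floats (hot path for fitting)."""
    n = len(outcomes)
    bs = np.empty(n)
    bo = np.empty(n)
    pes = np.empty(n)
    peo = np.empty(n)
    for i in range(n):
        o = outcomes[i]
        c = type_codes[i]
        pe_s = 0.0 if c == 2 else o - b_s
        pe_o = 0.0 if c == 1 else o - b_o
        b_s = b_s + a_s * (pe_s + lam_o * pe_o) + delta * (0.5 - b_s)
        b_o = b_o + a_o * (pe_o + lam_s * pe_s) + delta * (0.5 - b_o)
        if b_s < 0.0:
            b_s = 0.0
        elif b_s > 1.0:
            b_s = 1.0
        if b_o < 0.0:
            b_o = 0.0
        elif b_o > 1.0:
            b_o = 1.0
        bs[i] = b_s
        bo[i] = b_o
        pes[i] = pe_s
        peo[i] = pe_o
    return bs, bo, pes, peo


def sequence_arrays(seq: TaskSequence) -> tuple[list[float], list[int]]:
    """Outcome and trial-type-code lists for the simulation kernel."""
    outcomes = [float(t.outcome) for t in seq.sampling_trials]
    codes = [_TYPE_CODE[t.trial_type] for t in seq.sampling_trials]
    return outcomes, codes


def simulate_trajectory(
    seq: TaskSequence,
    params: ModelParams,
    spec: ModelSpec | None = None,
    initial_state: BeliefState | None = None,
) -> BeliefTrajectory:
    """Run the belief recursion over a full task sequence (deterministic)."""
    if seq.n_sampling == 0:
        raise ValueError("empty task sequence")
    if spec is not None:
        params = spec.constrain(params)
    state0 = initial_state or BeliefState(INITIAL_BELIEF, INITIAL_BELIEF)
    outcomes, codes = sequence_arrays(seq)
    bs, bo, pes, peo = _simulate_kernel(
        outcomes,
        codes,
        params.alpha_self,
        params.effective_alpha_other,
        params.delta,
        params.lambda_self,
        params.lambda_other,
        state0.b_self,
        state0.b_other,
    )
    return BeliefTrajectory(bs, bo, pes, peo, state0)


@dataclass(frozen=True)
class ResponseSet:
    """Probability reports at probe trials, aligned to a sequence's probes."""

    probe_index: np.ndarray   # 1-based interleaved-stream indices
    probe_agent: np.ndarray   # "self" / "other"
    response: np.ndarray      # reports in [0, 1]

    def __post_init__(self) -> None:
        if not (len(self.probe_index) == len(self.probe_agent) == len(self.response)):
            raise ValueError("response columns must have equal length")
        resp = np.asarray(self.response, dtype=float)
        if len(resp) and (resp.min() < 0.0 or resp.max() > 1.0):
            raise ValueError("responses must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.response)


def simulate_responses(
    traj: BeliefTrajectory,
    seq: TaskSequence,
    params: ModelParams,
    seed: int | np.random.Generator | None = None,
) -> ResponseSet:
    """Draw probe responses: Beta with mode = probed agent's belief, variance = tau."""
    from .inference import beta_shapes_from_mode_variance  # deferred: inference builds on this module

    if not TAU_MIN <= params.tau <= TAU_MAX:
        raise ValueError(f"tau out of [{TAU_MIN}, {TAU_MAX}]: {params.tau}")
    if len(traj) != seq.n_sampling:
        raise ValueError("trajectory is not aligned to the sequence")
    rng = np.random.default_rng(seed)
    modes = np.clip(traj.beliefs_at_probes(seq), BELIEF_EPS, 1.0 - BELIEF_EPS)
    a, b = beta_shapes_from_mode_variance(modes, params.tau)
    responses = rng.beta(a, b)
    return ResponseSet(
        probe_index=np.array([p.index for p in seq.probe_trials]),
        probe_agent=seq.probe_agents(),
        response=responses,
    )


def write_responses(responses: ResponseSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "probe_index": responses.probe_index,
            "probe_agent": responses.probe_agent,
            "response": responses.response,
        }
    ).to_csv(path, index=False)


def read_responses(path: str | Path) -> ResponseSet:
    df = pd.read_csv(path)
    missing = [c for c in ("probe_index", "probe_agent", "response") if c not in df.columns]
    if missing:
        raise ValueError(f"missing response columns: {missing}")
    return ResponseSet(
        probe_index=df["probe_index"].to_numpy(),
        probe_agent=df["probe_agent"].astype(str).to_numpy(),
        response=df["response"].to_numpy(dtype=float),
    )
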