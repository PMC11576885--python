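"""Trial-sequence generation for the probabilistic false-belief task (p-FBT).

The task presents a stream of binary outcomes (e.g. umbrella = 1 vs
sunshade = 0) whose underlying Bernoulli probability follows a bounded
random walk.  Two latent walks run in parallel: ``P_Self`` governs what the
participant can learn about, ``P_Other`` governs what a hypothetical other
agent can learn about.  Three sampling-trial types control who "sees" each
outcome:

* ``shared``     — outcome visible to both agents (drawn from either walk,
  the choice recorded);
* ``privileged`` — outcome drawn from ``P_Self``, hidden from the other;
* ``decoy``      — outcome drawn from ``P_Other``, misleading for the
  other agent only.

Every 4–9 sampling trials a probe is interleaved asking for a probability
report, either from the participant's own perspective (``self`` probe) or
from the other agent's perspective (``other`` probe).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

TRIAL_TYPES = ("shared", "privileged", "decoy")
PROBE_AGENTS = ("self", "other")

PROBE_GAP_MIN = 4
PROBE_GAP_MAX = 9
N_SAMPLING_TRIALS = 360
WALK_STEP = 0.025


class SequenceValidationError(ValueError):
    """A serialized task sequence violates the schema or an invariant."""


@dataclass(frozen=True)
class RandomWalkConfig:
    """Bounded random walk for a latent Bernoulli probability.

    Each step moves the probability by ``step_size`` (up or down with equal
    probability for the ``binary`` mechanism, or by a Gaussian increment of
    SD ``step_size`` for ``gaussian``), reflecting at the bounds.
    """

    n_steps: int = N_SAMPLING_TRIALS
    step_size: float = WALK_STEP
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    start_value: float = 0.5
    mechanism: Literal["binary", "gaussian"] = "binary"

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be below upper_bound")
        if not self.lower_bound <= self.start_value <= self.upper_bound:
            raise ValueError("start_value must lie within the bounds")
        if self.mechanism not in ("binary", "gaussian"):
            raise ValueError(f"unknown step mechanism {self.mechanism!r}")


@dataclass(frozen=True)
class SamplingTrial:
    """One outcome-presentation trial; indices are 1-based."""

    index: int
    trial_type: str
    outcome: int
    p_self: float
    p_other: float
    walk_used: str  # which walk the outcome was drawn from: "self"|"other"

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")
        if not (0.0 <= self.p_self <= 1.0 and 0.0 <= self.p_other <= 1.0):
            raise ValueError("latent probabilities must be in [0, 1]")


@dataclass(frozen=True)
class ProbeTrial:
    """A probability-report probe, interleaved into the sampling stream."""

    index: int                 # 1-based position in the interleaved stream
    after_sampling_index: int  # sampling trial immediately preceding
    probe_agent: str           # "self" or "other"

    def __post_init__(self) -> None:
        if self.probe_agent not in PROBE_AGENTS:
            raise ValueError(f"unknown probe_agent {self.probe_agent!r}")


@dataclass(frozen=True)
class TaskConfig:
    """Full generation configuration for one task sequence.

    Trial-type proportions are (shared, privileged, decoy).  The default
    keeps shared trials sparse: a shared outcome is a common input to both
    agents' learning, and with any substantial shared fraction the Self and
    Other belief trajectories become correlated even under fully
    agent-specific updating (zero leakage), defeating the task's central
    design property that leakage alone couples the two trajectories.  With
    each belief carrying a cross-walk input weight b, the induced
    correlation is about 2ab/(a^2+b^2); at a 2% shared fraction it is
    indistinguishable from zero empirically.
    """

    n_sampling_trials: int = N_SAMPLING_TRIALS
    walk: RandomWalkConfig = field(default_factory=RandomWalkConfig)
    trial_type_proportions: tuple[float, float, float] = (0.02, 0.49, 0.49)
    probe_gap_range: tuple[int, int] = (PROBE_GAP_MIN, PROBE_GAP_MAX)
    probe_agent_scheme: Literal["random", "alternating"] = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.trial_type_proportions) - 1.0) > 1e-9:
            raise ValueError("trial_type_proportions must sum to 1")
        lo, hi = self.probe_gap_range
        if not (1 <= lo <= hi):
            raise ValueError("probe_gap_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class TaskSequence:
    """A complete pre-generated task: sampling trials plus probe schedule."""

    sampling_trials: tuple[SamplingTrial, ...]
    probe_trials: tuple[ProbeTrial, ...]
    config: TaskConfig | None = None

    @property
    def n_sampling(self) -> int:
        return len(self.sampling_trials)

    @property
    def n_probes(self) -> int:
        return len(self.probe_trials)

    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.sampling_trials], dtype=float)

    def trial_types(self) -> np.ndarray:
        return np.array([t.trial_type for t in self.sampling_trials])

    def probe_positions(self) -> np.ndarray:
        """0-based indices into the sampling stream after which each probe occurs."""
        return np.array(
            [p.after_sampling_index - 1 for p in self.probe_trials], dtype=int
        )

    def probe_agents(self) -> np.ndarray:
        return np.array([p.probe_agent for p in self.probe_trials])


def generate_random_walk(
    config: RandomWalkConfig, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Generate a bounded random walk of probabilities.

    Steps are ±``step_size`` with equal probability (or Gaussian with SD
    ``step_size``), reflected at the bounds so every value stays inside
    ``[lower_bound, upper_bound]`` and no increment exceeds ``step_size``
    in magnitude (for the binary mechanism).
    """
    rng = np.random.default_rng(rng)
    lo, hi = config.lower_bound, config.upper_bound
    if config.mechanism == "binary":
        steps = rng.choice([-config.step_size, config.step_size], size=config.n_steps)
    else:
        steps = rng.normal(0.0, config.step_size, size=config.n_steps)
    values = np.empty(config.n_steps)
    x = config.start_value
    for i, s in enumerate(steps):
        x = x + s
        # reflect at the bounds
        if x > hi:
            x = 2 * hi - x
        if x < lo:
            x = 2 * lo - x
        x = min(max(x, lo), hi)
        values[i] = x
    return values


def _probe_schedule(
    n_trials: int, gap_range: tuple[int, int], rng: np.random.Generator
) -> list[int]:
    """1-based sampling-trial indices after which probes occur."""
    lo, hi = gap_range
    positions: list[int] = []
    pos = 0
    while True:
        pos += int(rng.integers(lo, hi + 1))
        if pos > n_trials:
            break
        positions.append(pos)
    return positions


def generate_task_sequence(config: TaskConfig | None = None, seed: int | None = None) -> TaskSequence:
    """Generate a full p-FBT sequence: walks, outcomes, trial types, probes.

    Outcome provenance follows trial type: privileged outcomes are Bernoulli
    draws from the Self walk, decoy outcomes from the Other walk, and shared
    outcomes from a walk chosen by fair coin (recorded in ``walk_used``).
    Reproducible from the config seed; an explicit ``seed`` overrides it.
    """
    if config is None:
        config = TaskConfig()
    if seed is not None:
        config = TaskConfig(
            n_sampling_trials=config.n_sampling_trials,
            walk=config.walk,
            trial_type_proportions=config.trial_type_proportions,
            probe_gap_range=config.probe_gap_range,
            probe_agent_scheme=config.probe_agent_scheme,
            seed=seed,
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_sampling_trials

    walk_cfg = RandomWalkConfig(
        n_steps=n,
        step_size=config.walk.step_size,
        lower_bound=config.walk.lower_bound,
        upper_bound=config.walk.upper_bound,
        start_value=config.walk.start_value,
        mechanism=config.walk.mechanism,
    )
    p_self = generate_random_walk(walk_cfg, rng)
    p_other = generate_random_walk(walk_cfg, rng)

    # trial types: fixed counts per proportion, randomly interleaved
    counts = np.floor(np.asarray(config.trial_type_proportions) * n).astype(int)
    while counts.sum() < n:
        counts[int(rng.integers(0, 3))] += 1
    types = np.repeat(np.array(TRIAL_TYPES), counts)
    rng.shuffle(types)

    sampling: list[SamplingTrial] = []
    for i in range(n):
        tt = str(types[i])
        if tt == "privileged":
            walk_used = "self"
        elif tt == "decoy":
            walk_used = "other"
        else:
            walk_used = "self" if rng.random() < 0.5 else "other"
        p = p_self[i] if walk_used == "self" else p_other[i]
        outcome = int(rng.random() < p)
        sampling.append(
            SamplingTrial(
                index=i + 1,
                trial_type=tt,
                outcome=outcome,
                p_self=float(p_self[i]),
                p_other=float(p_other[i]),
                walk_used=walk_used,
            )
        )

    probe_after = _probe_schedule(n, config.probe_gap_range, rng)
    probes: list[ProbeTrial] = []
    for k, after in enumerate(probe_after):
        if config.probe_agent_scheme == "alternating":
            agent = PROBE_AGENTS[k % 2]
        else:
            agent = "self" if rng.random() < 0.5 else "other"
        probes.append(
            ProbeTrial(index=after + k + 1, after_sampling_index=after, probe_agent=agent)
        )

    return TaskSequence(
        sampling_trials=tuple(sampling), probe_trials=tuple(probes), config=config
    )


# ---------------------------------------------------------------------------
# Serialization: interleaved long CSV + JSON config sidecar
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "trial_index", "phase", "trial_type", "outcome",
    "probe_agent", "p_self", "p_other", "walk_used",
]


def sequence_to_frame(seq: TaskSequence) -> pd.DataFrame:
    """Interleaved long-format view: one row per sampling or probe event."""
    rows = []
    probes_after: dict[int, list[ProbeTrial]] = {}
    for p in seq.probe_trials:
        probes_after.setdefault(p.after_sampling_index, []).append(p)
    idx = 0
    for t in seq.sampling_trials:
        idx += 1
        rows.append(dict(
            trial_index=idx, phase="sampling", trial_type=t.trial_type,
            outcome=t.outcome, probe_agent="NA",
            p_self=t.p_self, p_other=t.p_other, walk_used=t.walk_used,
        ))
        for p in probes_after.get(t.index, []):
            idx += 1
            rows.append(dict(
                trial_index=idx, phase="probe", trial_type="NA",
                outcome="NA", probe_agent=p.probe_agent,
                p_self=t.p_self, p_other=t.p_other, walk_used="NA",
            ))
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_sequence(seq: TaskSequence, path: str | Path) -> None:
    """Write the sequence CSV and, if a config is attached, a JSON sidecar."""
    path = Path(path)
    sequence_to_frame(seq).to_csv(path, index=False)
    if seq.config is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(asdict(seq.config), indent=2))


def read_sequence(path: str | Path) -> TaskSequence:
    """Read a sequence CSV (and config sidecar if present), validating rows."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SequenceValidationError(f"missing columns: {missing}")

    sampling: list[SamplingTrial] = []
    probes: list[ProbeTrial] = []
    gap_since_probe = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        phase = row.phase
        if phase == "sampling":
            if row.trial_type not in TRIAL_TYPES:
                raise SequenceValidationError(
                    f"row {row_no}: unknown trial_type {row.trial_type!r}"
                )
            if row.outcome not in ("0", "1"):
                raise SequenceValidationError(
                    f"row {row_no}: outcome must be 0 or 1, got {row.outcome!r}"
                )
            sampling.append(SamplingTrial(
                index=len(sampling) + 1,
                trial_type=row.trial_type,
                outcome=int(row.outcome),
                p_self=float(row.p_self),
                p_other=float(row.p_other),
                walk_used=row.walk_used,
            ))
            gap_since_probe += 1
        elif phase == "probe":
            if row.probe_agent not in PROBE_AGENTS:
                raise SequenceValidationError(
                    f"row {row_no}: unknown probe_agent {row.probe_agent!r}"
                )
            if not sampling:
                raise SequenceValidationError(f"row {row_no}: probe before any sampling trial")
            probes.append(ProbeTrial(
                index=int(row.trial_index),
                after_sampling_index=len(sampling),
                probe_agent=row.probe_agent,
            ))
            gap_since_probe = 0
        else:
            raise SequenceValidationError(f"row {row_no}: unknown phase {phase!r}")

    warnings = validate_probe_gaps(probes)
    config = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        raw["walk"] = RandomWalkConfig(**raw["walk"])
        raw["trial_type_proportions"] = tuple(raw["trial_type_proportions"])
        raw["probe_gap_range"] = tuple(raw["probe_gap_range"])
        config = TaskConfig(**raw)
    seq = TaskSequence(tuple(sampling), tuple(probes), config)
    if warnings:
        import logging
        logging.getLogger(__name__).warning(
            "probe-gap invariant violations: %s", warnings
        )
    return seq


def validate_probe_gaps(
    probes: Sequence[ProbeTrial],
    gap_range: tuple[int, int] = (PROBE_GAP_MIN, PROBE_GAP_MAX),
) -> list[str]:
    """Flag probe gaps (in sampling trials) outside the design range."""
    lo, hi = gap_range
    flags = []
    prev = 0
    for p in probes:
        gap = p.after_sampling_index - prev
        if not lo <= gap <= hi:
            flags.append(f"probe after sampling trial {p.after_sampling_index}: gap {gap}")
        prev = p.after_sampling_index
    return flags
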