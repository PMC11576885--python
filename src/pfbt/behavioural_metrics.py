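"""Model-free outcome-belief correlation analyses.

Performance on the task is measured without any learning model: probe
responses are correlated with an exponential recency-weighted average ``O``
of the outcomes the probed agent could learn from (for Self: privileged +
shared outcomes; for Other: decoy + shared).  The recency average, rather
than the latent generating probability, is used as the tracking target so
that sampling error in the observed outcomes does not count against the
participant.  The pooled correlation is referenced against a null
distribution built from sets of uniform random responses on the same
sequence: a score of zero indicates chance-level responding, and a
participant is flagged above chance only when the raw correlation exceeds
the null's 95th percentile.

Cross-agent correlations expose leakage without a model: corr(O_Self,
reported B_Other) measures idiocentric updating, corr(O_Other, reported
B_Self) allocentric updating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .agent_model import ResponseSet
from .task_design import TaskSequence

logger = logging.getLogger(__name__)

DEFAULT_RECENCY_WEIGHT = 0.1
DEFAULT_INITIAL_O = 0.5


@dataclass(frozen=True)
class RecencyAverages:
    """Recency-weighted outcome averages sampled at probe times."""

    o_self: np.ndarray
    o_other: np.ndarray
    weight: float
    n_flagged_initial: int  # probes seen before any pertinent outcome


@dataclass(frozen=True)
class NullDistribution:
    mean: float
    sd: float
    p95: float
    n_sims: int
    samples: np.ndarray


@dataclass(frozen=True)
class MetricReport:
    performance_raw: float
    within_self: float
    within_other: float
    idiocentric: float      # corr(O_Self, reported B_Other) on other-probes
    allocentric: float      # corr(O_Other, reported B_Self) on self-probes
    performance_overall: float | None = None  # null-referenced score
    above_chance: bool | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    null_p95: float | None = None


def _pertinent_mask(seq: TaskSequence, agent: str) -> np.ndarray:
    types = seq.trial_types()
    if agent == "self":
        return (types == "privileged") | (types == "shared")
    if agent == "other":
        return (types == "decoy") | (types == "shared")
    raise ValueError(f"unknown agent {agent!r}")


def recency_weighted_outcomes(
    seq: TaskSequence,
    agent: str,
    weight: float = DEFAULT_RECENCY_WEIGHT,
    initial: float = DEFAULT_INITIAL_O,
) -> np.ndarray:
    """Exponential recency-weighted outcome average at each probe.

    ``O`` is updated as ``O <- O + weight * (outcome - O)`` over the stream
    of outcomes pertinent to ``agent``, and read out at every probe.  Probes
    occurring before any pertinent outcome carry the initial value (flagged
    in the log).
    """
    if not 0.0 < weight <= 1.0:
        raise ValueError("recency weight must be in (0, 1]")
    outcomes = seq.outcomes()
    pertinent = _pertinent_mask(seq, agent)
    pos = seq.probe_positions()

    o = initial
    o_after = np.empty(seq.n_sampling)
    seen = np.zeros(seq.n_sampling, dtype=bool)
    any_seen = False
    for i in range(seq.n_sampling):
        if pertinent[i]:
            o = o + weight * (outcomes[i] - o)
            any_seen = True
        o_after[i] = o
        seen[i] = any_seen
    n_flagged = int(np.sum(~seen[pos]))
    if n_flagged:
        logger.warning(
            "%d probe(s) occur before any %s-pertinent outcome; initial O used",
            n_flagged, agent,
        )
    return o_after[pos]


def compute_recency_averages(
    seq: TaskSequence,
    weight: float = DEFAULT_RECENCY_WEIGHT,
    initial: float = DEFAULT_INITIAL_O,
) -> RecencyAverages:
    o_s = recency_weighted_outcomes(seq, "self", weight, initial)
    o_o = recency_weighted_outcomes(seq, "other", weight, initial)
    return RecencyAverages(o_self=o_s, o_other=o_o, weight=weight, n_flagged_initial=0)


def _corr(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> float:
    """Pearson correlation; NaN (undefined) for short or zero-variance input."""
    if len(x) < min_n or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def pooled_performance(
    responses: np.ndarray, averages: RecencyAverages, is_self_probe: np.ndarray
) -> float:
    """One per-participant score: corr(response, probed agent's O), pooled."""
    o = np.where(is_self_probe, averages.o_self, averages.o_other)
    return _corr(np.asarray(responses, dtype=float), o)


def outcome_belief_correlations(
    responses: ResponseSet, averages: RecencyAverages, seq: TaskSequence
) -> MetricReport:
    """Raw within- and across-agent outcome-belief correlations."""
    if len(responses) != seq.n_probes:
        raise ValueError("responses not aligned to the sequence's probes")
    is_self = seq.probe_agents() == "self"
    r = np.asarray(responses.response, dtype=float)
    return MetricReport(
        performance_raw=pooled_performance(r, averages, is_self),
        within_self=_corr(averages.o_self[is_self], r[is_self]),
        within_other=_corr(averages.o_other[~is_self], r[~is_self]),
        idiocentric=_corr(averages.o_self[~is_self], r[~is_self]),
        allocentric=_corr(averages.o_other[is_self], r[is_self]),
    )


def null_distribution(
    seq: TaskSequence,
    n_sims: int = 1000,
    seed: int | np.random.Generator | None = None,
    weight: float = DEFAULT_RECENCY_WEIGHT,
) -> NullDistribution:
    """Null of the pooled performance score under uniform random responding."""
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    rng = np.random.default_rng(seed)
    averages = compute_recency_averages(seq, weight)
    is_self = seq.probe_agents() == "self"
    o = np.where(is_self, averages.o_self, averages.o_other)
    n_probes = seq.n_probes

    resp = rng.uniform(size=(n_sims, n_probes))
    oc = o - o.mean()
    rc = resp - resp.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(rc**2, axis=1) * np.sum(oc**2))
    samples = (rc @ oc) / denom
    return NullDistribution(
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)),
        p95=float(np.percentile(samples, 95)),
        n_sims=n_sims,
        samples=samples,
    )


def relative_performance(raw_statistic: float, null: NullDistribution) -> tuple[float, bool]:
    """Null-referenced score (raw minus null mean) and the above-chance flag.

    The flag is set only when the raw statistic strictly exceeds the null's
    95th percentile; a raw value at or below it counts as chance-level.
    """
    score = raw_statistic - null.mean
    above = bool(raw_statistic > null.p95)
    return score, above


def compute_metrics(
    seq: TaskSequence,
    responses: ResponseSet,
    weight: float = DEFAULT_RECENCY_WEIGHT,
    n_sims: int = 1000,
    seed: int | None = 0,
) -> MetricReport:
    """Full model-free report: raw correlations plus null-referenced score."""
    averages = compute_recency_averages(seq, weight)
    raw = outcome_belief_correlations(responses, averages, seq)
    null = null_distribution(seq, n_sims=n_sims, seed=seed, weight=weight)
    score, above = relative_performance(raw.performance_raw, null)
    return MetricReport(
        performance_raw=raw.performance_raw,
        within_self=raw.within_self,
        within_other=raw.within_other,
        idiocentric=raw.idiocentric,
        allocentric=raw.allocentric,
        performance_overall=score,
        above_chance=above,
        null_mean=null.mean,
        null_sd=null.sd,
        null_p95=null.p95,
    )
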