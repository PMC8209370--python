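"""Weighted multi-feature objective for candidate scoring.

The objective is the weighted sum of absolute feature errors against a
reference::

    score_MF  = sum_i |MF_sim_i  - MF_exp_i |  * w_MF
    score_LAT = sum_i |LAT_sim_i - LAT_exp_i|  * w_LAT
    score_BF  = sum_j |BF_sim_j  - BF_exp_j |  * w_BF * (std(BF_sim_j) + 1)
    total     = score_MF + score_LAT + score_BF

Frequencies are in Hz (weight 1), latencies in seconds (weight 1000), so a
1 Hz error in mean or burst frequency costs the same as a 1 ms latency lag.
The ``(std + 1)`` factor penalizes unstable bursting: a candidate whose
per-cycle burst frequencies fluctuate pays more for the same mean error.
``std`` is the population standard deviation across the analyzed cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSet

__all__ = [
    "FeatureWeights",
    "ReferenceFeatures",
    "ScoreBreakdown",
    "PENALTY_SCORE",
    "mean_frequency_score",
    "latency_score",
    "burst_score",
    "total_score",
]

#: Finite score assigned to diverged/invalid candidates.  Finite (rather
#: than inf) so the optimizer keeps a total ordering and results stay
#: serializable.
PENALTY_SCORE = 1e9


@dataclass(frozen=True)
class FeatureWeights:
    """Feature weights; defaults equalize 1 Hz errors and 1 ms latency lags."""

    mean_frequency: float = 1.0
    latency: float = 1000.0
    burst_frequency: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mean_frequency", "latency", "burst_frequency"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be >= 0")


@dataclass(frozen=True)
class ReferenceFeatures:
    """Target feature values, keyed by protocol id.

    ``mean_frequency`` (Hz) and ``latency`` (s) hold one target per step
    protocol; ``burst_frequency`` (Hz) one target per sinusoidal condition.
    ``provenance`` records whether the targets came from a synthetic ground
    truth or from a file.
    """

    mean_frequency: dict
    latency: dict
    burst_frequency: dict
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        for group_name in ("mean_frequency", "latency", "burst_frequency"):
            for key, value in getattr(self, group_name).items():
                if not np.isfinite(value):
                    raise ValueError(f"{group_name}[{key}] must be finite")
                if group_name != "latency" and value < 0:
                    raise ValueError(f"{group_name}[{key}] must be >= 0 Hz")


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-feature and total score of one candidate.

    ``total`` equals the exact float sum of the three components.
    ``burst_by_protocol`` decomposes the burst component per sinusoidal
    condition (useful for stacked-bar style reporting).
    """

    mean_frequency: float
    latency: float
    burst_frequency: float
    total: float
    penalty_applied: bool = False
    burst_by_protocol: dict = field(default_factory=dict)


def _check_keys(kind: str, sim_keys, ref_keys) -> None:
    sim_keys, ref_keys = set(sim_keys), set(ref_keys)
    if sim_keys != ref_keys:
        raise ValueError(
            f"{kind}: simulated and reference stimulus sets differ "
            f"(only simulated: {sorted(sim_keys - ref_keys)}, "
            f"only reference: {sorted(ref_keys - sim_keys)})"
        )


def mean_frequency_score(
    sim: FeatureSet, ref: ReferenceFeatures, weights: FeatureWeights = FeatureWeights()
) -> float:
    """Sum of absolute mean-frequency errors over step stimuli, weighted."""
    _check_keys("mean frequency", sim.mean_frequency, ref.mean_frequency)
    return float(
        sum(
            abs(sim.mean_frequency[k] - ref.mean_frequency[k]) * weights.mean_frequency
            for k in sorted(ref.mean_frequency)
        )
    )


def latency_score(
    sim: FeatureSet, ref: ReferenceFeatures, weights: FeatureWeights = FeatureWeights()
) -> float:
    """Sum of absolute first-spike-latency errors (s) over step stimuli, weighted."""
    _check_keys("latency", sim.latency, ref.latency)
    return float(
        sum(
            abs(sim.latency[k] - ref.latency[k]) * weights.latency
            for k in sorted(ref.latency)
        )
    )


def burst_score(
    sim: FeatureSet, ref: ReferenceFeatures, weights: FeatureWeights = FeatureWeights()
) -> float:
    """Weighted burst-frequency error with the burst-stability penalty."""
    _check_keys("burst frequency", sim.burst_mean, ref.burst_frequency)
    return float(
        sum(
            abs(sim.burst_mean[k] - ref.burst_frequency[k])
            * weights.burst_frequency
            * (sim.burst_std[k] + 1.0)
            for k in sorted(ref.burst_frequency)
        )
    )


def burst_score_by_protocol(
    sim: FeatureSet, ref: ReferenceFeatures, weights: FeatureWeights = FeatureWeights()
) -> dict:
    """Per-condition decomposition of :func:`burst_score`."""
    _check_keys("burst frequency", sim.burst_mean, ref.burst_frequency)
    return {
        k: abs(sim.burst_mean[k] - ref.burst_frequency[k])
        * weights.burst_frequency
        * (sim.burst_std[k] + 1.0)
        for k in sorted(ref.burst_frequency)
    }


def total_score(
    sim: FeatureSet, ref: ReferenceFeatures, weights: FeatureWeights = FeatureWeights()
) -> ScoreBreakdown:
    """Full weighted objective with its per-feature breakdown.

    Diverged/invalid feature sets receive the finite :data:`PENALTY_SCORE`
    (carried on the mean-frequency component so ``total`` stays the exact
    sum of components) instead of raising, so the optimizer always sees a
    totally ordered, finite objective.
    """
    if not sim.valid:
        return ScoreBreakdown(
            mean_frequency=PENALTY_SCORE,
            latency=0.0,
            burst_frequency=0.0,
            total=PENALTY_SCORE,
            penalty_applied=True,
        )
    s_mf = mean_frequency_score(sim, ref, weights)
    s_lat = latency_score(sim, ref, weights)
    per_burst = burst_score_by_protocol(sim, ref, weights)
    s_bf = float(sum(per_burst[k] for k in sorted(per_burst)))
    return ScoreBreakdown(
        mean_frequency=s_mf,
        latency=s_lat,
        burst_frequency=s_bf,
        total=s_mf + s_lat + s_bf,
        burst_by_protocol=per_burst,
    )
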