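"""Spike-train feature extraction.

Three behavioral features summarize a simulated granule-cell response:

* **mean frequency** — spike count divided by stimulation time under a
  current step (one point of the intensity-frequency curve);
* **first-spike latency** — delay from stimulus onset to the first spike;
* **burst frequency** — the inverse of the mean inter-spike interval within
  one cycle of sinusoidal stimulation, zero when a cycle holds one spike or
  none, averaged over consecutive cycles.  Enhanced burst frequency at
  theta-band stimulation frequencies is the signature of spiking resonance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .adex import (
    AdExParameters,
    SimulationConfig,
    StimulusProtocol,
    simulate,
)

__all__ = [
    "CycleWindow",
    "FeatureConfig",
    "FeatureSet",
    "mean_frequency",
    "first_spike_latency",
    "cycle_windows",
    "burst_frequency_cycle",
    "extract_feature_set",
    "feature_set_to_dict",
    "write_feature_set_csv",
]


@dataclass(frozen=True)
class CycleWindow:
    """One analysis window, [start_s, end_s), covering a stimulation cycle."""

    start_s: float
    end_s: float
    cycle_index: int

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("window start must precede its end")


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing choices for burst analysis.

    ``n_cycles`` consecutive stimulation cycles are analyzed (default 10).
    ``analysis_onset_s`` is where the first cycle window starts; ``None``
    means the stimulus onset.  ``phase_offset_deg`` shifts all windows by a
    fraction of the period, for users who prefer aligning windows to a
    particular phase of the sine rather than to its onset.
    """

    n_cycles: int = 10
    analysis_onset_s: Optional[float] = None
    phase_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def mean_frequency(spike_times: np.ndarray, window: tuple) -> float:
    """Spike count in ``window = (t0, t1)`` divided by the window length (Hz)."""
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError("window length must be > 0")
    spike_times = np.asarray(spike_times, dtype=float)
    count = int(np.count_nonzero((spike_times >= t0) & (spike_times < t1)))
    return count / (t1 - t0)


def first_spike_latency(
    spike_times: np.ndarray, onset_s: float, duration_s: float
) -> float:
    """Time from ``onset_s`` to the first subsequent spike (s).

    Candidates that never spike return ``duration_s`` as a penalty sentinel,
    which keeps the latency score finite and penalizes silence in proportion
    to the window they stayed silent for.
    """
    if onset_s < 0:
        raise ValueError("onset must be >= 0")
    spike_times = np.asarray(spike_times, dtype=float)
    after = spike_times[spike_times >= onset_s]
    if after.size == 0:
        return float(duration_s)
    return float(after[0] - onset_s)


def cycle_windows(
    protocol: StimulusProtocol,
    n_cycles: int,
    analysis_onset_s: Optional[float] = None,
    phase_offset_deg: float = 0.0,
) -> list[CycleWindow]:
    """``n_cycles`` abutting windows of one stimulation period each.

    Windows start at ``analysis_onset_s`` (default: the stimulus onset),
    optionally shifted by ``phase_offset_deg / 360`` periods, and must fit
    inside the stimulation window.
    """
    if protocol.kind != "sinusoid":
        raise ValueError("cycle windows are defined for sinusoidal protocols only")
    period = 1.0 / protocol.frequency_Hz
    start = protocol.onset_s if analysis_onset_s is None else float(analysis_onset_s)
    start += (phase_offset_deg / 360.0) * period
    end_needed = start + n_cycles * period
    if end_needed > protocol.end_s + 1e-9:
        raise ValueError(
            f"{n_cycles} cycles of {period:g} s do not fit in the stimulus "
            f"window ending at {protocol.end_s:g} s"
        )
    return [
        CycleWindow(start + k * period, start + (k + 1) * period, k)
        for k in range(n_cycles)
    ]


def burst_frequency_cycle(spike_times: np.ndarray, window: CycleWindow) -> float:
    """Inverse mean inter-spike interval of the in-window spikes (Hz).

    Cycles holding one spike or none contribute zero, matching how silent or
    single-spike cycles are treated in vitro.  Only intervals between spikes
    inside the window count; intervals straddling the window edge do not.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    inside = spike_times[(spike_times >= window.start_s) & (spike_times < window.end_s)]
    if inside.size <= 1:
        return 0.0
    mean_isi = float(np.mean(np.diff(inside)))
    if mean_isi <= 0.0:  # degenerate: coincident spike times
        return 0.0
    return 1.0 / mean_isi


@dataclass
class FeatureSet:
    """Per-stimulus features of one candidate.

    Step protocols map to ``mean_frequency`` (Hz) and ``latency`` (s);
    sinusoidal protocols map to the per-cycle burst frequencies
    (``burst_cycles``, Hz) with their mean (``burst_mean``) and population
    standard deviation (``burst_std``).  ``valid`` is False when any
    underlying simulation diverged; the fitness module then applies its
    penalty instead of scoring garbage.
    """

    mean_frequency: dict = field(default_factory=dict)
    latency: dict = field(default_factory=dict)
    burst_cycles: dict = field(default_factory=dict)
    burst_mean: dict = field(default_factory=dict)
    burst_std: dict = field(default_factory=dict)
    valid: bool = True


def extract_feature_set(
    params: AdExParameters,
    protocols: Sequence[StimulusProtocol],
    sim_config: SimulationConfig = SimulationConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
) -> FeatureSet:
    """Simulate every protocol once and fill a :class:`FeatureSet`.

    A pure, deterministic function of ``(params, protocols, configs)``.
    The suite must contain at least one step and one sinusoidal protocol.
    """
    steps = [p for p in protocols if p.kind == "step"]
    sines = [p for p in protocols if p.kind == "sinusoid"]
    if not steps or not sines:
        raise ValueError("protocol suite needs at least one step and one sinusoid")

    fs = FeatureSet()
    for prot in steps:
        result = simulate(params, prot, sim_config)
        if result.diverged:
            fs.valid = False
        window = (prot.onset_s, prot.end_s)
        fs.mean_frequency[prot.protocol_id] = mean_frequency(result.spike_times, window)
        fs.latency[prot.protocol_id] = first_spike_latency(
            result.spike_times, prot.onset_s, prot.duration_s
        )
    for prot in sines:
        result = simulate(params, prot, sim_config)
        if result.diverged:
            fs.valid = False
        windows = cycle_windows(
            prot,
            feature_config.n_cycles,
            feature_config.analysis_onset_s,
            feature_config.phase_offset_deg,
        )
        cycles = np.array(
            [burst_frequency_cycle(result.spike_times, w) for w in windows]
        )
        fs.burst_cycles[prot.protocol_id] = cycles
        fs.burst_mean[prot.protocol_id] = float(np.mean(cycles))
        fs.burst_std[prot.protocol_id] = float(np.std(cycles))
    return fs


def feature_set_to_dict(fs: FeatureSet) -> dict:
    """JSON-ready mapping of a feature set (units in the key names)."""
    return {
        "valid": fs.valid,
        "mean_frequency_Hz": {k: float(v) for k, v in sorted(fs.mean_frequency.items())},
        "first_spike_latency_s": {k: float(v) for k, v in sorted(fs.latency.items())},
        "burst_frequency_Hz": {k: float(v) for k, v in sorted(fs.burst_mean.items())},
        "burst_frequency_sd_Hz": {k: float(v) for k, v in sorted(fs.burst_std.items())},
        "burst_cycles_Hz": {
            k: [float(v) for v in cycles] for k, cycles in sorted(fs.burst_cycles.items())
        },
    }


def write_feature_set_csv(fs: FeatureSet, path) -> None:
    """Flat CSV: one row per (stimulus, feature) with value and units."""
    import csv

    rows = []
    for pid in sorted(fs.mean_frequency):
        rows.append((pid, "mean_frequency", fs.mean_frequency[pid], "Hz"))
    for pid in sorted(fs.latency):
        rows.append((pid, "first_spike_latency", fs.latency[pid], "s"))
    for pid in sorted(fs.burst_mean):
        rows.append((pid, "burst_frequency", fs.burst_mean[pid], "Hz"))
        rows.append((pid, "burst_frequency_sd", fs.burst_std[pid], "Hz"))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protocol_id", "feature", "value", "units"])
        for pid, feature, value, units in rows:
            writer.writerow([pid, feature, repr(float(value)), units])
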