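"""Adaptive exponential integrate-and-fire (AdEx) point-neuron simulation.

The AdEx model couples the membrane potential ``V`` with an adaptation
current ``w``::

    C_m dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T) - w + I(t)
    tau_w dw/dt = a (V - E_L) - w
    if V > V_peak:  V <- V_r,  w <- w + b

The exponential term models spike initiation: once ``V`` exceeds the
threshold ``V_T`` by a few slope factors ``Delta_T``, the upstroke diverges
in finite time and the crossing of ``V_peak`` is registered as a spike.

Internal unit system is pA / pF / nS / mV / ms, which is dimensionally
closed (nS * mV = pA, pF * mV / ms = pA).  All times crossing the public
interface are in seconds; the conversion happens at the module boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def decorator(func):
            return func

        return decorator


__all__ = [
    "PARAM_NAMES",
    "REPORT_ORDER",
    "AdExParameters",
    "ParameterBounds",
    "DEFAULT_BOUNDS",
    "StimulusProtocol",
    "SimulationConfig",
    "SimulationResult",
    "ProtocolError",
    "build_step_protocol",
    "build_sinusoid_protocol",
    "stimulus_current",
    "simulate",
]

#: Canonical ordering of the tunable parameters for array round-trips.
PARAM_NAMES = ("C_m", "g_L", "E_L", "V_T", "Delta_T", "V_peak", "V_r", "a", "b", "tau_w")

#: Ordering used in reports and CSV exports of candidate tables.
REPORT_ORDER = ("a", "V_peak", "V_T", "b", "C_m", "E_L", "g_L", "Delta_T", "tau_w", "V_r")


class ProtocolError(ValueError):
    """Raised for ill-formed stimulation protocols."""


@dataclass(frozen=True)
class AdExParameters:
    """The ten tunable physical parameters of one candidate neuron.

    Parameters
    ----------
    C_m : float
        Membrane capacitance (pF).  Must be > 0.
    g_L : float
        Total leak conductance (nS).  Must be >= 0.
    E_L : float
        Leak reversal potential (mV); also the initial membrane potential.
    V_T : float
        Spike-initiation threshold potential (mV).
    Delta_T : float
        Slope factor of the exponential spike-initiation term (mV); > 0.
    V_peak : float
        Potential that triggers the reset rule when exceeded (mV).
    V_r : float
        Post-spike reset potential (mV).
    a : float
        Subthreshold adaptation conductance (nS).
    b : float
        Spike-triggered adaptation increment (pA).
    tau_w : float
        Adaptation time constant (ms); > 0.
    """

    C_m: float
    g_L: float
    E_L: float
    V_T: float
    Delta_T: float
    V_peak: float
    V_r: float
    a: float
    b: float
    tau_w: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value!r}")
        if self.C_m <= 0:
            raise ValueError(f"C_m must be > 0 pF, got {self.C_m}")
        if self.tau_w <= 0:
            raise ValueError(f"tau_w must be > 0 ms, got {self.tau_w}")
        if self.Delta_T <= 0:
            raise ValueError(f"Delta_T must be > 0 mV, got {self.Delta_T}")
        if self.g_L < 0:
            raise ValueError(f"g_L must be >= 0 nS, got {self.g_L}")

    def to_array(self) -> np.ndarray:
        """Return the parameters as a float array in ``PARAM_NAMES`` order."""
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "AdExParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: dict) -> "AdExParameters":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise ValueError(f"missing parameter name(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for the search, one (lower, upper) pair per parameter.

    Arrays are in ``PARAM_NAMES`` order.  The defaults span the granule-cell
    search space used throughout the package.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != (len(PARAM_NAMES),) or upper.shape != (len(PARAM_NAMES),):
            raise ValueError("bounds must provide one (lower, upper) pair per parameter")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        bad = np.nonzero(lower >= upper)[0]
        if bad.size:
            names = [PARAM_NAMES[i] for i in bad]
            raise ValueError(f"lower bound must be < upper bound for: {names}")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ParameterBounds":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s) in bounds: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise ValueError(f"missing bounds for parameter(s): {sorted(missing)}")
        lower = np.array([float(mapping[n][0]) for n in PARAM_NAMES])
        upper = np.array([float(mapping[n][1]) for n in PARAM_NAMES])
        return cls(lower, upper)

    def to_dict(self) -> dict:
        return {
            name: [float(lo), float(hi)]
            for name, lo, hi in zip(PARAM_NAMES, self.lower, self.upper)
        }

    def contains(self, params: AdExParameters, atol: float = 1e-9) -> bool:
        arr = params.to_array()
        return bool(
            np.all(arr >= self.lower - atol) and np.all(arr <= self.upper + atol)
        )

    @property
    def dim(self) -> int:
        return len(PARAM_NAMES)


#: Default search-space box: capacitance 0.1-5 pF, leak 0.001-10 nS,
#: reversal/reset potentials -80..-40 mV, threshold -60..-20 mV, slope factor
#: 1-1000 mV, peak -20..20 mV, adaptation a in +-1 nS, b in +-1 pA,
#: tau_w 1-1000 ms.
DEFAULT_BOUNDS = ParameterBounds(
    lower=np.array([0.1, 0.001, -80.0, -60.0, 1.0, -20.0, -80.0, -1.0, -1.0, 1.0]),
    upper=np.array([5.0, 10.0, -40.0, -20.0, 1000.0, 20.0, -40.0, 1.0, 1.0, 1000.0]),
)


@dataclass(frozen=True)
class StimulusProtocol:
    """Description of one injected-current stimulus.

    ``kind`` is ``"step"`` (constant ``amplitude_pA`` during the window) or
    ``"sinusoid"`` (``offset_pA + amplitude_pA * sin(2 pi f (t - onset) +
    phase)``).  Outside ``[onset_s, onset_s + duration_s)`` the current is
    zero.  ``phase_deg`` is the sine phase in degrees at ``t = onset_s``
    (default 0, i.e. the current starts at the offset value).
    """

    kind: str
    amplitude_pA: float
    duration_s: float
    onset_s: float = 0.0
    offset_pA: float = 0.0
    frequency_Hz: float = 0.0
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "sinusoid"):
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")
        if not math.isfinite(self.amplitude_pA):
            raise ProtocolError("amplitude must be finite")
        if self.duration_s <= 0:
            raise ProtocolError(f"duration must be > 0 s, got {self.duration_s}")
        if self.onset_s < 0:
            raise ProtocolError(f"onset must be >= 0 s, got {self.onset_s}")
        if self.kind == "sinusoid":
            if self.frequency_Hz <= 0:
                raise ProtocolError(
                    f"sinusoid frequency must be > 0 Hz, got {self.frequency_Hz}"
                )
        else:
            if self.offset_pA != 0.0 or self.frequency_Hz != 0.0:
                raise ProtocolError("step protocols take no offset or frequency")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def protocol_id(self) -> str:
        if self.kind == "step":
            return f"step_{self.amplitude_pA:g}pA"
        return f"sin_{self.amplitude_pA:g}pA_{self.frequency_Hz:g}Hz"

    def current(self, t):
        """Injected current (pA) at time(s) ``t`` (s); vectorized and pure."""
        t = np.asarray(t, dtype=float)
        inside = (t >= self.onset_s) & (t < self.end_s)
        if self.kind == "step":
            out = np.where(inside, self.amplitude_pA, 0.0)
        else:
            phase = np.deg2rad(self.phase_deg)
            wave = self.offset_pA + self.amplitude_pA * np.sin(
                2.0 * np.pi * self.frequency_Hz * (t - self.onset_s) + phase
            )
            out = np.where(inside, wave, 0.0)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        d = {
            "id": self.protocol_id,
            "kind": self.kind,
            "amplitude_pA": float(self.amplitude_pA),
            "duration_s": float(self.duration_s),
            "onset_s": float(self.onset_s),
        }
        if self.kind == "sinusoid":
            d["offset_pA"] = float(self.offset_pA)
            d["frequency_Hz"] = float(self.frequency_Hz)
            d["phase_deg"] = float(self.phase_deg)
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "StimulusProtocol":
        known = {
            "kind", "amplitude_pA", "duration_s", "onset_s",
            "offset_pA", "frequency_Hz", "phase_deg",
        }
        fields = {k: v for k, v in mapping.items() if k != "id"}
        unknown = set(fields) - known
        if unknown:
            raise ProtocolError(f"unknown protocol field(s): {sorted(unknown)}")
        return cls(**fields)


def build_step_protocol(
    amplitude_pA: float, duration_s: float, onset_s: float = 0.0
) -> StimulusProtocol:
    """Constant current of ``amplitude_pA`` on ``[onset, onset + duration)``."""
    return StimulusProtocol(
        kind="step", amplitude_pA=amplitude_pA, duration_s=duration_s, onset_s=onset_s
    )


def build_sinusoid_protocol(
    amplitude_pA: float,
    offset_pA: float,
    frequency_Hz: float,
    duration_s: float,
    onset_s: float = 0.0,
    phase_deg: float = 0.0,
) -> StimulusProtocol:
    """Offset sinusoid: ``offset + amplitude * sin(2 pi f (t-onset) + phase)``."""
    return StimulusProtocol(
        kind="sinusoid",
        amplitude_pA=amplitude_pA,
        duration_s=duration_s,
        onset_s=onset_s,
        offset_pA=offset_pA,
        frequency_Hz=frequency_Hz,
        phase_deg=phase_deg,
    )


def stimulus_current(protocol: StimulusProtocol, t):
    """Evaluate ``protocol`` at time(s) ``t`` (seconds); returns pA."""
    return protocol.current(t)


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for the fixed-step integration.

    ``dt_ms`` is the forward-Euler step (default 0.1 ms).  ``v_init_mV`` is
    the initial membrane potential; ``None`` means start at the leak reversal
    potential ``E_L``.  ``exp_clip`` caps the argument of the exponential
    spike-initiation term before exponentiation, preventing float overflow
    during the (divergent) upstroke without altering spike timing at step
    resolution.
    """

    dt_ms: float = 0.1
    w_init_pA: float = 0.0
    v_init_mV: Optional[float] = None
    exp_clip: float = 30.0
    record_traces: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dt_ms) and self.dt_ms > 0):
            raise ValueError(f"dt_ms must be > 0, got {self.dt_ms}")
        if not (math.isfinite(self.exp_clip) and self.exp_clip > 0):
            raise ValueError(f"exp_clip must be > 0, got {self.exp_clip}")


@dataclass(frozen=True)
class SimulationResult:
    """Spike times (s, strictly increasing) plus optional sampled traces."""

    spike_times: np.ndarray
    diverged: bool = False
    t_ms: Optional[np.ndarray] = None
    V_mV: Optional[np.ndarray] = None
    w_pA: Optional[np.ndarray] = None

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@njit(cache=True)
def _euler_adex(C_m, g_L, E_L, V_T, Delta_T, V_peak, V_r, a, b, tau_w,
                V0, w0, I, dt, exp_clip, record):  # pragma: no cover - jitted
    n = I.shape[0]
    spike_steps = np.empty(n, dtype=np.int64)
    n_spikes = 0
    diverged = False
    if record:
        V_tr = np.empty(n + 1)
        w_tr = np.empty(n + 1)
        V_tr[0] = V0
        w_tr[0] = w0
    else:
        V_tr = np.empty(0)
        w_tr = np.empty(0)
    V = V0
    w = w0
    steps_done = 0
    for k in range(n):
        arg = (V - V_T) / Delta_T
        if arg > exp_clip:
            arg = exp_clip
        dV = (-g_L * (V - E_L) + g_L * Delta_T * math.exp(arg) - w + I[k]) / C_m
        dw = (a * (V - E_L) - w) / tau_w
        V = V + dt * dV
        w = w + dt * dw
        if not (math.isfinite(V) and math.isfinite(w)):
            diverged = True
            steps_done = k
            break
        if V > V_peak:
            spike_steps[n_spikes] = k
            n_spikes += 1
            V = V_r
            w = w + b
        if record:
            V_tr[k + 1] = V
            w_tr[k + 1] = w
        steps_done = k + 1
    return spike_steps[:n_spikes], diverged, V_tr, w_tr, steps_done


def simulate(
    params: AdExParameters,
    protocol: StimulusProtocol,
    config: SimulationConfig = SimulationConfig(),
) -> SimulationResult:
    """Integrate the AdEx equations under ``protocol`` and detect spikes.

    Fixed-step forward Euler at ``config.dt_ms``.  A spike is registered
    whenever the updated potential exceeds ``V_peak``; the state is then
    reset (``V <- V_r``, ``w <- w + b``) within the same step, so recorded
    trace samples never exceed ``V_peak``.  The run covers
    ``[0, protocol.end_s]``.  Identical inputs give bit-identical outputs.

    A non-finite state (possible for extreme parameter/step combinations
    despite the exponential clip) terminates the run and sets ``diverged``
    instead of raising.
    """
    dt = float(config.dt_ms)
    total_ms = protocol.end_s * 1000.0
    n_steps = int(round(total_ms / dt))
    if n_steps < 1:
        raise ValueError("protocol shorter than one integration step")
    # current sampled at the left edge of each Euler step
    t_s = np.arange(n_steps, dtype=float) * (dt / 1000.0)
    I = np.ascontiguousarray(protocol.current(t_s), dtype=float)
    v0 = params.E_L if config.v_init_mV is None else float(config.v_init_mV)
    spike_steps, diverged, V_tr, w_tr, steps_done = _euler_adex(
        params.C_m, params.g_L, params.E_L, params.V_T, params.Delta_T,
        params.V_peak, params.V_r, params.a, params.b, params.tau_w,
        v0, float(config.w_init_pA), I, dt, float(config.exp_clip),
        config.record_traces,
    )
    spike_times = (np.asarray(spike_steps, dtype=float) + 1.0) * (dt / 1000.0)
    if config.record_traces:
        n_keep = steps_done + 1
        t_ms = np.arange(n_keep, dtype=float) * dt
        return SimulationResult(
            spike_times=spike_times,
            diverged=bool(diverged),
            t_ms=t_ms,
            V_mV=np.asarray(V_tr)[:n_keep].copy(),
            w_pA=np.asarray(w_tr)[:n_keep].copy(),
        )
    return SimulationResult(spike_times=spike_times, diverged=bool(diverged))


def dump_trace_csv(result: SimulationResult, v_path, w_path) -> None:
    """Write two-column CSVs (time_ms, V_mV) and (time_ms, w_pA)."""
    if result.t_ms is None:
        raise ValueError("simulation was run without record_traces")
    np.savetxt(
        v_path,
        np.column_stack([result.t_ms, result.V_mV]),
        delimiter=",",
        header="time_ms,V_mV",
        comments="",
    )
    np.savetxt(
        w_path,
        np.column_stack([result.t_ms, result.w_pA]),
        delimiter=",",
        header="time_ms,w_pA",
        comments="",
    )
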