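"""Signal preprocessing and Izhikevich spike encoding.

The three tactile mechanoreceptor classes (SA-I, RA-I, RA-II) are emulated
with the two-variable Izhikevich neuron in regular-spiking mode,

    v' = 0.04 v^2 + 5 v + 140 - u + G * I / Cm
    u' = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

with per-receptor input gain G (kOhm): 1.3 for SA-I, 17 for RA-I and 2 for
RA-II.  Time constants follow the standard regular-spiking parameterisation
(a = 0.02, b = 0.2, c = -65, d = 8) with the state equations expressed per
millisecond, so physiological firing rates emerge on a 1 kHz sensor stream.

Preprocessing mirrors a typical acquisition chain: the piezoelectric
vibration trace is min-max normalised and band-pass filtered 5-250 Hz
(eighth-order Butterworth, zero-phase) to strip motor noise and DC; the
proprioception trace is noise-filtered and affinely mapped onto the
[0.95, 1.08] fascicle-length range expected by the muscle-spindle model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import signal

from .innervation import InnervationMap, apply_innervation
from .synth_rig import SensorRecording

__all__ = [
    "IzhikevichParams",
    "SpikeTrain",
    "preprocess_piezo",
    "preprocess_proprio",
    "izhikevich_encode",
    "encode_population",
    "RECEPTOR_GAINS",
]

# Table of per-receptor input gains (kOhm)
RECEPTOR_GAINS = {"SA-I": 1.3, "RA-I": 17.0, "RA-II": 2.0}

# Full-scale sensor voltage: normalized channel values in [-1, 1] or [0, 1]
# are interpreted against the 5 V supply rail of the readout electronics.
SENSOR_FULL_SCALE_V = 5.0

PIEZO_BAND_HZ = (5.0, 250.0)
PIEZO_BAND_ORDER = 4  # per band edge -> eighth-order band-pass
# Dataset-level normalisation scale (volts) for the piezo channel: dividing
# every trial by the same reference keeps relative vibration amplitude --
# which grows with scanning speed -- informative across trials, mirroring
# the per-dataset (not per-trial) normalisation of the taxel channels.
PIEZO_NORM_SCALE_V = 2.5
PROPRIO_HP_HZ = 1.0
PROPRIO_LP_HZ = 20.0
PROPRIO_RANGE = (0.95, 1.08)


@dataclass(frozen=True)
class IzhikevichParams:
    """Regular-spiking Izhikevich parameters with receptor gain ``G``."""

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    G: float = 1.0
    Cm: float = 1.0
    v_peak: float = 30.0

    def with_gain(self, gain: float) -> "IzhikevichParams":
        return replace(self, G=gain)

    @property
    def resting_state(self) -> tuple[float, float]:
        """Stable fixed point of the subthreshold dynamics at I = 0.

        Solving 0.04 v^2 + 5 v + 140 - u = 0 with u = b v gives
        v in {-50, -70}; the lower root is the stable one.
        """
        disc = np.sqrt((5.0 - self.b) ** 2 - 4 * 0.04 * 140.0)
        v = (-(5.0 - self.b) - disc) / (2 * 0.04)
        return float(v), float(self.b * v)


@dataclass
class SpikeTrain:
    """Ordered spike times (s) of one afferent over one trial."""

    spike_times: np.ndarray
    duration: float
    afferent_id: str = ""
    afferent_type: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and (
            np.any(np.diff(self.spike_times) <= 0)
            or self.spike_times[0] < 0
            or self.spike_times[-1] > self.duration
        ):
            raise ValueError("spike times must be strictly increasing in "
                             "[0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def rate(self) -> float:
        return self.n_spikes / self.duration if self.duration > 0 else 0.0


def preprocess_piezo(trace: np.ndarray, sample_rate: float,
                     scale: float | None = None) -> np.ndarray:
    """Normalise and band-pass the piezoelectric vibration trace.

    Normalisation precedes an eighth-order Butterworth band-pass
    (5-250 Hz) applied forward-backward (zero phase); DC and sub-5 Hz
    robot-motion components are removed.  With ``scale=None`` the trace is
    min-max normalised to [-1, 1] (per-trial); with a numeric ``scale``
    the mean-removed trace is divided by that fixed reference instead, so
    vibration amplitude remains comparable across trials of one dataset.
    """
    trace = np.asarray(trace, dtype=float)
    if sample_rate < 1000.0:
        raise ValueError("sample_rate must be >= 1000 Hz for a 250 Hz corner")
    if trace.size < 3 * 2 * PIEZO_BAND_ORDER:
        raise ValueError("trace shorter than filter warm-up")
    if scale is None:
        lo, hi = trace.min(), trace.max()
        if hi > lo:
            trace = 2.0 * (trace - lo) / (hi - lo) - 1.0
        else:
            trace = np.zeros_like(trace)
    else:
        if scale <= 0:
            raise ValueError("scale must be positive")
        trace = (trace - trace.mean()) / scale
    sos = signal.butter(PIEZO_BAND_ORDER, PIEZO_BAND_HZ, "bandpass",
                        fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, trace)


def preprocess_proprio(trace: np.ndarray, sample_rate: float,
                       filter_mode: str = "smooth_only") -> np.ndarray:
    """Filter the proprioception trace and map it onto [0.95, 1.08].

    ``filter_mode='smooth_only'`` (default) removes measurement noise with a
    20 Hz second-order low-pass, preserving the absolute position trend the
    spindle model needs.  ``filter_mode='highpass'`` applies a first-order
    1 Hz Butterworth high-pass instead; note that it also strips the slow
    position trend, so it is offered for protocol comparison only.  The
    filtered trace is affinely mapped so its minimum is exactly 0.95 and
    its maximum exactly 1.08 (normalised fascicle length).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty proprio trace")
    if filter_mode not in ("smooth_only", "highpass", "none"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    filtered = trace
    if trace.size > 24 and filter_mode == "smooth_only":
        sos = signal.butter(2, PROPRIO_LP_HZ, "lowpass", fs=sample_rate,
                            output="sos")
        filtered = signal.sosfiltfilt(sos, trace)
    elif trace.size > 24 and filter_mode == "highpass":
        sos = signal.butter(1, PROPRIO_HP_HZ, "highpass", fs=sample_rate,
                            output="sos")
        filtered = signal.sosfiltfilt(sos, trace)
    lo, hi = filtered.min(), filtered.max()
    if hi - lo <= 0:
        raise ValueError("degenerate proprio signal (zero range)")
    lo_m, hi_m = PROPRIO_RANGE
    return lo_m + (hi_m - lo_m) * (filtered - lo) / (hi - lo)


@njit(cache=False)
def _integrate(currents, dt_ms, substeps, a, b, c, d, v_peak, v0, u0):
    """Explicit-midpoint (RK2) integration of a bank of Izhikevich neurons.

    ``currents`` is (n_neurons, T) in effective drive units (G*I/Cm already
    applied), held constant within each sample of ``1/substeps`` ms steps.
    The second-order step plus linear interpolation of the threshold
    crossing (with the post-reset remainder of the step integrated from
    the reset state) keeps spike-time error well below the step size.
    Returns flat arrays (neuron_index, spike_step_index, crossing_frac).
    """
    n, T = currents.shape
    v = np.full(n, v0)
    u = np.full(n, u0)
    max_spikes = n * T * substeps
    sp_neuron = np.empty(max_spikes, dtype=np.int64)
    sp_step = np.empty(max_spikes, dtype=np.int64)
    sp_frac = np.empty(max_spikes, dtype=np.float64)
    k = 0
    for j in range(T):
        for s in range(substeps):
            for i in range(n):
                I = currents[i, j]
                v_old = v[i]
                u_old = u[i]
                dv1 = 0.04 * v_old * v_old + 5.0 * v_old + 140.0 - u_old + I
                du1 = a * (b * v_old - u_old)
                vm = v_old + 0.5 * dt_ms * dv1
                um = u_old + 0.5 * dt_ms * du1
                dv2 = 0.04 * vm * vm + 5.0 * vm + 140.0 - um + I
                du2 = a * (b * vm - um)
                v_new = v_old + dt_ms * dv2
                u_new = u_old + dt_ms * du2
                if v_new >= v_peak:
                    theta = (v_peak - v_old) / (v_new - v_old)
                    if theta < 0.0:
                        theta = 0.0
                    elif theta > 1.0:
                        theta = 1.0
                    sp_neuron[k] = i
                    sp_step[k] = j * substeps + s
                    sp_frac[k] = theta
                    k += 1
                    # reset at the crossing, then finish the step
                    v_r = c
                    u_r = u_old + theta * dt_ms * du2 + d
                    rem = (1.0 - theta) * dt_ms
                    dv1 = 0.04 * v_r * v_r + 5.0 * v_r + 140.0 - u_r + I
                    du1 = a * (b * v_r - u_r)
                    vm = v_r + 0.5 * rem * dv1
                    um = u_r + 0.5 * rem * du1
                    dv2 = 0.04 * vm * vm + 5.0 * vm + 140.0 - um + I
                    du2 = a * (b * vm - um)
                    v[i] = v_r + rem * dv2
                    u[i] = u_r + rem * du2
                    if v[i] >= v_peak:  # pathological drive: clamp below
                        v[i] = c
                elif v_new > 1000.0 or v_new != v_new:
                    return sp_neuron[:0], sp_step[:0], sp_frac[:0], True
                else:
                    v[i] = v_new
                    u[i] = u_new
    return sp_neuron[:k], sp_step[:k], sp_frac[:k], False


def izhikevich_encode(current: np.ndarray, params: IzhikevichParams,
                      dt: float = 0.25e-3, sample_rate: float = 1000.0
                      ) -> SpikeTrain:
    """Encode one input-current trace into a spike train.

    ``current`` is sampled at ``sample_rate`` and held constant within each
    sample while the neuron is integrated with explicit-midpoint substeps
    of ``dt`` seconds (default 0.25 ms).  The gain ``params.G`` is applied
    to the current; integration starts from the resting fixed point.
    """
    trains = encode_currents(np.asarray(current, float)[None, :], [params],
                             dt=dt, sample_rate=sample_rate)
    return trains[0]


def encode_currents(currents: np.ndarray, params_list: list[IzhikevichParams],
                    dt: float = 0.25e-3, sample_rate: float = 1000.0
                    ) -> list[SpikeTrain]:
    """Vectorised encoding of a (n, T) current matrix, one params per row."""
    if dt > 1e-3:
        raise ValueError("dt must be <= 1 ms")
    currents = np.asarray(currents, dtype=float)
    if not np.all(np.isfinite(currents)):
        raise ValueError("currents must be finite")
    n, T = currents.shape
    if len(params_list) != n:
        raise ValueError("one IzhikevichParams per current row required")
    substeps = max(1, int(round(1.0 / (sample_rate * dt))))
    dt_ms = 1000.0 / (sample_rate * substeps)

    p0 = params_list[0]
    for p in params_list:
        if (p.a, p.b, p.c, p.d, p.v_peak) != (p0.a, p0.b, p0.c, p0.d, p0.v_peak):
            raise ValueError("mixed neuron dynamics in one bank")
    gains = np.array([p.G / p.Cm for p in params_list])
    drive = gains[:, None] * currents
    v0, u0 = p0.resting_state
    sp_neuron, sp_step, sp_frac, blew_up = _integrate(
        drive, dt_ms, substeps, p0.a, p0.b, p0.c, p0.d, p0.v_peak, v0, u0)
    if blew_up:
        raise FloatingPointError(
            "membrane potential diverged; use a smaller integration step dt")
    duration = T / sample_rate
    step_s = dt_ms / 1000.0
    trains = []
    for i in range(n):
        sel = sp_neuron == i
        times = np.minimum((sp_step[sel] + sp_frac[sel]) * step_s, duration)
        trains.append(SpikeTrain(times, duration))
    return trains


def encode_population(recording: SensorRecording, imap: InnervationMap,
                      params: IzhikevichParams | None = None,
                      gains: dict[str, float] | None = None,
                      dt: float = 0.25e-3,
                      ra_pathway: str = "dynamic",
                      piezo_scale: float | None = PIEZO_NORM_SCALE_V
                      ) -> list[SpikeTrain]:
    """Encode a full recording into the tactile afferent population.

    Returns ``n_sa1 + n_ra1 + 1`` spike trains in row order: the SA-I and
    RA-I trains driven through the innervation map, then the single RA-II
    train driven by the preprocessed piezo trace.  Normalised channel
    values are interpreted as fractions of the 5 V sensor full scale.
    """
    if params is None:
        params = IzhikevichParams()
    if gains is None:
        gains = RECEPTOR_GAINS
    drive = apply_innervation(imap, recording, ra_pathway=ra_pathway)
    piezo = preprocess_piezo(recording.piezo, recording.sample_rate,
                             scale=piezo_scale)
    currents = np.vstack([drive.currents, piezo[None, :]])
    currents = SENSOR_FULL_SCALE_V * currents
    types = list(drive.afferent_types) + ["RA-II"]
    params_list = [params.with_gain(gains[t]) for t in types]
    trains = encode_currents(currents, params_list, dt=dt,
                             sample_rate=recording.sample_rate)
    prefixes = {"SA-I": "sa1", "RA-I": "ra1", "RA-II": "ra2"}
    counters: dict[str, int] = {}
    for train, t in zip(trains, types):
        counters[t] = counters.get(t, 0) + 1
        train.afferent_type = t
        train.afferent_id = f"{prefixes[t]}_{counters[t]}"
    return trains
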