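"""Biomimetic-fingertip scan simulator.

Produces the three sensor channels a soft robotic fingertip records while
sliding over a fine texture at constant speed:

* an 8x8 piezoresistive taxel array (normalized contact pressure in [0, 1]),
* a single piezoelectric vibration trace (volts, arbitrary scale), and
* a proprioception (fingertip position) trace (volts, monotone ramp).

A texture is modelled as a 1-D surface-height profile: a sum of sinusoidal
spatial components plus broadband roughness noise.  Scanning at speed ``v``
turns a spatial wavelength ``p`` (mm) into a temporal vibration frequency
``v / p`` (Hz), so faster scans shift the induced vibration spectrum upward
-- the property the downstream encoding and classification stages must cope
with.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "TextureSpec",
    "ScanConfig",
    "SensorRecording",
    "default_texture_library",
    "generate_texture_profile",
    "simulate_scan",
    "make_dataset",
]

TAXEL_GRID = 8
TAXEL_PITCH_MM = 1.5  # array pitch of the 8x8 sensor

# Quasi-static elastomer filtering of the taxel pathway: the soft silicone
# layer disperses indentation, acting as a mechanical low-pass.
ELASTOMER_LP_HZ = 50.0
ELASTOMER_LP_ORDER = 2

PIEZO_NOISE_FRAC = 0.01    # sensor noise SD as a fraction of signal RMS
PROPRIO_NOISE_FRAC = 0.005  # position-sensor noise SD as fraction of range
PROPRIO_VOLTS_PER_MM = 0.1  # arbitrary but fixed transduction gain


@dataclass(frozen=True)
class TextureSpec:
    """Parametric stand-in for one physical texture surface.

    ``spatial_periods`` are the wavelengths (mm) of the sinusoidal surface
    components, ``amplitudes`` their relative heights, and
    ``roughness_noise_sd`` the SD of broadband surface noise.  These specs
    are synthetic surrogates with distinct spectral signatures; they are not
    measurements of any physical sample.
    """

    texture_id: int
    spatial_periods: tuple[float, ...]
    amplitudes: tuple[float, ...]
    roughness_noise_sd: float = 0.0
    contact_gain: float = 0.15

    def __post_init__(self) -> None:
        periods = tuple(float(p) for p in self.spatial_periods)
        amps = tuple(float(a) for a in self.amplitudes)
        object.__setattr__(self, "spatial_periods", periods)
        object.__setattr__(self, "amplitudes", amps)
        if len(periods) == 0:
            raise ValueError("texture needs at least one spatial component")
        if len(periods) != len(amps):
            raise ValueError("spatial_periods and amplitudes length mismatch")
        if any(p <= 0 for p in periods):
            raise ValueError("spatial periods must be positive")
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")
        if self.roughness_noise_sd < 0:
            raise ValueError("roughness_noise_sd must be non-negative")

    @property
    def min_period(self) -> float:
        return min(self.spatial_periods)


@dataclass(frozen=True)
class ScanConfig:
    """One constant-speed scan: speed (mm/s) plus duration or displacement.

    Exactly one of ``duration`` (s) / ``displacement`` (mm) is given; the
    other is derived via ``displacement = speed * duration``.
    """

    speed: float
    duration: float | None = None
    displacement: float | None = None
    sample_rate: float = 1000.0
    indentation: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if (self.duration is None) == (self.displacement is None):
            raise ValueError("give exactly one of duration or displacement")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0.0 <= self.indentation <= 1.0:
            raise ValueError("indentation must lie in [0, 1]")
        if self.duration is None:
            object.__setattr__(self, "duration", self.displacement / self.speed)
        else:
            object.__setattr__(self, "displacement", self.speed * self.duration)
        if self.duration <= 0:
            raise ValueError("scan duration must be positive")
        if not 40.0 <= self.speed <= 90.0:
            warnings.warn(
                f"scanning speed {self.speed} mm/s outside the calibrated "
                "40-90 mm/s range",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass
class SensorRecording:
    """Time-aligned raw channels of one scan trial.

    ``taxels`` has shape (T, 8, 8) with values in [0, 1]; ``piezo`` and
    ``proprio`` have shape (T,).
    """

    taxels: np.ndarray
    piezo: np.ndarray
    proprio: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.taxels.shape[0]
        if self.piezo.shape[0] != t or self.proprio.shape[0] != t:
            raise ValueError("channel lengths differ")
        if self.taxels.shape[1:] != (TAXEL_GRID, TAXEL_GRID):
            raise ValueError("taxel frames must be 8x8")

    @property
    def duration(self) -> float:
        return self.taxels.shape[0] / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.taxels.shape[0]

    def taxels_flat(self) -> np.ndarray:
        """Taxel series as a (64, T) channel matrix (row-major grid order)."""
        return self.taxels.reshape(self.n_samples, -1).T


def default_texture_library() -> list[TextureSpec]:
    """Ten synthetic textures S1..S10 with distinct spectral signatures.

    Periods span 0.4-3.0 mm (fine-texture regime).  The lower bound keeps
    the fastest scan (90 mm/s) below the 250 Hz analysis band-edge and well
    below the 1 kHz Nyquist limit.
    """
    return [
        TextureSpec(1, (2.0,), (1.0,), 0.02),
        TextureSpec(2, (1.2,), (1.0,), 0.02),
        TextureSpec(3, (0.8,), (1.0,), 0.03),
        TextureSpec(4, (0.55,), (1.0,), 0.03),
        TextureSpec(5, (0.4,), (1.0,), 0.03),
        TextureSpec(6, (2.5, 0.6), (0.7, 0.5), 0.02),
        TextureSpec(7, (1.6, 0.45), (0.6, 0.6), 0.04),
        TextureSpec(8, (2.8, 1.0, 0.5), (0.5, 0.4, 0.3), 0.05),
        TextureSpec(9, (0.9, 0.45), (0.5, 0.7), 0.08),
        TextureSpec(10, (1.4,), (0.4,), 0.15),
    ]


def generate_texture_profile(
    spec: TextureSpec,
    length_mm: float,
    resolution: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample the 1-D surface-height profile of ``spec``.

    Parameters
    ----------
    length_mm : spatial extent of the profile (mm).
    resolution : samples per mm; the finest spatial period must span at
        least 4 samples.
    seed : RNG seed (or Generator) controlling component phases and the
        roughness noise; the profile is deterministic given the seed.
    """
    if length_mm <= 0:
        raise ValueError("length must be positive")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if spec.min_period * resolution < 4:
        raise ValueError(
            f"resolution {resolution}/mm undersamples the finest period "
            f"{spec.min_period} mm (need >= {4 / spec.min_period:.1f}/mm)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(length_mm * resolution))
    x = np.arange(n) / resolution
    profile = np.zeros(n)
    for period, amp in zip(spec.spatial_periods, spec.amplitudes):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        profile += amp * np.sin(2.0 * np.pi * x / period + phase)
    if spec.roughness_noise_sd > 0:
        profile += rng.normal(0.0, spec.roughness_noise_sd, size=n)
    return profile


def _check_aliasing(spec: TextureSpec, cfg: ScanConfig) -> None:
    for period in spec.spatial_periods:
        f = cfg.speed / period
        if cfg.sample_rate <= 2.0 * f:
            raise ValueError(
                f"component with period {period} mm at {cfg.speed} mm/s "
                f"induces {f:.1f} Hz, aliased at fs={cfg.sample_rate} Hz"
            )


def _piezo_aperture() -> np.ndarray:
    """Gaussian sensitivity aperture of the central vibration sensor.

    The piezoelectric disc sits under the centre of the fingertip, so taxel
    contributions to the vibration signal fall off with distance from the
    array centre.  The aperture is slightly off-centre (as any physical
    mounting is), which also prevents exact phase cancellation across the
    taxel columns when the spatial period divides twice the 1.5 mm pitch.
    """
    rows = np.arange(TAXEL_GRID) - ((TAXEL_GRID - 1) / 2.0 + 0.23)
    cols = np.arange(TAXEL_GRID) - ((TAXEL_GRID - 1) / 2.0 + 0.37)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.exp(-(rr**2 + cc**2) / (2.0 * 2.0**2))


def simulate_scan(spec: TextureSpec, cfg: ScanConfig) -> SensorRecording:
    """Simulate one constant-speed scan of ``spec``.

    Each taxel sees ``indentation + contact_gain * profile`` evaluated at its
    own position along the scan axis (columns trail by the 1.5 mm pitch;
    rows get a fixed per-scan lateral jitter emulating 2-D surface
    irregularity), low-pass filtered by the elastomer layer and clipped to
    [0, 1].  The piezo channel is the aperture-weighted time derivative of
    the raw (unfiltered) contact signal; the proprio channel is a noisy
    linear ramp proportional to fingertip displacement.
    """
    _check_aliasing(spec, cfg)
    rng = np.random.default_rng(cfg.seed)

    fs = cfg.sample_rate
    n = cfg.n_samples
    t = np.arange(n) / fs
    pos = cfg.speed * t  # mm

    span = (TAXEL_GRID - 1) * TAXEL_PITCH_MM
    resolution = max(20.0, np.ceil(8.0 / spec.min_period))
    margin = max(spec.spatial_periods)
    length = cfg.displacement + span + 2 * margin
    profile = generate_texture_profile(spec, length, resolution, rng)
    x_grid = np.arange(profile.size) / resolution

    # per-row lateral jitter (mm) -- rows slide over slightly shifted
    # tracks; a fraction of the coarsest period, since naturalistic
    # surfaces stay largely coherent across the 10.5 mm contact width
    row_jitter = rng.uniform(0.0, 0.15 * max(spec.spatial_periods),
                             size=TAXEL_GRID)

    raw = np.empty((n, TAXEL_GRID, TAXEL_GRID))
    for r in range(TAXEL_GRID):
        for c in range(TAXEL_GRID):
            x = pos + c * TAXEL_PITCH_MM + row_jitter[r] + margin
            raw[:, r, c] = np.interp(x, x_grid, profile)
    contact = cfg.indentation + spec.contact_gain * raw

    # taxel pathway: elastomer low-pass then clip to the sensor range
    sos = signal.butter(ELASTOMER_LP_ORDER, ELASTOMER_LP_HZ, "lowpass", fs=fs,
                        output="sos")
    if n > 24:
        taxels = signal.sosfiltfilt(sos, contact, axis=0)
    else:
        taxels = contact
    taxels = np.clip(taxels, 0.0, 1.0)

    # piezo pathway: derivative of the aperture-weighted raw contact sum
    aperture = _piezo_aperture()
    summed = np.tensordot(contact, aperture, axes=([1, 2], [0, 1]))
    piezo = np.gradient(summed, 1.0 / fs)
    rms = np.sqrt(np.mean(piezo**2))
    if rms > 0:
        piezo = piezo + rng.normal(0.0, PIEZO_NOISE_FRAC * rms, size=n)

    # proprio pathway: linear ramp in volts with additive measurement noise
    proprio = PROPRIO_VOLTS_PER_MM * pos
    vrange = proprio[-1] - proprio[0] if n > 1 else 1.0
    proprio = proprio + rng.normal(0.0, PROPRIO_NOISE_FRAC * abs(vrange), size=n)

    meta = {
        "texture_id": spec.texture_id,
        "speed": cfg.speed,
        "repetition": 0,
        "seed": cfg.seed,
    }
    return SensorRecording(taxels, piezo, proprio, fs, meta)


def trial_seed(master_seed: int, texture_id: int, speed: float, repetition: int) -> int:
    """Stable per-trial seed derived from the master seed and trial labels."""
    key = f"{master_seed}|{texture_id}|{speed:.6g}|{repetition}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


def make_dataset(
    specs: list[TextureSpec],
    speeds: list[float],
    repetitions: int,
    cfg: ScanConfig | None = None,
    master_seed: int = 0,
) -> list[SensorRecording]:
    """Full-factorial dataset: one recording per (texture, speed, repetition).

    Per-trial seeds are derived deterministically from ``master_seed`` and
    the trial labels, so any single trial can be regenerated in isolation.
    """
    if not specs or not speeds:
        raise ValueError("specs and speeds must be non-empty")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    ids = [s.texture_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate texture_ids in spec list")
    if cfg is None:
        cfg = ScanConfig(speed=speeds[0], displacement=40.0)
    recordings = []
    for spec in specs:
        for speed in speeds:
            for rep in range(repetitions):
                seed = trial_seed(master_seed, spec.texture_id, speed, rep)
                trial_cfg = replace(cfg, speed=speed, duration=None,
                                    displacement=cfg.displacement, seed=seed)
                rec = simulate_scan(spec, trial_cfg)
                rec.meta["repetition"] = rep
                recordings.append(rec)
    return recordings
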