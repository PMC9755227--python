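"""Muscle-spindle afferent model (three intrafusal fibers with occlusion).

The proprioception channel, mapped onto normalised fascicle length
L in [0.95, 1.08], drives three intrafusal fibers -- bag1, bag2 and chain.
Each fiber's firing rate is a rectified polynomial function of stretch and
stretch speed,

    rate = max(0, k_f * f  +  k_L * (L - 0.95)  +  k_V * sign(dL) * |dL|^0.3)

where ``f`` is the constant fusimotor drive for that fiber class (the
dynamic drive for bag1, the static drive for bag2/chain; both default to
70 spikes/s).  Bag1 carries the velocity sensitivity; bag2 and chain are
length-sensitive only.

The primary afferent (MS-Prim) combines all fibers with partial occlusion:
the smaller of bag1 and (bag2 + chain) is attenuated by S = 0.156 before
summation, i.e.  prim = max(b1, b2c) + S * min(b1, b2c).  The secondary
afferent (MS-Sec) is simply bag2 + chain.  Both outputs are instantaneous
firing rates (spikes/s), not spike trains.

Fiber gain defaults are stand-ins chosen to give physiologically plausible
rate ranges on ramp-and-hold stretches; the fiber law is pluggable so a
full differential-equation intrafusal model can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "FiberParams",
    "SpindleConfig",
    "SpindleResponse",
    "combine_intrafusal",
    "intrafusal_response",
    "spindle_afferents",
]

L_REST = 0.95  # mapped fascicle length at rest
VELOCITY_LP_HZ = 20.0  # smoothing of the numerically estimated dL/dt


@dataclass(frozen=True)
class FiberParams:
    """Rate-law coefficients of one intrafusal fiber.

    k_f : spikes/s per (spike/s) of fusimotor drive (baseline offset gain)
    k_L : spikes/s per unit of normalised length above rest
    k_V : spikes/s per (unit length/s)^velocity_exponent
    """

    k_f: float
    k_L: float
    k_V: float
    velocity_exponent: float = 0.3


@dataclass(frozen=True)
class SpindleConfig:
    """Fusimotor drives, occlusion factor and per-fiber parameters."""

    f_dynamic: float = 70.0
    f_static: float = 70.0
    S: float = 0.156
    bag1: FiberParams = field(default_factory=lambda: FiberParams(
        k_f=0.15, k_L=200.0, k_V=100.0))
    bag2: FiberParams = field(default_factory=lambda: FiberParams(
        k_f=0.10, k_L=150.0, k_V=0.0))
    chain: FiberParams = field(default_factory=lambda: FiberParams(
        k_f=0.10, k_L=150.0, k_V=0.0))

    def fiber(self, name: str) -> FiberParams:
        if name not in ("bag1", "bag2", "chain"):
            raise ValueError(f"unknown intrafusal fiber {name!r}")
        return getattr(self, name)

    def drive(self, name: str) -> float:
        return self.f_dynamic if name == "bag1" else self.f_static


@dataclass
class SpindleResponse:
    """MS-Prim and MS-Sec instantaneous firing-rate traces (spikes/s)."""

    prim_rate: np.ndarray
    sec_rate: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if self.prim_rate.shape != self.sec_rate.shape:
            raise ValueError("prim/sec length mismatch")
        if np.any(self.prim_rate < 0) or np.any(self.sec_rate < 0):
            raise ValueError("firing rates must be non-negative")


def _length_velocity(L: np.ndarray, sample_rate: float) -> np.ndarray:
    """dL/dt from sampled L: central differences then 20 Hz low-pass."""
    dL = np.gradient(L, 1.0 / sample_rate)
    if L.size > 24 and sample_rate > 2.0 * VELOCITY_LP_HZ:
        sos = signal.butter(2, VELOCITY_LP_HZ, "lowpass", fs=sample_rate,
                            output="sos")
        dL = signal.sosfiltfilt(sos, dL)
    return dL


def intrafusal_response(L: np.ndarray, sample_rate: float, fiber: str,
                        cfg: SpindleConfig | None = None) -> np.ndarray:
    """Firing-rate trace of one intrafusal fiber for a length trace ``L``."""
    if cfg is None:
        cfg = SpindleConfig()
    L = np.asarray(L, dtype=float)
    if np.any(~np.isfinite(L)):
        raise ValueError("NaN/inf in fascicle length trace")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    lo, hi = L_REST * 0.8, 1.08 * 1.2
    if L.min() < lo or L.max() > hi:
        raise ValueError("length trace far outside the mapped [0.95, 1.08] "
                         "range; run preprocess_proprio first")
    p = cfg.fiber(fiber)
    dL = _length_velocity(L, sample_rate)
    rate = (p.k_f * cfg.drive(fiber)
            + p.k_L * (L - L_REST)
            + p.k_V * np.sign(dL) * np.abs(dL) ** p.velocity_exponent)
    return np.maximum(rate, 0.0)


def combine_intrafusal(b1, b2c, S: float = 0.156):
    """Partial-occlusion combination of fiber rates into (prim, sec).

    The smaller of the bag1 response and the summed bag2+chain response is
    attenuated by ``S`` before summation; the secondary afferent carries
    bag2+chain alone.  Elementwise over arrays.
    """
    b1 = np.asarray(b1, dtype=float)
    b2c = np.asarray(b2c, dtype=float)
    prim = np.maximum(b1, b2c) + S * np.minimum(b1, b2c)
    return prim, b2c


def spindle_afferents(L: np.ndarray, sample_rate: float,
                      cfg: SpindleConfig | None = None) -> SpindleResponse:
    """MS-Prim / MS-Sec rates from a mapped fascicle-length trace.

    With b1 the bag1 rate and b2c = bag2 + chain, elementwise over time:

        prim = max(b1, b2c) + S * min(b1, b2c)
        sec  = b2c
    """
    if cfg is None:
        cfg = SpindleConfig()
    b1 = intrafusal_response(L, sample_rate, "bag1", cfg)
    b2c = (intrafusal_response(L, sample_rate, "bag2", cfg)
           + intrafusal_response(L, sample_rate, "chain", cfg))
    prim, sec = combine_intrafusal(b1, b2c, cfg.S)
    return SpindleResponse(prim, sec, sample_rate)
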