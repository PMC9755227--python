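"""Random weighted innervation of the 8x8 taxel array.

Each model afferent (12 SA-I and 24 RA-I by default, the 1:2 ratio of
slowly- to rapidly-adapting type-I units) is connected to a spatially
connected neighborhood of taxels with distance-decaying weights, forming
complex overlapping receptive fields.  Driving currents for the spiking
neurons are then weighted sums over each afferent's receptive field: the
raw (static) taxel signal for SA-I, and a band-limited temporal-derivative
signal for RA-I, which responds to dynamic skin deformation only.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth_rig import SensorRecording, TAXEL_GRID

__all__ = [
    "InnervationMap",
    "AfferentDrive",
    "build_innervation",
    "apply_innervation",
    "mean_innervated_taxels",
]

logger = logging.getLogger(__name__)

N_TAXELS = TAXEL_GRID * TAXEL_GRID
MIN_WEIGHT = 0.001  # smallest admissible positive connection weight

RA_BAND_HZ = (5.0, 250.0)
RA_BAND_ORDER = 4  # per band edge
# Reference frequency normalising the derivative pathway: a unit-amplitude
# sinusoidal taxel oscillation at this frequency yields a unit-amplitude
# dynamic drive, so faster vibrations produce proportionally stronger input.
RA_REFERENCE_HZ = 12.5


@dataclass
class InnervationMap:
    """Weighted afferent x taxel connection matrix.

    ``weights`` has shape (n_afferents, 64); positive entries are >=
    ``MIN_WEIGHT``.  ``afferent_types`` labels each row 'SA-I' or 'RA-I'.
    """

    weights: np.ndarray
    afferent_types: list[str]
    target_mean_innervation: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weights.shape != (len(self.afferent_types), N_TAXELS):
            raise ValueError("weights shape inconsistent with afferent_types")

    @property
    def n_afferents(self) -> int:
        return self.weights.shape[0]

    def rows_of_type(self, afferent_type: str) -> np.ndarray:
        return np.array([t == afferent_type for t in self.afferent_types])

    def to_csv(self) -> str:
        """Serialize as CSV: one row per afferent, type column first."""
        buf = io.StringIO()
        header = ["afferent_type"] + [f"taxel_{i}" for i in range(N_TAXELS)]
        buf.write(",".join(header) + "\n")
        for t, row in zip(self.afferent_types, self.weights):
            buf.write(t + "," + ",".join(f"{w:.6g}" for w in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, target_mean: float = 0.0, seed: int = 0
                 ) -> "InnervationMap":
        lines = [ln for ln in text.strip().splitlines() if ln]
        types, rows = [], []
        for ln in lines[1:]:
            parts = ln.split(",")
            types.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(np.array(rows), types, target_mean, seed)


@dataclass
class AfferentDrive:
    """Per-afferent input-current traces, rows aligned with the map."""

    currents: np.ndarray
    afferent_types: list[str]
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.currents.shape[0] != len(self.afferent_types):
            raise ValueError("row count / type count mismatch")
        if not np.all(np.isfinite(self.currents)):
            raise ValueError("non-finite drive values")


def _neighbors8(idx: int) -> list[int]:
    r, c = divmod(idx, TAXEL_GRID)
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < TAXEL_GRID and 0 <= cc < TAXEL_GRID:
                out.append(rr * TAXEL_GRID + cc)
    return out


def _chebyshev(a: int, b: int) -> int:
    ra, ca = divmod(a, TAXEL_GRID)
    rb, cb = divmod(b, TAXEL_GRID)
    return max(abs(ra - rb), abs(ca - cb))


def _grow_field(center: int, size: int, covered: np.ndarray,
                rng: np.random.Generator) -> list[int]:
    """Grow a connected 8-neighborhood of ``size`` taxels from ``center``.

    Frontier taxels not yet covered by any afferent are preferred, which
    keeps full-array coverage achievable at low innervation densities
    without losing spatial locality.
    """
    members = [center]
    in_field = {center}
    while len(members) < size:
        frontier = sorted({n for m in members for n in _neighbors8(m)} - in_field)
        if not frontier:
            break
        uncovered = [f for f in frontier if not covered[f]]
        pool = uncovered if uncovered else frontier
        nxt = int(rng.choice(pool))
        members.append(nxt)
        in_field.add(nxt)
    return members


def build_innervation(n_sa1: int = 12, n_ra1: int = 24,
                      target_mean: float = 7.2, seed: int = 0
                      ) -> InnervationMap:
    """Draw a random innervation map with a requested mean receptive-field size.

    The total number of positive connections is ``round(target_mean * n)``,
    split across afferents as evenly as the integer constraint allows, so
    the realized mean innervation tracks the target tightly.  Every taxel
    is guaranteed at least one afferent: orphan taxels remaining after
    field growth are appended to the nearest afferent (lowest row index on
    ties), which can raise the realized mean above a low target.

    Weights decay with Chebyshev distance ``d`` from the field centre and
    their amplitude grows with the field size ``m``:
    ``w = max(0.001, u * min(1, m / 4) * exp(-d / lambda))`` with
    ``u ~ U(0.5, 1)``.  Sparse innervation therefore yields dim, low-gain
    receptive fields (weights approaching the 0.001 floor) while dense
    innervation yields bright high-gain centres -- the gain/density
    coupling that makes very sparse wiring weakly informative.
    """
    n = n_sa1 + n_ra1
    if n_sa1 < 1 or n_ra1 < 1:
        raise ValueError("need at least one afferent of each type")
    if not 1.0 <= target_mean <= N_TAXELS:
        raise ValueError(f"target_mean must lie in [1, {N_TAXELS}]")
    rng = np.random.default_rng(seed)

    total = int(round(target_mean * n))
    base = total // n
    extra = total - base * n
    sizes = np.full(n, base, dtype=int)
    sizes[rng.choice(n, size=extra, replace=False)] += 1
    sizes = np.maximum(sizes, 1)

    covered = np.zeros(N_TAXELS, dtype=bool)
    centers = np.empty(n, dtype=int)
    fields: list[list[int]] = []
    for i in range(n):
        uncovered = np.flatnonzero(~covered)
        pool = uncovered if uncovered.size else np.arange(N_TAXELS)
        center = int(rng.choice(pool))
        members = _grow_field(center, int(sizes[i]), covered, rng)
        covered[members] = True
        centers[i] = center
        fields.append(members)

    orphans = np.flatnonzero(~covered)
    if orphans.size:
        logger.warning("appending %d orphan taxels to nearest afferents",
                       orphans.size)
        for taxel in orphans:
            dists = np.array([_chebyshev(taxel, c) for c in centers])
            # nearest afferents first; among those within one step of the
            # closest, the least-loaded (lowest index on ties) wins, so
            # forced appends stay balanced across the population
            near = np.flatnonzero(dists <= dists.min() + 1)
            loads = np.array([len(fields[i]) for i in near])
            winner = int(near[np.argmin(loads)])
            fields[winner].append(int(taxel))
            covered[taxel] = True

    weights = np.zeros((n, N_TAXELS))
    for i, members in enumerate(fields):
        lam = max(1.0, np.sqrt(len(members)) / 2.0)
        gain = min(1.0, len(members) / 4.0)
        for taxel in members:
            d = _chebyshev(taxel, int(centers[i]))
            u = rng.uniform(0.5, 1.0)
            weights[i, taxel] = max(MIN_WEIGHT, gain * u * np.exp(-d / lam))

    types = ["SA-I"] * n_sa1 + ["RA-I"] * n_ra1
    return InnervationMap(weights, types, target_mean, seed)


def mean_innervated_taxels(imap: InnervationMap) -> float:
    """Mean number of positively weighted taxels per afferent row."""
    return float(np.mean(np.count_nonzero(imap.weights > 0, axis=1)))


def dynamic_component(taxels: np.ndarray, sample_rate: float) -> np.ndarray:
    """Extract the dynamic (rapidly adapting) component of taxel signals.

    First temporal difference scaled to a derivative, band-passed 5-250 Hz
    and normalised by ``2 * pi * RA_REFERENCE_HZ`` so amplitude grows
    linearly with vibration frequency around the reference.  Input shape
    (64, T); output the same.
    """
    deriv = np.gradient(taxels, 1.0 / sample_rate, axis=-1)
    n = taxels.shape[-1]
    if n > 30 and sample_rate > 2.0 * RA_BAND_HZ[1]:
        sos = signal.butter(RA_BAND_ORDER, RA_BAND_HZ, "bandpass",
                            fs=sample_rate, output="sos")
        deriv = signal.sosfiltfilt(sos, deriv, axis=-1)
    return deriv / (2.0 * np.pi * RA_REFERENCE_HZ)


def apply_innervation(imap: InnervationMap, recording: SensorRecording,
                      ra_pathway: str = "dynamic") -> AfferentDrive:
    """Project a recording's taxel signals through the receptive fields.

    SA-I rows receive the weighted raw taxel sum (static pressure); RA-I
    rows receive the weighted dynamic component (``ra_pathway='dynamic'``,
    default) or the same raw sum (``'raw'``) for ablation studies.  Linear
    in the taxel signals.
    """
    if ra_pathway not in ("dynamic", "raw"):
        raise ValueError("ra_pathway must be 'dynamic' or 'raw'")
    taxels = recording.taxels_flat()
    if taxels.shape[0] != N_TAXELS:
        raise ValueError("recording does not have 64 taxel channels")
    static = imap.weights @ taxels
    currents = static
    if ra_pathway == "dynamic":
        ra_rows = imap.rows_of_type("RA-I")
        if ra_rows.any():
            dyn = dynamic_component(taxels, recording.sample_rate)
            currents = static.copy()
            currents[ra_rows] = imap.weights[ra_rows] @ dyn
    return AfferentDrive(currents, list(imap.afferent_types),
                         recording.sample_rate)
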