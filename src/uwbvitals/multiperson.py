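"""Multi-person detection: threshold-crossing TOA and beamforming azimuth.

The TOA stage runs CLEAN-style iterative peak extraction on the
instantaneous power p = r^2 of a fast-time profile (by default the
slow-time standard deviation of the clutter-suppressed matrix, since
persons are where slow-time variance lives).  Each iteration takes the
global maximum of a "dirty map", stops below a power threshold, zeroes a
guard window around the candidate, and stores the candidate only if it is
the maximum of the *original* power over its own guard window -- candidates
that are sidelobes of an already-extracted cluster are discarded.  The
number of stored TOAs is the number of detected persons.

Azimuth comes from conventional (delay-and-sum) beamforming over a planar
array: per-element unit-modulus steering phases
exp(-j 2 pi (dx cos(theta) sin(phi) + dy cos(theta) cos(phi)) / lambda_c)
are correlated against per-element complex channel samples at a person's
range gate, and the (theta, phi) grid argmax is the direction estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import C

__all__ = [
    "TOAConfig",
    "ArrayGeometry",
    "PersonRecord",
    "NonConvergenceError",
    "default_threshold",
    "toa_threshold_crossing",
    "steering_vector",
    "cbf_azimuth",
    "match_targets",
]


class NonConvergenceError(RuntimeError):
    """Raised when iterative TOA extraction exceeds its safety cap."""


@dataclass
class TOAConfig:
    """Threshold and guard extents for iterative TOA extraction."""

    thd: float
    n_left: int = 32
    n_right: int = 32
    max_iter: int = 256

    def __post_init__(self) -> None:
        if self.thd <= 0:
            raise ValueError("threshold must be positive")
        if self.n_left < 1 or self.n_right < 1:
            raise ValueError("guard extents must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def default_threshold(r: np.ndarray, factor: float = 6.0) -> float:
    """Power threshold: ``factor`` times the median instantaneous power."""
    p = np.asarray(r, dtype=float) ** 2
    med = float(np.median(p))
    if med <= 0.0:
        med = float(np.mean(p)) or 1e-30
    return factor * med


def toa_threshold_crossing(r: np.ndarray, cfg: TOAConfig) -> list[int]:
    """Iterative threshold-crossing TOA extraction on the power of ``r``.

    Returns stored TOA bin indices in extraction (descending-power) order.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("signal must be finite")
    if r.size <= cfg.n_left + cfg.n_right:
        raise ValueError("signal shorter than the guard window")
    power = r ** 2
    dirty = power.copy()
    toas: list[int] = []
    for _ in range(cfg.max_iter):
        tau = int(np.argmax(dirty))
        amp = dirty[tau]
        if amp < cfg.thd:
            return toas
        lo = max(tau - cfg.n_left, 0)
        hi = min(tau + cfg.n_right + 1, power.size)
        dirty[lo:hi] = 0.0
        # Sidelobe check: a valid peak dominates its guard window in the
        # ORIGINAL power signal; otherwise it belongs to an already
        # extracted cluster and is discarded.
        if amp < np.max(power[lo:hi]):
            continue
        toas.append(tau)
    if np.max(dirty) >= cfg.thd:
        raise NonConvergenceError(
            f"TOA extraction did not converge within {cfg.max_iter} "
            f"iterations at threshold {cfg.thd}")
    return toas


@dataclass
class ArrayGeometry:
    """Planar array: per-element (x, y) offsets (m) and carrier wavelength."""

    offsets: np.ndarray  # (E, 2)
    wavelength: float

    def __post_init__(self) -> None:
        self.offsets = np.atleast_2d(np.asarray(self.offsets, dtype=float))
        if self.offsets.shape[0] < 1 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must be an (E, 2) array with E >= 1")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @classmethod
    def planar_2x2(cls, fc: float = 7.29e9,
                   spacing: float | None = None) -> "ArrayGeometry":
        """Square 2x2 array, half-wavelength spacing by default."""
        lam = C / fc
        d = spacing if spacing is not None else lam / 2.0
        off = np.array([[0.0, 0.0], [d, 0.0], [0.0, d], [d, d]])
        return cls(offsets=off, wavelength=lam)

    @property
    def n_elements(self) -> int:
        return self.offsets.shape[0]


def steering_vector(geometry: ArrayGeometry, theta_deg: float,
                    phi_deg: float) -> np.ndarray:
    """Unit-modulus per-element phases for direction (theta, phi) in degrees.

    theta is elevation in [-90, 90], phi azimuth in [0, 360).
    """
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    dx = geometry.offsets[:, 0]
    dy = geometry.offsets[:, 1]
    arg = (dx * np.cos(th) * np.sin(ph) + dy * np.cos(th) * np.cos(ph))
    return np.exp(-1j * 2.0 * np.pi * arg / geometry.wavelength)


def cbf_azimuth(channels: np.ndarray, geometry: ArrayGeometry,
                theta_grid: np.ndarray, phi_grid: np.ndarray,
                ) -> tuple[np.ndarray, tuple[float, float]]:
    """Delay-and-sum power map over a (theta, phi) grid and its argmax.

    ``channels`` is (E,) or (E, L) complex: one sample (or short gate) per
    element.  P(theta, phi) = || sum_e conj(s_e) x_e ||^2.
    """
    x = np.asarray(channels, dtype=complex)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != geometry.n_elements:
        raise ValueError("channel count must match array elements")
    if x.shape[0] < 2:
        raise ValueError("beamforming needs at least 2 elements")
    theta_grid = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    phi_grid = np.atleast_1d(np.asarray(phi_grid, dtype=float))
    if theta_grid.size == 0 or phi_grid.size == 0:
        raise ValueError("direction grid must be nonempty")
    pmap = np.zeros((theta_grid.size, phi_grid.size))
    for i, th in enumerate(theta_grid):
        for j, ph in enumerate(phi_grid):
            s = steering_vector(geometry, th, ph)
            pmap[i, j] = float(np.sum(
                np.abs(np.conj(s) @ x) ** 2))
    i, j = np.unravel_index(np.argmax(pmap), pmap.shape)
    return pmap, (float(theta_grid[i]), float(phi_grid[j]))


@dataclass
class PersonRecord:
    """One detected person, TOA-matched to azimuth and vital estimates."""

    person_id: int
    toa_bin: int
    toa_s: float
    range_m: float
    azimuth_deg: float = float("nan")
    rr_bpm: float = float("nan")
    hr_bpm: float = float("nan")
    flags: str = ""


def match_targets(toas: list[int], tf: float,
                  azimuths: list[tuple[int, float]] | None = None,
                  vitals: dict[int, dict] | None = None,
                  gate_tolerance: int = 64) -> list[PersonRecord]:
    """Pair each TOA with the azimuth whose range gate is nearest.

    ``azimuths`` is a list of (gate_bin, azimuth_deg) detections; ``vitals``
    maps TOA bin -> dict with rr_bpm/hr_bpm.  Unmatched TOAs are flagged
    ``azimuth-unknown``, never dropped.  Output is sorted by range.
    """
    azimuths = azimuths or []
    vitals = vitals or {}
    records = []
    for toa in toas:
        az = float("nan")
        flags = ""
        if azimuths:
            gates = np.array([g for g, _ in azimuths])
            k = int(np.argmin(np.abs(gates - toa)))
            if abs(int(gates[k]) - toa) <= gate_tolerance:
                az = azimuths[k][1]
        if np.isnan(az):
            flags = "azimuth-unknown"
        v = vitals.get(toa, {})
        records.append(PersonRecord(
            person_id=0,
            toa_bin=int(toa),
            toa_s=toa * tf,
            range_m=toa * tf * C / 2.0,
            azimuth_deg=az,
            rr_bpm=float(v.get("rr_bpm", np.nan)),
            hr_bpm=float(v.get("hr_bpm", np.nan)),
            flags=flags,
        ))
    records.sort(key=lambda rec: rec.range_m)
    for i, rec in enumerate(records):
        rec.person_id = i
    return records
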