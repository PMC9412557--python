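"""Target range estimation from the clutter-suppressed echo matrix.

Two stages.  A coarse stage computes, per fast-time bin, the ratio
phi = EK / RMS of the slow-time series, where EK is the excess kurtosis
(biased 1/N moments) and RMS the root-mean-square.  Gaussian noise has
EK ~ 0 while a sinusoidally modulated echo is platykurtic (EK -> -1.5 for a
pure tone), so target bins stand out by |phi|.  A fine stage runs a
Mexican-hat continuous wavelet transform over the slow-time standard
deviation profile, restricted to scales whose wavelet peak frequency lies
in a fast-time analysis band (0.6-1.2 GHz by default, matched to the pulse
envelope width); the position of the largest |coefficient| is the TOA
estimate, converted to range via R = C*tau/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signal_model import C, EchoMatrix

__all__ = [
    "RangeProfile",
    "CwtSpec",
    "CwtResult",
    "DegenerateSampleError",
    "BandError",
    "excess_kurtosis",
    "kurtosis_rms_profile",
    "mexican_hat",
    "mexican_hat_scale_for_frequency",
    "cwt_refine",
]


class DegenerateSampleError(ValueError):
    """Raised for samples on which kurtosis is undefined (zero variance)."""


class BandError(ValueError):
    """Raised when no admissible CWT scale maps into the analysis band."""


def excess_kurtosis(x: np.ndarray) -> float:
    """Excess kurtosis E[(x-m)^4]/E[(x-m)^2]^2 - 3 with biased (1/N) moments."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise DegenerateSampleError(f"need at least 4 samples, got {x.size}")
    if np.var(x) == 0.0:
        raise DegenerateSampleError("zero-variance sample")
    return float(stats.kurtosis(x, fisher=True, bias=True))


@dataclass
class RangeProfile:
    """phi = EK/RMS per fast-time bin, with degenerate bins flagged."""

    phi: np.ndarray
    flags: np.ndarray  # True where the bin was degenerate (phi forced to 0)
    tf: float

    @property
    def bin_axis(self) -> np.ndarray:
        return np.arange(self.phi.size) * self.tf

    @property
    def range_axis(self) -> np.ndarray:
        return self.bin_axis * C / 2.0

    def candidate_bins(self, n_mad: float = 3.0) -> np.ndarray:
        """Bins whose |phi| exceeds median + n_mad * MAD of |phi|."""
        a = np.abs(self.phi)
        med = np.median(a)
        mad = np.median(np.abs(a - med))
        return np.flatnonzero(a > med + n_mad * mad)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": np.arange(self.phi.size),
            "delay_s": self.bin_axis,
            "range_m": self.range_axis,
            "phi": self.phi,
            "flagged": self.flags,
        })


def kurtosis_rms_profile(echo: EchoMatrix) -> RangeProfile:
    """Excess kurtosis per fast-time bin over the global matrix RMS.

    The RMS runs over the fast-time index, i.e. it is a single scalar
    normalization for the whole matrix; dividing each bin's EK by its own
    column RMS would boost low-energy noise bins and invert the
    discrimination.  Columns with zero variance get phi = 0 and a flag
    instead of an error.
    """
    if echo.n_frames < 4:
        raise ValueError("need at least 4 slow-time frames")
    data = echo.data
    var = data.var(axis=0)
    flags = var == 0.0
    phi = np.zeros(echo.n_bins)
    ok = ~flags
    rms = float(np.sqrt(np.mean(data ** 2)))
    if np.any(ok) and rms > 0.0:
        ek = stats.kurtosis(data[:, ok], axis=0, fisher=True, bias=True)
        phi[ok] = ek / rms
    return RangeProfile(phi=phi, flags=flags, tf=echo.tf)


_MH_NORM = 2.0 / (np.sqrt(3.0) * np.pi ** 0.25)


def mexican_hat(tau) -> np.ndarray:
    """Mexican-hat (Ricker) mother wavelet, unit-energy normalization."""
    tau = np.asarray(tau, dtype=float)
    return _MH_NORM * (1.0 - tau ** 2) * np.exp(-(tau ** 2) / 2.0)


def mexican_hat_scale_for_frequency(f_hz: float, tf: float) -> float:
    """Scale (in samples) whose wavelet spectral peak sits at ``f_hz``.

    The Mexican hat's spectrum peaks at omega = sqrt(2)/a, i.e.
    f = sqrt(2) / (2 pi a Tf) for unit-spaced samples of interval Tf.
    """
    return float(np.sqrt(2.0) / (2.0 * np.pi * f_hz * tf))


@dataclass
class CwtSpec:
    """Analysis band (fast-time Hz) and scale count for the CWT stage."""

    f_lo: float = 0.6e9
    f_hi: float = 1.2e9
    n_scales: int = 16

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if self.n_scales < 1:
            raise ValueError("need at least one scale")

    def scales(self, tf: float) -> np.ndarray:
        """Scales (samples, ascending) spanning [f_lo, f_hi]."""
        freqs = np.geomspace(self.f_lo, self.f_hi, self.n_scales)
        s = np.array([mexican_hat_scale_for_frequency(f, tf) for f in freqs])
        return np.sort(s)


@dataclass
class CwtResult:
    """Fine TOA estimate and the coefficient plane that produced it."""

    bin: int
    tau_s: float
    range_m: float
    scales: np.ndarray
    coefficients: np.ndarray  # (n_scales, n_bins) CWT magnitude plane


def _cwt_row(row: np.ndarray, scale: float) -> np.ndarray:
    """Discrete CWT at one scale: a^{-1/2} sum_n T(n) psi((n - b)/a)."""
    half = int(np.ceil(5.0 * scale))
    k = np.arange(-half, half + 1)
    kern = mexican_hat(k / scale) / np.sqrt(scale)
    # psi is even, so correlation == convolution
    return np.convolve(row, kern, mode="same")


def cwt_refine(row: np.ndarray, tf: float,
               spec: CwtSpec | None = None,
               center: int | None = None,
               halfwidth: int | None = None) -> CwtResult:
    """Locate the echo by the peak |CWT coefficient| over the scale plane.

    ``row`` is a fast-time signal (typically the slow-time standard
    deviation profile).  If ``center``/``halfwidth`` are given the argmax is
    restricted to that window of fast-time bins, which is how per-person
    refinement around a coarse TOA works.
    """
    spec = spec or CwtSpec()
    row = np.asarray(row, dtype=float)
    if not np.all(np.isfinite(row)):
        raise ValueError("row must be finite")
    scales = spec.scales(tf)
    if scales.size == 0 or scales.max() < 1e-9:
        raise BandError("no admissible scales map into the analysis band")
    plane = np.abs(np.stack([_cwt_row(row, a) for a in scales]))
    search = plane
    offset = 0
    if center is not None:
        hw = halfwidth if halfwidth is not None else int(np.ceil(5 * scales.max()))
        lo = max(center - hw, 0)
        hi = min(center + hw + 1, row.size)
        search = plane[:, lo:hi]
        offset = lo
    _, b = np.unravel_index(np.argmax(search), search.shape)
    b = int(b) + offset
    return CwtResult(bin=b, tau_s=b * tf, range_m=b * tf * C / 2.0,
                     scales=scales, coefficients=plane)
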