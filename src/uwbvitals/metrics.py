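"""Evaluation arithmetic: spectral SNR, relative error, Bland-Altman limits.

The SNR of a vital-sign spectrum is the power in a band of half-width B
around the detected peak over the remaining power inside the physiological
bands, in dB.  The relative error is the mean absolute fractional deviation
from a reference, in percent.  Bland-Altman agreement between two paired
rate measurements reports the mean difference and the limits of agreement
mean +/- 1.96 * SD (sample SD, denominator n-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SNRConfig",
    "BlandAltmanResult",
    "vital_snr",
    "relative_error",
    "bland_altman",
    "limits_of_agreement",
]


@dataclass
class SNRConfig:
    """Peak location/width and the physiological bands for the SNR integral."""

    fp: float
    b: float = 0.05
    vr: tuple[float, float] = (0.1, 0.7)
    vh: tuple[float, float] = (0.8, 2.0)

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("peak half-width must be positive")


def _band_integral(freqs: np.ndarray, px: np.ndarray,
                   lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(px[mask], freqs[mask]))


def vital_snr(freqs: np.ndarray, px: np.ndarray, cfg: SNRConfig) -> float:
    """Peak-band power over remaining in-band power, in dB.

    Returns +inf when the out-of-peak power is non-positive (the
    infinite-SNR flag) rather than raising.
    """
    freqs = np.asarray(freqs, dtype=float)
    px = np.asarray(px, dtype=float)
    peak = _band_integral(freqs, px, cfg.fp - cfg.b, cfg.fp + cfg.b)
    total = (_band_integral(freqs, px, *cfg.vr)
             + _band_integral(freqs, px, *cfg.vh))
    denom = total - peak
    if denom <= 0.0:
        return float("inf")
    return 10.0 * float(np.log10(peak / denom))


def relative_error(ref: np.ndarray, meas: np.ndarray) -> float:
    """Mean of |ref - meas| / ref in percent."""
    ref = np.asarray(ref, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if ref.shape != meas.shape:
        raise ValueError("reference and measurement must have equal length")
    if np.any(ref <= 0):
        raise ValueError("reference entries must be positive")
    return float(np.mean(np.abs(ref - meas) / ref) * 100.0)


@dataclass
class BlandAltmanResult:
    """Agreement statistics between two paired rate measurements (bpm)."""

    mean_diff: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int
    means: np.ndarray = field(default_factory=lambda: np.array([]))
    diffs: np.ndarray = field(default_factory=lambda: np.array([]))


def limits_of_agreement(mean_diff: float, sd: float) -> tuple[float, float]:
    """(lower, upper) = mean_diff -/+ 1.96 * sd."""
    return mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements: d = a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = limits_of_agreement(mean_diff, sd)
    return BlandAltmanResult(
        mean_diff=mean_diff, sd=sd, loa_lower=lo, loa_upper=hi,
        n=a.size, means=(a + b) / 2.0, diffs=d)
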