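"""CIR-SS: smoothing-spline separation of respiration and heartbeat.

The slow-time series at a person's fast-time bin is dominated by the large,
smooth respiration motion; the heartbeat rides on top at roughly ten times
smaller displacement, and the respiration harmonics (3rd/4th) fall right in
the heart-rate band.  Fitting a penalized cubic smoothing spline

    min_f  sum_i (z(t_i) - f(t_i))^2 + lambda * Int f''(t)^2 dt

captures the respiration waveform; the residual z - f_hat is taken as the
heartbeat channel.  The penalty acts as a fourth-order low-pass whose
cutoff is set by lambda; by default lambda is chosen per window by
generalized cross-validation (GCV).

Rates are read off zero-padded FFT magnitude spectra restricted to
physiological bands (respiration 0.1-0.7 Hz, heartbeat 0.8-2.0 Hz by
default), with 3-point parabolic peak interpolation, and reported in
breaths/beats per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.interpolate import BSpline

__all__ = [
    "SplineFit",
    "VitalEstimate",
    "CirssConfig",
    "WindowMismatchError",
    "fit_smoothing_spline",
    "smoother_matrix",
    "extract_heartbeat",
    "estimate_rate",
    "pick_rate_from_spectrum",
    "rate_spectrum",
    "select_lambda",
    "separate_vitals",
]

DEFAULT_LAMBDA_GRID = np.logspace(-4.0, 4.0, 17)


class WindowMismatchError(ValueError):
    """Raised when a residual is requested for a different window than the fit."""


def _basis(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with one interior knot per sample.

    Returns (knot vector, dense design matrix of shape (n, n+2)).
    """
    t = np.asarray(times, dtype=float)
    kn = np.concatenate([[t[0]] * 4, t[1:-1], [t[-1]] * 4])
    b = BSpline.design_matrix(t, kn, 3).toarray()
    return kn, b


def _penalty(kn: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Exact roughness Gram matrix A[i,j] = Int f_i'' f_j'' dt.

    Second derivatives of cubic B-splines are piecewise linear, so their
    products are piecewise quadratic and 2-point Gauss-Legendre per knot
    interval integrates them exactly.
    """
    t = np.asarray(times, dtype=float)
    nb = kn.size - 4
    lo, hi = t[:-1], t[1:]
    mid = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    g = 1.0 / np.sqrt(3.0)
    x = np.concatenate([mid - g * half, mid + g * half])
    w = np.concatenate([half, half])
    d2 = BSpline(kn, np.eye(nb), 3)(x, nu=2)
    return d2.T @ (w[:, None] * d2)


@dataclass
class SplineFit:
    """A penalized cubic-spline fit of one slow-time window."""

    times: np.ndarray
    data: np.ndarray
    lam: float
    knots: np.ndarray
    coefficients: np.ndarray
    fitted: np.ndarray

    @property
    def residual(self) -> np.ndarray:
        return self.data - self.fitted


def fit_smoothing_spline(z: np.ndarray, lam: float,
                         times: np.ndarray | None = None,
                         ts: float = 1.0) -> SplineFit:
    """Fit the roughness-penalized cubic spline to one window.

    Solves (B'B + lam*A) c = B'z with B the B-spline design matrix and A
    the exact curvature Gram matrix.  lam = 0 interpolates (minimum-norm
    coefficients); lam -> infinity converges to the least-squares line
    (the null space of the curvature penalty).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size < 4:
        raise ValueError("window must be a 1-D series of length >= 4")
    if lam < 0:
        raise ValueError("smoothing parameter must be non-negative")
    t = (np.arange(z.size) * ts) if times is None else np.asarray(times, float)
    if t.size != z.size:
        raise ValueError("times and data must have equal length")
    kn, b = _basis(t)
    if lam == 0.0:
        coef, *_ = np.linalg.lstsq(b, z, rcond=None)
    else:
        a = _penalty(kn, t)
        coef = np.linalg.solve(b.T @ b + lam * a, b.T @ z)
    return SplineFit(times=t, data=z, lam=lam, knots=kn,
                     coefficients=coef, fitted=b @ coef)


def smoother_matrix(times: np.ndarray, lam: float) -> np.ndarray:
    """Hat matrix H with fitted = H z; eigenvalues lie in [0, 1]."""
    t = np.asarray(times, dtype=float)
    kn, b = _basis(t)
    if lam == 0.0:
        return b @ np.linalg.pinv(b)
    a = _penalty(kn, t)
    return b @ np.linalg.solve(b.T @ b + lam * a, b.T)


def extract_heartbeat(y: np.ndarray, fit: SplineFit) -> np.ndarray:
    """Heartbeat channel: the window minus its respiration spline fit."""
    y = np.asarray(y, dtype=float)
    if y.size != fit.fitted.size:
        raise WindowMismatchError(
            f"series of length {y.size} does not match fit window of "
            f"length {fit.fitted.size}")
    return y - fit.fitted


def rate_spectrum(series: np.ndarray, ts: float,
                  pad_factor: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded FFT magnitude spectrum of a slow-time series."""
    series = np.asarray(series, dtype=float)
    n = sp_fft.next_fast_len(pad_factor * series.size)
    mag = np.abs(np.fft.rfft(series - series.mean(), n=n))
    freqs = np.fft.rfftfreq(n, d=ts)
    return freqs, mag


def _parabolic_peak(freqs: np.ndarray, mag: np.ndarray, p: int) -> float:
    f_peak = freqs[p]
    if 0 < p < freqs.size - 1:
        ym, y0, yp = mag[p - 1], mag[p], mag[p + 1]
        denom = ym - 2.0 * y0 + yp
        if denom != 0.0:
            shift = 0.5 * (ym - yp) / denom
            f_peak = freqs[p] + np.clip(shift, -0.5, 0.5) * (freqs[1] - freqs[0])
    return float(f_peak)


def estimate_rate(series: np.ndarray, ts: float,
                  band_hz: tuple[float, float],
                  exclude_harmonics_of: float | None = None,
                  search_tol_hz: float = 0.045,
                  mask_tol_hz: float = 0.025,
                  floor_ratio: float = 6.0,
                  min_global_ratio: float = 0.15,
                  prefer_subharmonic: bool = False,
                  subharmonic_ratio: float = 0.25) -> float:
    """Peak frequency in ``band_hz`` of the series spectrum, in per-minute units.

    Uses 3-point parabolic interpolation around the in-band magnitude peak.

    If ``exclude_harmonics_of`` is a fundamental frequency (Hz), the actual
    spectral peak nearest each integer multiple of it (within
    ``search_tol_hz``) is masked to ``mask_tol_hz`` half-width while
    searching: respiration harmonics fall inside the heart-rate band and
    would otherwise be picked.  The best unmasked peak is accepted when it
    stands clear of the noise floor (``floor_ratio`` times the median
    in-band magnitude) and is not vanishingly small next to the global
    peak (``min_global_ratio``); otherwise the global peak wins -- when
    the heartbeat coincides exactly with a harmonic, the merged line is
    the only physical line in the band and everything outside the mask is
    noise near the floor.

    ``prefer_subharmonic`` guards against octave errors on the slow channel:
    if half the peak frequency lies in band and carries at least
    ``subharmonic_ratio`` of the peak magnitude, the subharmonic is taken
    as the fundamental (a high-pass-attenuated fundamental can fall below
    its own second harmonic).
    """
    lo, hi = band_hz
    nyq = 0.5 / ts
    if not 0 <= lo < hi:
        raise ValueError("band must satisfy 0 <= lo < hi")
    if hi > nyq * (1 + 1e-9):
        raise ValueError(
            f"band upper edge {hi} Hz exceeds Nyquist {nyq:.3f} Hz")
    series = np.asarray(series, dtype=float)
    if series.size * ts * (hi - lo) < 2.0:
        raise ValueError("series too short to resolve the requested band")
    freqs, mag = rate_spectrum(series, ts)
    return pick_rate_from_spectrum(
        freqs, mag, band_hz,
        exclude_harmonics_of=exclude_harmonics_of,
        search_tol_hz=search_tol_hz, mask_tol_hz=mask_tol_hz,
        floor_ratio=floor_ratio, min_global_ratio=min_global_ratio,
        prefer_subharmonic=prefer_subharmonic,
        subharmonic_ratio=subharmonic_ratio)


def pick_rate_from_spectrum(freqs: np.ndarray, mag: np.ndarray,
                            band_hz: tuple[float, float],
                            exclude_harmonics_of: float | None = None,
                            search_tol_hz: float = 0.045,
                            mask_tol_hz: float = 0.025,
                            floor_ratio: float = 6.0,
                            min_global_ratio: float = 0.15,
                            prefer_subharmonic: bool = False,
                            subharmonic_ratio: float = 0.25) -> float:
    """Peak picking on an already-computed magnitude spectrum (see
    :func:`estimate_rate` for the peak/mask/sub-harmonic semantics).

    Accepting a spectrum directly allows rate estimation on magnitude
    spectra summed across several fast-time bins of a range gate, which
    makes the respiration fundamental visible regardless of the carrier
    phase at any single bin.
    """
    freqs = np.asarray(freqs, dtype=float)
    mag = np.asarray(mag, dtype=float)
    lo, hi = band_hz
    df = freqs[1] - freqs[0]
    in_band = (freqs >= lo) & (freqs <= hi)
    idx = np.flatnonzero(in_band)
    p_global = idx[np.argmax(mag[idx])]
    p = p_global
    if exclude_harmonics_of is not None and exclude_harmonics_of > 0:
        f0 = exclude_harmonics_of
        masked = np.zeros(freqs.size, dtype=bool)
        for k in range(2, int(hi / f0) + 2):
            fk = k * f0
            if fk < lo - search_tol_hz or fk > hi + search_tol_hz:
                continue
            near = np.flatnonzero(np.abs(freqs - fk) <= search_tol_hz)
            if near.size == 0:
                continue
            # the local maximum nearest fk (not the largest in the window:
            # that may be a neighboring genuine line, e.g. the heartbeat)
            interior = near[(near > 0) & (near < freqs.size - 1)]
            is_peak = interior[(mag[interior] >= mag[interior - 1])
                               & (mag[interior] >= mag[interior + 1])]
            if is_peak.size:
                center = is_peak[np.argmin(np.abs(freqs[is_peak] - fk))]
            else:
                center = near[np.argmax(mag[near])]
            w = int(np.ceil(mask_tol_hz / df))
            masked[max(center - w, 0): center + w + 1] = True
            # leakage shoulders of a strong harmonic: mask bins near the
            # center that are well below it (a genuine neighboring line
            # of comparable height survives)
            ext = int(np.ceil(2.0 * search_tol_hz / df))
            region = np.arange(max(center - ext, 0),
                               min(center + ext + 1, freqs.size))
            masked[region[mag[region] < 0.5 * mag[center]]] = True
        clean = idx[~masked[idx]]
        if clean.size:
            p_clean = clean[np.argmax(mag[clean])]
            floor = np.median(mag[idx])
            if (mag[p_clean] >= floor_ratio * floor
                    and mag[p_clean] >= min_global_ratio * mag[p_global]):
                p = p_clean
    if prefer_subharmonic:
        f_half = freqs[p] / 2.0
        if f_half >= lo:
            near = np.flatnonzero(np.abs(freqs - f_half) <= search_tol_hz)
            if near.size:
                q = near[np.argmax(mag[near])]
                if mag[q] >= subharmonic_ratio * mag[p]:
                    p = q
    return 60.0 * _parabolic_peak(freqs, mag, p)


def select_lambda(z: np.ndarray, ts: float = 1.0,
                  grid: np.ndarray | None = None) -> float:
    """Choose the smoothing parameter by generalized cross-validation.

    GCV(lam) = n * RSS / (n - tr(H_lam))^2, minimized over the grid.
    """
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("candidate grid must be nonempty")
    if grid.size == 1:
        return float(grid[0])
    z = np.asarray(z, dtype=float)
    t = np.arange(z.size) * ts
    kn, b = _basis(t)
    a = _penalty(kn, t)
    btb, btz = b.T @ b, b.T @ z
    n = z.size
    best_lam, best_score = float(grid[0]), np.inf
    for lam in grid:
        if lam == 0.0:
            continue  # GCV is degenerate at interpolation (tr H = n)
        coef = np.linalg.solve(btb + lam * a, btz)
        fitted = b @ coef
        rss = float(np.sum((z - fitted) ** 2))
        tr = float(np.trace(np.linalg.solve(btb + lam * a, btb)))
        denom = n - tr
        score = n * rss / denom ** 2 if denom > 1e-9 else np.inf
        if score < best_score:
            best_lam, best_score = float(lam), score
    return best_lam


@dataclass
class VitalEstimate:
    """Per-person output record of the pipeline."""

    person_id: int
    range_m: float
    azimuth_deg: float
    rr_bpm: float
    hr_bpm: float
    rr_spectrum: tuple[np.ndarray, np.ndarray] | None = None
    hr_spectrum: tuple[np.ndarray, np.ndarray] | None = None
    snr_rr_db: float = float("nan")
    snr_hr_db: float = float("nan")
    flags: str = ""


@dataclass
class CirssConfig:
    """Windowing, bands and smoothing policy for the separation stage."""

    window_s: float = 30.0
    hop_fraction: float = 0.5
    rr_band: tuple[float, float] = (0.1, 0.7)
    hr_band: tuple[float, float] = (0.8, 2.0)
    lam: float | None = None  # None -> GCV per window
    lambda_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())


def separate_vitals(series: np.ndarray, ts: float,
                    cfg: CirssConfig | None = None,
                    rr_bpm_override: float | None = None) -> dict:
    """Windowed CIR-SS on one person's slow-time series.

    The spline is fitted window by window (smoothing parameter by GCV per
    window unless fixed in the config) and the residuals are stitched by
    overlap averaging.  The headline respiration rate comes from the full
    series spectrum (with sub-harmonic disambiguation) and the heartbeat
    rate from the full stitched residual (with respiration harmonics
    masked); per-window rates are returned for diagnostics.

    ``rr_bpm_override`` substitutes an externally determined respiration
    rate (e.g. from a range-gate-aggregated spectrum, which is robust to
    the carrier phase of the single analysis bin) for the headline RR and
    for harmonic masking.
    """
    cfg = cfg or CirssConfig()
    series = np.asarray(series, dtype=float)
    wlen = max(int(round(cfg.window_s / ts)), 8)
    wlen = min(wlen, series.size)
    hop = max(int(round(wlen * cfg.hop_fraction)), 1)
    starts = list(range(0, series.size - wlen + 1, hop)) or [0]

    rows = []
    residual_full = np.zeros_like(series)
    counts = np.zeros_like(series)
    for t0 in starts:
        z = series[t0: t0 + wlen]
        lam = cfg.lam if cfg.lam is not None else select_lambda(
            z, ts, cfg.lambda_grid)
        fit = fit_smoothing_spline(z, lam, ts=ts)
        resid = extract_heartbeat(z, fit)
        rr_w = estimate_rate(z, ts, cfg.rr_band)
        hr_w = estimate_rate(resid, ts, cfg.hr_band,
                             exclude_harmonics_of=rr_w / 60.0)
        residual_full[t0: t0 + wlen] += resid
        counts[t0: t0 + wlen] += 1.0
        rows.append({"t0_s": t0 * ts, "lambda": lam,
                     "rr_bpm": rr_w, "hr_bpm": hr_w})

    residual_full /= np.maximum(counts, 1.0)
    if rr_bpm_override is not None:
        rr_bpm = float(rr_bpm_override)
    else:
        rr_bpm = estimate_rate(series, ts, cfg.rr_band,
                               prefer_subharmonic=True)
    hr_bpm = estimate_rate(residual_full, ts, cfg.hr_band,
                           exclude_harmonics_of=rr_bpm / 60.0)
    return {
        "rr_bpm": rr_bpm,
        "hr_bpm": hr_bpm,
        "windows": rows,
        "rr_spectrum": rate_spectrum(series, ts),
        "hr_spectrum": rate_spectrum(residual_full, ts),
        "residual": residual_full,
    }
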