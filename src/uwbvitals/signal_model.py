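"""Physics-based IR-UWB echo simulation and its closed-form spectral oracle.

An impulse-radio UWB radar illuminates a scene with short Gaussian-envelope
pulses.  A breathing, beating chest at nominal distance ``d0`` modulates the
round-trip delay of its echo,

    tau_v(t) = tau0 + tau_r * sin(2*pi*fr*t) + tau_h * sin(2*pi*fh*t),

with ``tau0 = 2*d0/C``, ``tau_r = 2*Ar/C``, ``tau_h = 2*Ah/C``.  Sampling one
received waveform per slow-time frame yields a real matrix R[m, n] (slow time
x fast time).  On top of the moving echo the simulator adds static
scatterers, a linear slow-time trend, white Gaussian noise and a slowly
wandering (random-walk) clutter term -- the interference classes the
downstream suppression chain is designed to remove.

Because the delay modulation is a sum of two sinusoids, the slow-time series
at a fixed fast-time bin has a pure line spectrum at frequencies
``k*fr + l*fh`` whose weights are Bessel-series integrals over the pulse
spectrum.  :func:`analytic_spectrum` evaluates those weights by quadrature
and serves as an independent oracle for the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "C",
    "VitalSignProfile",
    "PulseSpec",
    "TimingSpec",
    "TargetPlacement",
    "StaticScatterer",
    "SceneConfig",
    "EchoMatrix",
    "TargetTruth",
    "AnalyticSpectrum",
    "InvalidTimingError",
    "SceneError",
    "frame_interval",
    "frames_in",
    "gaussian_pulse",
    "pulse_spectrum",
    "chest_delay",
    "simulate_echo",
    "simulate_array_echo",
    "analytic_spectrum",
]

#: Propagation speed used throughout (m/s).
C = 3.0e8


class InvalidTimingError(ValueError):
    """Raised for non-physical timing parameters (e.g. PRF <= 0)."""


class SceneError(ValueError):
    """Raised when a scene places a scatterer outside the fast-time window."""


@dataclass
class VitalSignProfile:
    """Chest-motion parameters of one person.

    Parameters
    ----------
    d0 : float
        Nominal antenna-chest distance in metres.
    ar, ah : float
        Peak chest displacement (m) due to respiration and heartbeat.
    fr, fh : float
        Respiration and heartbeat frequencies in Hz.
    """

    d0: float
    ar: float = 0.004
    ah: float = 0.0003
    fr: float = 0.3
    fh: float = 1.2

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError(f"d0 must be positive, got {self.d0}")
        if self.ar < 0 or self.ah < 0:
            raise ValueError("displacement amplitudes must be non-negative")
        if self.fr > 0 and self.fh > 0 and not self.fr < self.fh:
            raise ValueError("need fr < fh when both are nonzero")
        if self.ah >= self.ar > 0:
            warnings.warn(
                "heartbeat displacement >= breathing displacement is "
                "physiologically implausible",
                stacklevel=2,
            )

    @property
    def tau0(self) -> float:
        """Round-trip delay to the nominal chest position (s)."""
        return 2.0 * self.d0 / C

    @property
    def tau_r(self) -> float:
        return 2.0 * self.ar / C

    @property
    def tau_h(self) -> float:
        return 2.0 * self.ah / C


@dataclass
class PulseSpec:
    """Transmit pulse: Gaussian-envelope cosine at the carrier.

    The envelope width is set so the -10 dB *power* width of the spectrum
    equals ``bandwidth``.  Defaults follow an X4-class sensor: 7.29 GHz
    carrier, 1.4 GHz bandwidth, 23.328 GS/s receive sampling.
    """

    fc: float = 7.29e9
    bandwidth: float = 1.4e9
    fast_rate: float = 23.328e9
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.bandwidth < 2 * self.fc:
            raise ValueError("need 0 < bandwidth < 2*fc")
        if self.fast_rate <= 0:
            raise ValueError("fast_rate must be positive")

    @property
    def sigma_t(self) -> float:
        """Envelope standard deviation (s): exp(-4 pi^2 s^2 (B/2)^2) = 0.1."""
        return float(np.sqrt(np.log(10.0)) / (np.pi * self.bandwidth))

    @property
    def support_bins(self) -> int:
        """Half-width of the effective pulse support in fast-time bins."""
        return int(np.ceil(4.0 * self.sigma_t * self.fast_rate))


@dataclass
class TimingSpec:
    """Acquisition timing: segmented fast-time sweep and slow-time framing.

    ``N_seg`` samples per segment, ``n_segments`` segments per sweep, ``Na``
    averaged acquisitions per frame at pulse repetition frequency ``prf``.
    One frame then takes ``Ts = N_seg * Na / prf`` seconds.  ``window_ns``,
    if given, overrides the fast-time sample interval to
    ``window_ns * 1e-9 / N_seg`` (otherwise Tf = 1/fast_rate of the pulse).
    """

    n_seg: int = 682
    n_segments: int = 6
    na: int = 30
    prf: float = 6.0e5
    frame_count: int = 1759
    window_ns: float | None = None

    def __post_init__(self) -> None:
        if self.n_seg < 1 or self.n_segments < 1 or self.na < 1:
            raise InvalidTimingError("n_seg, n_segments, na must be >= 1")
        if self.prf <= 0:
            raise InvalidTimingError(f"PRF must be positive, got {self.prf}")
        if self.frame_count < 1:
            raise InvalidTimingError("frame_count must be >= 1")

    @property
    def fast_length(self) -> int:
        return self.n_seg * self.n_segments

    @property
    def ts(self) -> float:
        return frame_interval(self)

    def tf(self, pulse: PulseSpec) -> float:
        if self.window_ns is not None:
            return self.window_ns * 1e-9 / self.n_seg
        return 1.0 / pulse.fast_rate


def frame_interval(timing: TimingSpec) -> float:
    """Slow-time frame interval Ts = N_seg * Na / PRF in seconds."""
    if timing.prf <= 0:
        raise InvalidTimingError(f"PRF must be positive, got {timing.prf}")
    return timing.n_seg * timing.na / timing.prf


def frames_in(duration_s: float, timing: TimingSpec) -> int:
    """Number of whole frames acquired in ``duration_s`` seconds."""
    if duration_s < 0:
        raise ValueError(f"duration must be non-negative, got {duration_s}")
    return int(np.floor(duration_s / frame_interval(timing)))


@dataclass
class TargetPlacement:
    """One person in the scene: motion profile plus direction/reflectivity."""

    profile: VitalSignProfile
    azimuth_deg: float = 0.0
    elevation_deg: float = 0.0
    reflectivity: float = 1.0


@dataclass
class StaticScatterer:
    """Motionless reflector at round-trip delay ``tau`` (s), amplitude ``a``."""

    tau: float
    a: float


@dataclass
class SceneConfig:
    """Full simulation scene.

    ``trend_slope`` is the linear slow-time drift added per frame (same for
    every fast-time bin); ``awgn_sigma`` the i.i.d. Gaussian noise standard
    deviation; ``nonstat_clutter_sigma`` the per-frame step size of a
    per-bin random-walk clutter term.  ``seed`` fixes every random draw.
    """

    targets: list[TargetPlacement] = field(default_factory=list)
    statics: list[StaticScatterer] = field(default_factory=list)
    trend_slope: float = 0.0
    awgn_sigma: float = 0.0
    nonstat_clutter_sigma: float = 0.0
    seed: int = 0


@dataclass
class EchoMatrix:
    """Slow-time x fast-time real echo matrix with sampling metadata."""

    data: np.ndarray
    ts: float
    tf: float
    fc: float
    transient_frames: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("data must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("echo matrix must be finite")
        if self.ts <= 0 or self.tf <= 0:
            raise ValueError("sampling intervals must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def slow_axis(self) -> np.ndarray:
        """Slow-time stamps of each frame (s)."""
        return np.arange(self.n_frames) * self.ts

    @property
    def fast_delays(self) -> np.ndarray:
        """Round-trip delay of each fast-time bin (s)."""
        return np.arange(self.n_bins) * self.tf

    @property
    def range_axis(self) -> np.ndarray:
        """One-way range of each fast-time bin (m): R = C*tau/2."""
        return self.fast_delays * C / 2.0

    def with_data(self, data: np.ndarray, *, ts: float | None = None,
                  transient_frames: int | None = None) -> "EchoMatrix":
        """Copy metadata onto a transformed matrix."""
        return EchoMatrix(
            data=data,
            ts=self.ts if ts is None else ts,
            tf=self.tf,
            fc=self.fc,
            transient_frames=(self.transient_frames
                              if transient_frames is None else transient_frames),
        )


@dataclass
class TargetTruth:
    """Ground truth for one simulated person."""

    person_id: int
    range_m: float
    bin: int
    azimuth_deg: float
    fr_hz: float
    fh_hz: float


def gaussian_pulse(t: np.ndarray, pulse: PulseSpec) -> np.ndarray:
    """Gaussian-envelope cosine s(t) = A exp(-t^2/(2 sigma^2)) cos(2 pi fc t)."""
    t = np.asarray(t, dtype=float)
    s = pulse.sigma_t
    return pulse.amplitude * np.exp(-(t ** 2) / (2.0 * s * s)) * np.cos(
        2.0 * np.pi * pulse.fc * t)


def pulse_spectrum(f: np.ndarray, pulse: PulseSpec) -> np.ndarray:
    """Analytic Fourier transform U(f) of :func:`gaussian_pulse` (real, even)."""
    f = np.asarray(f, dtype=float)
    s = pulse.sigma_t
    g = pulse.amplitude * s * np.sqrt(2.0 * np.pi) / 2.0
    return g * (np.exp(-2.0 * np.pi ** 2 * s * s * (f - pulse.fc) ** 2)
                + np.exp(-2.0 * np.pi ** 2 * s * s * (f + pulse.fc) ** 2))


def chest_delay(t, profile: VitalSignProfile):
    """Round-trip delay tau_v(t) of the moving chest (s)."""
    t = np.asarray(t, dtype=float)
    return (profile.tau0
            + profile.tau_r * np.sin(2.0 * np.pi * profile.fr * t)
            + profile.tau_h * np.sin(2.0 * np.pi * profile.fh * t))


def _target_columns(echo: np.ndarray, placement: TargetPlacement,
                    pulse: PulseSpec, tf: float, t_slow: np.ndarray,
                    extra_delay: float, index: int) -> None:
    """Add one moving target's delayed pulses to ``echo`` in place.

    Only the fast-time columns inside the pulse support around the target
    bin are touched (the pulse is effectively zero elsewhere).
    """
    prof = placement.profile
    tau_v = chest_delay(t_slow, prof) + extra_delay
    n_bins = echo.shape[1]
    center = (prof.tau0 + extra_delay) / tf
    sway = int(np.ceil((prof.tau_r + prof.tau_h + abs(extra_delay)) / tf)) + 2
    half = pulse.support_bins + sway
    lo = int(np.floor(center)) - half
    hi = int(np.ceil(center)) + half + 1
    if center < 0 or center > n_bins - 1:
        raise SceneError(
            f"target {index} at delay {prof.tau0 + extra_delay:.3e} s falls "
            f"outside the fast-time window of {n_bins} bins")
    lo = max(lo, 0)
    hi = min(hi, n_bins)
    bins = np.arange(lo, hi) * tf
    echo[:, lo:hi] += placement.reflectivity * gaussian_pulse(
        bins[None, :] - tau_v[:, None], pulse)


def _static_row(n_bins: int, statics: Sequence[StaticScatterer],
                pulse: PulseSpec, tf: float) -> np.ndarray:
    row = np.zeros(n_bins)
    for i, sc in enumerate(statics):
        b = sc.tau / tf
        if b < 0 or b > n_bins - 1:
            raise SceneError(
                f"static scatterer {i} at delay {sc.tau:.3e} s falls outside "
                f"the fast-time window of {n_bins} bins")
        lo = max(int(b) - pulse.support_bins, 0)
        hi = min(int(b) + pulse.support_bins + 1, n_bins)
        bins = np.arange(lo, hi) * tf
        row[lo:hi] += sc.a * gaussian_pulse(bins - sc.tau, pulse)
    return row


def simulate_echo(scene: SceneConfig, pulse: PulseSpec | None = None,
                  timing: TimingSpec | None = None,
                  ) -> tuple[EchoMatrix, list[TargetTruth]]:
    """Simulate one receive channel.

    Returns the echo matrix and the ground-truth record of every target
    (true fast-time bin, range, frequencies).  Deterministic under
    ``scene.seed``.
    """
    pulse = pulse or PulseSpec()
    timing = timing or TimingSpec()
    if not scene.targets and not scene.statics:
        raise SceneError("scene needs at least one target or static scatterer")
    tf = timing.tf(pulse)
    m, n = timing.frame_count, timing.fast_length
    t_slow = np.arange(m) * timing.ts
    rng = np.random.default_rng(scene.seed)

    echo = np.zeros((m, n))
    for i, placement in enumerate(scene.targets):
        _target_columns(echo, placement, pulse, tf, t_slow, 0.0, i)
    echo += _static_row(n, scene.statics, pulse, tf)[None, :]
    if scene.trend_slope:
        echo += scene.trend_slope * np.arange(m)[:, None]
    if scene.awgn_sigma:
        echo += rng.normal(0.0, scene.awgn_sigma, size=(m, n))
    if scene.nonstat_clutter_sigma:
        echo += np.cumsum(
            rng.normal(0.0, scene.nonstat_clutter_sigma, size=(m, n)), axis=0)

    truth = [
        TargetTruth(
            person_id=i,
            range_m=p.profile.d0,
            bin=int(round(p.profile.tau0 / tf)),
            azimuth_deg=p.azimuth_deg,
            fr_hz=p.profile.fr,
            fh_hz=p.profile.fh,
        )
        for i, p in enumerate(scene.targets)
    ]
    return EchoMatrix(echo, ts=timing.ts, tf=tf, fc=pulse.fc), truth


def element_extra_delay(offset_xy: tuple[float, float], azimuth_deg: float,
                        elevation_deg: float) -> float:
    """One-way geometric delay of an array element for a far-field target.

    Matches the conventional-beamforming phase convention: the path
    difference is ``dx*cos(theta)*sin(phi) + dy*cos(theta)*cos(phi)``.
    """
    th = np.deg2rad(elevation_deg)
    ph = np.deg2rad(azimuth_deg)
    dx, dy = offset_xy
    return (dx * np.cos(th) * np.sin(ph) + dy * np.cos(th) * np.cos(ph)) / C


def simulate_array_echo(scene: SceneConfig, offsets: np.ndarray,
                        pulse: PulseSpec | None = None,
                        timing: TimingSpec | None = None,
                        ) -> tuple[list[EchoMatrix], list[TargetTruth]]:
    """Simulate every element of a planar receive array.

    ``offsets`` is an (E, 2) array of element (x, y) positions in metres.
    Each element sees each target with the geometric path-difference delay
    for the target's direction; noise is drawn independently per element but
    all elements share ``scene.seed`` deterministically.
    """
    pulse = pulse or PulseSpec()
    timing = timing or TimingSpec()
    if not scene.targets and not scene.statics:
        raise SceneError("scene needs at least one target or static scatterer")
    offsets = np.atleast_2d(np.asarray(offsets, dtype=float))
    tf = timing.tf(pulse)
    m, n = timing.frame_count, timing.fast_length
    t_slow = np.arange(m) * timing.ts
    rng = np.random.default_rng(scene.seed)

    echoes = []
    static = _static_row(n, scene.statics, pulse, tf)
    for off in offsets:
        echo = np.zeros((m, n))
        for i, placement in enumerate(scene.targets):
            extra = element_extra_delay(
                (off[0], off[1]), placement.azimuth_deg,
                placement.elevation_deg)
            _target_columns(echo, placement, pulse, tf, t_slow, extra, i)
        echo += static[None, :]
        if scene.trend_slope:
            echo += scene.trend_slope * np.arange(m)[:, None]
        if scene.awgn_sigma:
            echo += rng.normal(0.0, scene.awgn_sigma, size=(m, n))
        if scene.nonstat_clutter_sigma:
            echo += np.cumsum(
                rng.normal(0.0, scene.nonstat_clutter_sigma, size=(m, n)),
                axis=0)
        echoes.append(EchoMatrix(echo, ts=timing.ts, tf=tf, fc=pulse.fc))

    truth = [
        TargetTruth(i, p.profile.d0, int(round(p.profile.tau0 / tf)),
                    p.azimuth_deg, p.profile.fr, p.profile.fh)
        for i, p in enumerate(scene.targets)
    ]
    return echoes, truth


@dataclass
class AnalyticSpectrum:
    """Bessel-series line spectrum of the slow-time series at one bin.

    ``coefficients[(k, l)]`` is the (complex) weight of the spectral line at
    ``k*fr + l*fh`` for a bin offset ``delta = n*Tf - tau0`` from the pulse
    peak.  At ``delta = 0`` with an even real pulse all odd-order (k+l odd)
    weights vanish: motion sensitivity at the exact envelope peak is second
    order.
    """

    coefficients: dict[tuple[int, int], complex]
    fr: float
    fh: float
    delta: float = 0.0

    def line_frequency(self, k: int, l: int) -> float:
        return k * self.fr + l * self.fh

    def magnitude(self, k: int, l: int) -> float:
        return abs(self.coefficients[(k, l)])


def analytic_spectrum(profile: VitalSignProfile,
                      pulse: PulseSpec | None = None,
                      k_max: int = 2, l_max: int = 2,
                      delta: float = 0.0,
                      n_quad: int = 40001) -> AnalyticSpectrum:
    """Quadrature evaluation of the Bessel-series line weights.

    G_kl(delta) = Integral U(v) J_k(2 pi v tau_r) J_l(2 pi v tau_h)
                  exp(j 2 pi v delta) dv

    over the full real line, with U the analytic pulse spectrum.  The line
    at ``k*fr + l*fh`` in the slow-time spectrum of the simulated echo at
    bin offset ``delta`` carries weight ``|G_kl|``.
    """
    if k_max < 0 or l_max < 0:
        raise ValueError("k_max and l_max must be non-negative")
    pulse = pulse or PulseSpec()
    span = pulse.fc + 4.0 * pulse.bandwidth
    v = np.linspace(-span, span, n_quad)
    u = pulse_spectrum(v, pulse)
    phase = np.exp(1j * 2.0 * np.pi * v * delta)
    coeffs: dict[tuple[int, int], complex] = {}
    for k in range(-k_max, k_max + 1):
        jk = special.jv(k, 2.0 * np.pi * v * profile.tau_r)
        for l in range(-l_max, l_max + 1):
            jl = special.jv(l, 2.0 * np.pi * v * profile.tau_h)
            coeffs[(k, l)] = complex(np.trapezoid(u * jk * jl * phase, v))
    return AnalyticSpectrum(coeffs, fr=profile.fr, fh=profile.fh, delta=delta)
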