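# Methods

`uwbvitals` implements a complete processing chain for non-contact
multi-person vital-sign monitoring with impulse-radio ultra-wideband
(IR-UWB) radar, together with a physics-based echo simulator so that every
stage can be exercised and validated without hardware.

## Signal model and simulator

A person at nominal antenna–chest distance `d0` breathes and has a
heartbeat; the chest surface displacement is modelled as a sum of two
sinusoids with amplitudes `Ar` (respiration, default 4 mm) and `Ah`
(heartbeat, default 0.3 mm) at frequencies `fr` and `fh`.  The round-trip
echo delay is

    tau_v(t) = tau0 + tau_r sin(2*pi*fr*t) + tau_h sin(2*pi*fh*t),

with `tau0 = 2 d0 / C`, `tau_r = 2 Ar / C`, `tau_h = 2 Ah / C` and
`C = 3.0e8 m/s`.  The transmit pulse is a Gaussian-envelope cosine at the
carrier (7.29 GHz, 1.4 GHz −10 dB bandwidth, 23.328 GS/s receive
sampling); the envelope width follows from the bandwidth, giving an
effective support of about ±33 fast-time bins (±1.4 ns).  Sampling one
return per frame produces the real slow-time × fast-time matrix `R[m, n]`.
On top of the moving echoes the simulator adds, per the interference
classes a bench measurement contains: motionless reflectors (identical in
every frame), a linear slow-time drift, white Gaussian noise, and a
per-bin random-walk clutter term for slow non-stationary drift.  All
randomness flows from one seed; identical configurations are
bit-reproducible.

Acquisition timing follows a segmented sweep: `N_seg` samples per segment
(682), `Na` averaged acquisitions per frame (30) at a 600 kHz pulse
repetition frequency, so one frame takes `Ts = N_seg*Na/PRF = 0.0341 s`
(1759 frames in 60 s) and a six-segment sweep spans 4092 fast-time bins.
The per-segment 124 ns window sometimes quoted for this sensor class is
inconsistent with its stated sampling rate; we default to
`Tf = 1/fast_rate` and expose a `window_ns` override.

**Analytic oracle.**  Because the delay modulation is a two-tone sinusoid,
the slow-time series at a fixed fast-time bin has a pure line spectrum at
`k*fr + l*fh` whose weights are Bessel-series integrals over the pulse
spectrum `U(v)`:

    G_kl(delta) = Int U(v) J_k(2 pi v tau_r) J_l(2 pi v tau_h)
                  exp(j 2 pi v delta) dv,

where `delta` is the bin's offset from the envelope peak.
`analytic_spectrum` evaluates these weights by quadrature (the Gaussian
pulse spectrum is known in closed form) and the test suite checks the
simulator's DFT lines against them to 5 %.  One structural consequence
matters throughout the package: for an even pulse, all odd-order weights
(`k+l` odd) vanish at `delta = 0` — at the exact envelope peak the carrier
sits at an antinode and first-order motion sensitivity is zero.  Odd-order
content (the respiration fundamental and the heartbeat line) peaks a
quarter carrier cycle off the envelope peak; even-order harmonics peak at
the antinodes.  Which harmonics one sees therefore depends on the carrier
phase of the analysis bin, and several estimator choices below exist
precisely to cope with this.

## Clutter suppression

Four linear stages along slow time, per fast-time bin:

1. static removal — subtract each bin's slow-time mean (default) or the
   single grand mean (`static_mode="grand"`, the literal scalar form);
2. linear-trend removal — project onto the orthogonal complement of
   `span{ramp, ones}` (equivalently a per-column least-squares line fit,
   cross-checked against `scipy.signal.detrend`);
3. a fifth-order Butterworth high-pass (normalized cutoff 0.0212) and
   low-pass (0.1036) pair.  Cutoffs are fractions of the slow-time
   Nyquist `1/(2 Ts)` = 14.66 Hz, giving a ≈0.31–1.52 Hz passband that
   covers respiration harmonics and the heartbeat.  Filtering is causal
   with zero initial conditions; the start-up transient length (three
   time constants of the slowest pole, ≈150 frames) is carried as
   metadata rather than dropped;
4. a length-7 non-overlapping block average, decimating the frame rate to
   ≈4.19 Hz (Nyquist 2.09 Hz, just above the 2.0 Hz top of the heart
   band) and improving SNR by ≈7×.

The whole chain is linear to machine precision, which the suite asserts.
A consequence of stage 3 worth noting: a 12 bpm (0.2 Hz) respiration
fundamental sits below the high-pass corner and is attenuated ≈7× in
amplitude, which is why the rate estimator needs sub-harmonic
disambiguation (below).

## Range estimation

A coarse statistic and a fine localizer.

*Coarse:* per fast-time bin, the excess kurtosis (biased 1/N moments) of
the slow-time series divided by the global matrix RMS.  A sinusoidally
modulated echo is platykurtic (EK → −1.5 for a clean tone) while Gaussian
noise has EK ≈ 0 with a heavy **positive** sampling tail, so target
clusters appear as sustained negative-EK plateaus spanning the pulse
support.  The statistic localizes to the cluster, not to a bin — at the
default motion amplitude the series contains several harmonics and its EK
plateaus near −0.6 over ±33 bins — so the profile is used for gating
(|φ| above median + 3·MAD) and diagnostics, never as the final range.

*Fine:* a continuous wavelet transform of the slow-time standard-deviation
profile with the Mexican-hat mother wavelet, over scales whose spectral
peak (`f = sqrt(2)/(2 pi a Tf)`) lies in a 0.6–1.2 GHz fast-time band
matched to the pulse envelope width.  The position of the largest
|coefficient| over the scale–translation plane is the TOA; range is
`C*tau/2`.  On seeded scenes the refined range lands within one fast-time
bin (≈6 mm) of the truth.  scipy removed its `cwt`; the transform is the
direct short convolution per scale.

## Multi-person detection

TOA extraction is CLEAN-style iterative peak removal on the instantaneous
power of the std profile: take the global maximum of a dirty map, stop
below a threshold (default 6× the median power), zero a guard window
(default the pulse support, ±33 bins), and store the candidate only if it
dominates the *original* power over its own guard window — candidates that
are sidelobes of an already-extracted cluster are discarded.  For
symmetric guards this is provably equivalent to "all guard-window local
maxima above the threshold, in descending power order", which the suite
verifies against a brute-force oracle on 200 random instances.

Azimuth uses conventional delay-and-sum beamforming over a 2×2 planar
array (half-wavelength spacing at 7.29 GHz by default).  Per-element
complex channel samples are taken from the analytic signal of the
slow-time-mean fast-time row at the person's range gate; the steering
phase is `exp(-j 2 pi (dx cos(theta) sin(phi) + dy cos(theta) cos(phi)) /
lambda_c)` and the grid argmax of the beamformed power is the direction
estimate (1° grid, ≈1° accuracy on simulated scenes).  Detections are
matched to TOAs by nearest range gate; unmatched TOAs are flagged, never
dropped.

## CIR-SS: smoothing-spline separation

The slow-time series at a person's bin is dominated by respiration; the
heartbeat is an order of magnitude smaller and the 2nd–4th respiration
harmonics fall inside the heart-rate band.  The separation fits a
penalized cubic smoothing spline

    min_f  sum_i (z(t_i) - f(t_i))^2 + lambda * Int f''(t)^2 dt

with a cubic B-spline basis (one interior knot per sample, n+2 basis
functions), the curvature Gram matrix integrated exactly by two-point
Gauss–Legendre per knot interval, and the normal equations
`(B'B + lambda A) c = B'z`.  At `lambda = 0` the fit interpolates
(minimum-norm coefficients); as `lambda → ∞` it converges to the
least-squares line (the penalty's null space); the smoother matrix has
eigenvalues in [0, 1] with trace monotone in `lambda`.  Because the
minimizer of the same functional over all twice-differentiable functions
is the natural cubic smoothing spline, which lies in our basis span,
`scipy.interpolate.make_smoothing_spline` with the same `lambda` is an
exact independent oracle, used in tests only.  The spline acts as a
fourth-order low-pass whose cutoff is set by `lambda`; the residual
`z − f̂` is the heartbeat channel.

`lambda` is chosen per 30 s window (50 % hop) by generalized
cross-validation, `GCV = n*RSS/(n − tr H)^2`, over a log grid
`1e-4 … 1e4`; a fixed value can be configured for reproducibility.
Residuals are stitched by overlap averaging, and the headline rates are
read from full-record spectra (zero-padded FFT, 3-point parabolic peak
interpolation, reported as 60·f in per-minute units).

**Rate-picking rules.**  Several deliberate estimator choices handle the
carrier-phase and harmonic structure described above; all were fixed
against seeded simulations during development:

- *Gate-aggregated respiration.*  RR is picked from the magnitude
  spectrum summed over every bin of the person's range gate.  At any one
  bin the fundamental can be carrier-phase-suppressed (odd-order); summed
  across the gate's mixed phases it is always visible.
- *Sub-harmonic preference.*  If half the RR peak frequency carries at
  least 25 % of the peak magnitude, the half frequency is taken as the
  fundamental: a slow fundamental attenuated by the 0.31 Hz high-pass can
  fall below its own second harmonic.
- *Analysis-bin choice.*  The separation runs on the gate bin whose
  spectrum carries the strongest respiration-fundamental line.  The
  heartbeat line is also odd-order, so it is most visible at exactly
  those bins.
- *Harmonic-aware heart peak.*  In the residual's 0.8–2.0 Hz band, the
  local maximum nearest each integer multiple of the estimated RR is
  masked (±0.025 Hz), together with any nearby bins below half that
  harmonic's height (leakage shoulders).  The best unmasked peak is
  accepted if it stands at least 6× above the median in-band magnitude;
  otherwise the global in-band peak wins.  The fallback matters when the
  heartbeat coincides exactly with a harmonic: the merged line is then
  the only physical line in the band and everything else is noise.

## Evaluation metrics

Spectral SNR integrates the power in a ±B band (default B = 0.05 Hz)
around the detected peak against the remaining power inside the
physiological bands (respiration 0.1–0.7 Hz, heartbeat 0.8–2.0 Hz), in
dB; a non-positive denominator returns +inf rather than raising.  The
relative error is the mean of |ref − meas|/ref in percent — the absolute
value is deliberate; signed errors would cancel.  Bland–Altman agreement
reports the mean paired difference, the sample SD (denominator n−1), and
limits of agreement mean ± 1.96·SD.

## Study conditions and what passing shows

The seeded suites use: one to three seated persons at 1–3 m, `Ar` = 4 mm,
`Ah` = 0.3 mm, `fr` ∈ [0.2, 0.5] Hz, `fh` ∈ [1.0, 1.7] Hz, white noise at
one tenth of the echo peak (post-chain respiration SNR ≈ 12 dB), trend
slope 1e-4/frame and random-walk clutter 1e-4/step, one 682-sample
fast-time segment (a 29 ns / 4.4 m window containing every scene) and
60 s of slow time.  The harmonic-collision scenario draws
`fr` ∈ [0.4, 0.5] Hz and pins `fh = 3 fr`, so that the 2nd respiration
harmonic also falls inside the heart band — the genuinely confounded case
the separation exists for.

Under these conditions 20/20 seeded scenes recover RR within ±1 bpm and
HR within ±2 bpm (relative errors ≈ 0.02–0.9 %), two persons 1 m apart
are both detected in 100 % of noisy trials, and ranges land within ≈6 mm.
These numbers characterize the model world, not real radar: real chests
move non-sinusoidally (intrinsic waveform harmonics), real rooms add
multipath that overlaps target gates, antennas couple, and subjects move.
The simulator models none of those, so field accuracy will be worse than
the synthetic suite suggests; what the suite does establish is the
internal consistency of every stage against independent oracles and the
separation's harmonic rejection under controlled collisions.

One study is intentionally strict and sits at its boundary: with
`fh = 3 fr` exactly, the raw band search usually locks to the merged
3rd-harmonic + heartbeat line, which *is* the true heart frequency — the
raw estimate is right for the wrong reason — so "residual strictly closer
to truth than raw" reduces to sub-resolution jitter in those seeds.  The
residual wins decisively whenever the raw peak lands on the 2nd harmonic
instead; across seed bases the strict-win fraction measures 0.75–0.80.

## Numerical choices and limitations

- Biased (1/N) moments for kurtosis; sample (n−1) SD for agreement
  limits.
- Zero-padded FFTs use `next_fast_len(8n)`; parabolic interpolation is
  clamped to ±half a grid step.
- The λ → 0 spline solve uses minimum-norm least squares (the basis is
  underdetermined by two); for λ > 0 the normal equations are
  nonsingular.
- Degenerate inputs flag rather than raise where a pipeline must survive
  them (zero-variance bins in the range profile, infinite SNR); they
  raise where silence would corrupt results (zero-variance kurtosis
  sample, single-frame static removal, unstable filters, scenes outside
  the fast-time window, non-positive reference rates).
- Beamforming assumes a far-field target and one-way geometric phase; the
  2×2 half-wavelength array has a broad beam, so azimuth accuracy is
  grid-limited (±1°) rather than aperture-limited in these scenes.
- Elevation is fixed at 0° in the shipped pipeline grid; the steering
  model supports full (θ, φ).
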