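# uwbvitals

Non-contact, multi-person vital-sign extraction from impulse-radio
ultra-wideband (IR-UWB) radar echoes — with a physics-based echo simulator
so the whole chain runs and validates without hardware.

An IR-UWB radar transmits sub-nanosecond pulses; a breathing, beating
chest at range `R` modulates the echo's round-trip delay

    tau_v(t) = 2R/C + (2Ar/C) sin(2*pi*fr*t) + (2Ah/C) sin(2*pi*fh*t),

so respiration (`fr`, amplitude `Ar` ≈ 4 mm) and heartbeat (`fh`,
`Ah` ≈ 0.3 mm) appear as low-frequency modulation along the slow-time axis
of the echo matrix `R[m, n]`.  The package is aimed at researchers in
radar-based physiological monitoring who need a testable, reproducible
reference implementation of this processing chain:

- **simulation** (`signal_model`) — parametrized scenes (targets, static
  clutter, drift, noise, non-stationary clutter) plus a closed-form
  Bessel-series line spectrum used as an independent oracle;
- **clutter suppression** (`preprocess`) — static subtraction,
  linear-trend projection, a fifth-order Butterworth band-pass pair
  (normalized cutoffs 0.0212 / 0.1036), length-7 slow-time averaging;
- **range estimation** (`range_est`) — excess-kurtosis/RMS profiling and
  Mexican-hat continuous-wavelet TOA refinement (`R = C*tau/2`);
- **multi-person detection** (`multiperson`) — CLEAN-style
  threshold-crossing TOA extraction (one detection per person) and
  conventional delay-and-sum beamforming azimuth on a 2×2 planar array;
- **CIR-SS separation** (`cirss`) — a penalized cubic smoothing spline
  `min_f sum (z_i - f(t_i))^2 + lambda * Int f''^2` captures the
  respiration waveform; the residual is the heartbeat channel; rates are
  read from band-limited spectra with harmonic-aware peak picking;
- **metrics** (`metrics`) — spectral SNR, mean absolute relative error,
  Bland–Altman limits of agreement (mean ± 1.96 SD).

## Worked example

Three seated persons at 1, 2 and 3 m, azimuths −30°/0°/+30°, simulated
for 60 s and processed end to end:

```sh
python - <<'EOF'
from uwbvitals.config import RunConfig, save_config
from uwbvitals.fixtures import scene_for_kind, fixture_timing
cfg = RunConfig()
cfg.scene = scene_for_kind("three_person", 42)
cfg.timing = fixture_timing(60.0)
cfg.array.enabled = True
cfg.seed = 42
save_config(cfg, "three_person.yaml")
EOF
uwbvitals estimate --config three_person.yaml --out demo_out
```

prints

```
person 0: range 1.00 m, azimuth -31.0 deg, RR 25.9 bpm, HR 78.0 bpm
person 1: range 2.00 m, azimuth 0.0 deg, RR 27.4 bpm, HR 89.1 bpm
person 2: range 3.00 m, azimuth 30.0 deg, RR 13.7 bpm, HR 101.0 bpm
```

Each line is one detected person: the range from the refined TOA
(`C*tau/2`; truth 1/2/3 m, recovered within ~3 mm), the beamformed
azimuth (truth −30/0/+30°, 1° grid), and the respiration / heart rates in
breaths and beats per minute.  The ground truth for this seed is RR
25.9/27.4/13.7 bpm and HR 78.4/89.3/101.0 bpm — every rate lands within
0.5 bpm.  `demo_out/` also receives `persons.csv`, the range profile, the
per-person spectra and a machine-readable run log.

The other CLI verbs: `uwbvitals simulate` writes an echo container
(HDF5: `data`, `Ts`, `Tf`, `fc`) plus a ground-truth CSV;
`uwbvitals fixtures --kind harmonic_collision` generates the named test
scenarios (`single`, `two_person`, `three_person`, `harmonic_collision`,
`noise_only`); `uwbvitals evaluate` computes Bland–Altman agreement
between two rate CSVs.

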