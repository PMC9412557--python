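"""Seeded scenario generator: the study conditions for every test.

Each *kind* defines a physical scene the way the bench experiments are
described: seated, still subjects 1-3 m from the radar, 4 mm breathing
displacement, 0.3 mm heartbeat displacement, respiration 0.2-0.5 Hz,
heartbeat 1.0-1.7 Hz, moderate indoor noise (AWGN at one tenth of the echo
peak), a small linear drift and a slow random-walk clutter term.  The
``harmonic_collision`` kind draws the respiration rate from 0.4-0.5 Hz and
pins the heartbeat to exactly three times it, so that the second
respiration harmonic also falls inside the heart-rate search band -- the
confounded case the spline separation exists for.

Acquisition uses a single 682-sample fast-time segment (a 29 ns / 4.4 m
window that contains every scene) and 60 s of slow time (1759 frames).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .echo_io import save_echo, truth_to_csv
from .signal_model import (PulseSpec, SceneConfig, StaticScatterer,
                           TargetPlacement, TimingSpec, VitalSignProfile,
                           frames_in, simulate_echo)

__all__ = ["FIXTURE_KINDS", "fixture_timing", "scene_for_kind",
           "make_fixtures"]

FIXTURE_KINDS = ("single", "two_person", "three_person",
                 "harmonic_collision", "noise_only")

#: Default motion and interference levels shared by every kind.
BREATH_AMPLITUDE_M = 0.004
HEART_AMPLITUDE_M = 0.0003
AWGN_SIGMA = 0.1
TREND_SLOPE = 1e-4
NONSTAT_SIGMA = 1e-4
RR_RANGE_HZ = (0.2, 0.5)
HR_RANGE_HZ = (1.0, 1.7)
COLLISION_RR_RANGE_HZ = (0.4, 0.5)


def fixture_timing(duration_s: float = 60.0) -> TimingSpec:
    """Single-segment acquisition covering ``duration_s`` of slow time."""
    base = TimingSpec(n_segments=1, frame_count=1)
    return TimingSpec(n_segments=1,
                      frame_count=max(frames_in(duration_s, base), 1))


def _person(rng: np.random.Generator, d0: float,
            azimuth_deg: float = 0.0,
            collision: bool = False) -> TargetPlacement:
    if collision:
        fr = rng.uniform(*COLLISION_RR_RANGE_HZ)
        fh = 3.0 * fr
    else:
        fr = rng.uniform(*RR_RANGE_HZ)
        fh = rng.uniform(*HR_RANGE_HZ)
    prof = VitalSignProfile(d0=d0, ar=BREATH_AMPLITUDE_M,
                            ah=HEART_AMPLITUDE_M, fr=fr, fh=fh)
    return TargetPlacement(profile=prof, azimuth_deg=azimuth_deg)


def scene_for_kind(kind: str, seed: int) -> SceneConfig:
    """The named scenario, fully determined by ``seed``."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    targets: list[TargetPlacement] = []
    statics = [StaticScatterer(tau=2.0 * 3.5 / 3.0e8, a=0.5)]
    if kind == "single":
        targets = [_person(rng, d0=1.0 + rng.uniform(0.0, 1.0))]
    elif kind == "two_person":
        targets = [_person(rng, 1.0, azimuth_deg=-20.0),
                   _person(rng, 2.0, azimuth_deg=20.0)]
    elif kind == "three_person":
        targets = [_person(rng, 1.0, azimuth_deg=-30.0),
                   _person(rng, 2.0, azimuth_deg=0.0),
                   _person(rng, 3.0, azimuth_deg=30.0)]
    elif kind == "harmonic_collision":
        targets = [_person(rng, d0=1.0 + rng.uniform(0.0, 1.0),
                           collision=True)]
    elif kind == "noise_only":
        statics.append(StaticScatterer(tau=2.0 * 1.8 / 3.0e8, a=0.4))
    return SceneConfig(targets=targets, statics=statics,
                       trend_slope=TREND_SLOPE, awgn_sigma=AWGN_SIGMA,
                       nonstat_clutter_sigma=NONSTAT_SIGMA, seed=seed)


def make_fixtures(kind: str, seed: int, out_dir: str | Path,
                  duration_s: float = 60.0) -> dict[str, Path]:
    """Write the echo container and ground-truth CSV for one scenario."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene = scene_for_kind(kind, seed)
    pulse = PulseSpec()
    timing = fixture_timing(duration_s)
    echo, truth = simulate_echo(scene, pulse, timing)
    echo_path = out_dir / f"{kind}_seed{seed}.h5"
    truth_path = out_dir / f"{kind}_seed{seed}_truth.csv"
    save_echo(echo_path, echo)
    truth_to_csv(truth, truth_path)
    return {"echo": echo_path, "truth": truth_path}
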