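"""Shared fixtures: seeded scenario studies reused across test modules.

The heavier studies (20-scene recovery suite, harmonic-collision suite) are
computed once per session and shared, keeping the suite fast while letting
several tests assert different properties of the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from uwbvitals.cirss import estimate_rate
from uwbvitals.config import RunConfig
from uwbvitals.fixtures import fixture_timing, scene_for_kind
from uwbvitals.pipeline import person_vitals, run_pipeline
from uwbvitals.preprocess import suppress_clutter
from uwbvitals.signal_model import PulseSpec, simulate_echo

DEFAULT_SUITE_SEED = 2000
COLLISION_SUITE_SEED = 1000
N_SCENES = 20


def run_single_scene(kind: str, seed: int) -> dict:
    """Simulate one single-person scene and extract truth + estimates."""
    scene = scene_for_kind(kind, seed)
    pulse = PulseSpec()
    timing = fixture_timing(60.0)
    echo, truth = simulate_echo(scene, pulse, timing)
    post = suppress_clutter(echo)
    std = post.data.std(axis=0)
    toa_bin = int(std.argmax())
    guard = pulse.support_bins
    res = person_vitals(post, toa_bin, guard)
    series = post.data[post.transient_frames:, res["bin"]]
    hr_raw = estimate_rate(series, post.ts, (0.8, 2.0))
    t = truth[0]
    return {
        "seed": seed,
        "rr_true": 60.0 * t.fr_hz,
        "hr_true": 60.0 * t.fh_hz,
        "rr_est": res["rr_bpm"],
        "hr_est": res["hr_bpm"],
        "hr_raw": hr_raw,
        "toa_bin": toa_bin,
        "true_bin": t.bin,
        "spectra": {"rr": res["rr_spectrum"], "hr": res["hr_spectrum"]},
    }


@pytest.fixture(scope="session")
def default_suite():
    """Twenty seeded single-person scenes at the default study conditions."""
    return [run_single_scene("single", DEFAULT_SUITE_SEED + i)
            for i in range(N_SCENES)]


@pytest.fixture(scope="session")
def collision_suite():
    """Twenty seeded scenes with the heartbeat pinned to 3x respiration."""
    return [run_single_scene("harmonic_collision", COLLISION_SUITE_SEED + i)
            for i in range(N_SCENES)]


@pytest.fixture(scope="session")
def three_person_result():
    """One full pipeline run (with array) on the three-person demo scene."""
    cfg = RunConfig()
    cfg.scene = scene_for_kind("three_person", 42)
    cfg.timing = fixture_timing(60.0)
    cfg.array.enabled = True
    cfg.seed = 42
    return run_pipeline(cfg), scene_for_kind("three_person", 42)
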