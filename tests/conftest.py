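"""Shared fixtures: small synthetic sessions and gaze-trace builders."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import cbdrive as cb


@pytest.fixture(scope="session")
def default_schedule():
    """One deterministic group-C schedule (72 events + segment bounds)."""
    spec = cb.ScheduleSpec(group="C", seed=1234)
    events, bounds = cb.build_schedule(spec)
    return spec, events, bounds


@pytest.fixture(scope="session")
def small_session(default_schedule):
    """One fully simulated session with gaze (shared, read-only)."""
    _, events, bounds = default_schedule
    return cb.simulate_session(
        cb.default_params(), events, bounds, seed=99, participant_id="p000", group="C"
    )


@pytest.fixture(scope="session")
def small_fixations(small_session):
    return cb.detect_fixations(small_session.gaze)


def make_gaze(t, az_deg, el_deg=None, valid=None):
    """GazeStream from azimuth/elevation series in degrees."""
    t = np.asarray(t, dtype=float)
    az = np.radians(np.asarray(az_deg, dtype=float))
    el = np.radians(np.zeros_like(az) if el_deg is None else np.asarray(el_deg, dtype=float))
    dirs = np.stack([np.sin(az) * np.cos(el), np.sin(el), np.cos(az) * np.cos(el)], axis=-1)
    v = np.ones(t.size, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return cb.GazeStream(t=t, gaze_dir=dirs, head_pos=np.zeros((t.size, 3)), valid=v)


@pytest.fixture
def gaze_builder():
    return make_gaze


def random_trace(rng, n=None, irregular=False, invalid_p=0.0):
    """Random gaze trace: jitter around a wandering target with jumps."""
    n = n or int(rng.integers(50, 400))
    dt = np.full(n, 1.0 / 120.0)
    if irregular:
        gaps = rng.random(n) < 0.02
        dt[gaps] = rng.uniform(0.06, 0.2, size=int(gaps.sum()))
    t = np.cumsum(dt)
    az = np.empty(n)
    el = np.empty(n)
    cur_az, cur_el = 0.0, 0.0
    for i in range(n):
        if rng.random() < 0.08:
            cur_az += rng.uniform(-10, 10)
            cur_el += rng.uniform(-5, 5)
        az[i] = cur_az + rng.normal(0, 0.1)
        el[i] = cur_el + rng.normal(0, 0.1)
    valid = rng.random(n) >= invalid_p
    return make_gaze(t, az, el, valid)


@pytest.fixture
def trace_builder():
    return random_trace


def recovery_params(p: float) -> cb.DriverParams:
    """Generator configuration for detection-parameter recovery studies."""
    return dataclasses.replace(
        cb.default_params().with_uniform_detection(p),
        wrong_button_p=0.0,
        false_alarm_rate_per_min=0.0,
    )
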