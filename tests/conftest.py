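"""Shared fixtures: deterministic signals and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from cmci.cop_io import CopRecording
from cmci.synthetic import SimConfig, generate_cohort

FS = 100.0


def make_time(n: int, fs: float = FS) -> np.ndarray:
    return np.arange(n) / fs


def sway_like_signal(seed: int, n: int = 3000, fs: float = FS) -> np.ndarray:
    """A deterministic CoP-like test signal: two slow tones + mild noise."""
    rng = np.random.default_rng(seed)
    t = make_time(n, fs)
    sig = (np.sin(2 * np.pi * rng.uniform(0.2, 0.6) * t + rng.uniform(0, 6))
           + 0.5 * np.sin(2 * np.pi * rng.uniform(0.8, 1.4) * t + rng.uniform(0, 6))
           + 0.3 * rng.standard_normal(n))
    return sig


def make_recording(seed: int = 0, n: int = 800, fs: float = FS,
                   group: str = "elite", condition: str = "T1",
                   subject_id: str = "S01", height: float = 68.0) -> CopRecording:
    rng = np.random.default_rng(seed)
    t = make_time(n, fs)
    x = 0.3 * np.sin(2 * np.pi * 0.4 * t) + 0.05 * rng.standard_normal(n)
    y = 0.25 * np.sin(2 * np.pi * 0.3 * t + 1.0) + 0.05 * rng.standard_normal(n)
    return CopRecording(subject_id=subject_id, group=group, condition=condition,
                        height=height, sample_rate=fs, t=t, cop_x=x, cop_y=y)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 + 3 subjects, two conditions, 8 s trials — fast end-to-end input."""
    cfg = SimConfig(n_elite=3, n_expert=3, duration=8.0,
                    conditions=("T1", "T2"), seed=42)
    recordings, manifest = generate_cohort(cfg)
    return cfg, recordings, manifest
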