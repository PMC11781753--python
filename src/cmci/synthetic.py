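"""Synthetic CoP cohorts with a controllable group complexity difference.

The generator emulates quiet-stance stabilograms: each channel is a sum of
2-4 slow sway oscillators (0.1-1.5 Hz, random phases, low-frequency-heavy
amplitudes) plus 1/f^beta Gaussian noise (beta = 2 by default — quiet-
stance CoP spectra fall off steeply above the sway band, so the noise
floor is smooth at millisecond scales), scaled so the RMS sway sits in a
plausible posturographic range (~0.1-0.7 in depending on condition).  Four standing
conditions scale sway amplitude and noise (T1 firm < T3 firm/eyes-closed <
T2 foam < T4 foam/eyes-closed).

The between-group difference is injected into signal *irregularity*, not
sway magnitude: both groups carry the same noise fraction, but the
"expert" group's noise is spectrally flattened toward white (its 1/f
exponent shrinks with ``group_complexity_gap``, reaching pure white at
gap 1) and its oscillators pick up phase jitter, while "elite" noise
keeps the steep exponent.  A Gaussian noise
marginal does not depend on its colour and every signal is rescaled to
its condition's target RMS, so moment features (mean/SD/skewness/
kurtosis) barely separate the groups while short-timescale sample
entropy — hence the complexity index — does.  At gap 0 the two groups'
generative distributions are identical.

All randomness flows through one seeded generator with per-subject
substreams (spawned by counter), so cohorts are bit-reproducible and
extensible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cop_io import CONDITIONS, CopRecording, write_recording

__all__ = ["SimConfig", "pink_noise", "generate_recording", "generate_cohort"]


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the study conditions this generator emulates: 13 elite
    vs 12 expert subjects, 30 s trials at 100 Hz across four conditions,
    and a complexity gap of 0.8 (the calibrated setting at which the
    groups differ in irregularity with a large effect size while remaining
    matched in sway magnitude).
    """

    n_elite: int = 13
    n_expert: int = 12
    duration: float = 30.0  # s
    sample_rate: float = 100.0  # Hz
    conditions: tuple[str, ...] = CONDITIONS
    group_complexity_gap: float = 0.8  # in [0, 1]
    #: per-condition sway-amplitude multipliers (target RMS = base_rms * mult)
    sway_multipliers: dict = field(default_factory=lambda: {
        "T1": 1.0, "T2": 1.4, "T3": 1.2, "T4": 1.8,
    })
    #: per-condition noise multipliers (scales pink and broadband fractions)
    noise_multipliers: dict = field(default_factory=lambda: {
        "T1": 1.0, "T2": 1.2, "T3": 1.1, "T4": 1.3,
    })
    base_rms: float = 0.25  # in, firm-surface RMS sway
    noise_fraction: float = 0.35  # noise share of oscillator RMS (both groups)
    beta_gap_gain: float = 2.0  # spectral flattening of expert noise per unit gap
    jitter_gain: float = 0.2  # expert oscillator phase jitter per unit gap
    noise_exponent: float = 2.0  # beta of the elite-group 1/f^beta noise
    height_mean_in: float = 68.8  # ~174.7 cm
    height_sd_in: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sample_rate must be an integer")
        if not 0 <= self.group_complexity_gap <= 1:
            raise ValueError("group_complexity_gap must be in [0, 1]")
        for cond in self.conditions:
            if self.sway_multipliers.get(cond, 0) <= 0 or \
                    self.noise_multipliers.get(cond, 0) <= 0:
                raise ValueError(f"multipliers for {cond} must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        d["conditions"] = tuple(d["conditions"])
        return cls(**d)


def pink_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^beta Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    y = np.fft.irfft(spec * scale, n)
    return y / np.std(y)


def _channel(cfg: SimConfig, condition: str, is_expert: bool,
             rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_samples
    fs = cfg.sample_rate
    t = np.arange(n) / fs
    gap = cfg.group_complexity_gap
    noise_mult = cfg.noise_multipliers[condition]

    k = int(rng.integers(2, 5))
    freqs = rng.uniform(0.1, 1.5, size=k)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    amps = rng.uniform(0.5, 1.0, size=k) / (1.0 + freqs)
    # phase jitter and broadband noise are always drawn (identical stream
    # consumption for both groups) and scaled by the group factor, so at
    # gap = 0 the groups are generatively identical
    group_factor = gap if is_expert else 0.0
    walk = np.cumsum(rng.standard_normal(n)) / np.sqrt(fs)
    jitter = cfg.jitter_gain * group_factor * walk
    osc = np.zeros(n)
    for j in range(k):
        osc += amps[j] * np.sin(2.0 * np.pi * freqs[j] * t + phases[j] + jitter)
    osc /= np.std(osc)

    # both groups carry the same noise *fraction*; the group difference is
    # the noise colour (expert noise is flattened toward white), so the
    # marginal distribution — and every moment feature — stays matched
    # while short-timescale irregularity grows with the gap
    beta = max(0.0, cfg.noise_exponent - cfg.beta_gap_gain * group_factor)
    noise = pink_noise(n, beta, rng)
    sig = osc + cfg.noise_fraction * noise_mult * noise

    sig -= sig.mean()
    target_rms = cfg.base_rms * cfg.sway_multipliers[condition]
    sig *= target_rms / np.sqrt(np.mean(sig**2))
    return sig


def generate_recording(group: str, condition: str, cfg: SimConfig,
                       rng: np.random.Generator, subject_id: str = "S00",
                       height: float | None = None) -> CopRecording:
    """One synthetic CoP recording for a (group, condition) cell.

    ``rng`` is consumed in a fixed order regardless of group, so identical
    generator states yield comparable draws across groups.
    """
    if height is None:
        height = float(np.clip(rng.normal(cfg.height_mean_in, cfg.height_sd_in),
                               62.0, 76.0))
    is_expert = group == "expert"
    cop_x = _channel(cfg, condition, is_expert, rng)
    cop_y = _channel(cfg, condition, is_expert, rng)
    t = np.arange(cfg.n_samples) / cfg.sample_rate
    return CopRecording(
        subject_id=subject_id, group=group, condition=condition,
        height=height, sample_rate=cfg.sample_rate,
        t=t, cop_x=cop_x, cop_y=cop_y,
    )


def generate_cohort(cfg: SimConfig, out_dir: str | Path | None = None,
                    ) -> tuple[list[CopRecording], pd.DataFrame]:
    """Full cohort: every subject under every configured condition.

    Subjects get independent substreams spawned by counter from
    ``cfg.seed`` (height drawn once per subject).  When ``out_dir`` is
    given, recordings are written as CSV files next to a ``manifest.csv``
    and a ``simconfig.json`` — the exact format :mod:`cmci.cop_io`
    consumes.
    """
    ss = np.random.SeedSequence(cfg.seed)
    subjects = ([("elite", f"E{i + 1:02d}") for i in range(cfg.n_elite)]
                + [("expert", f"X{i + 1:02d}") for i in range(cfg.n_expert)])
    children = ss.spawn(len(subjects))
    recordings: list[CopRecording] = []
    manifest_rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for (group, sid), child in zip(subjects, children):
        rng = np.random.default_rng(child)
        height = float(np.clip(rng.normal(cfg.height_mean_in, cfg.height_sd_in),
                               62.0, 76.0))
        for cond in cfg.conditions:
            rec = generate_recording(group, cond, cfg, rng,
                                     subject_id=sid, height=height)
            recordings.append(rec)
            fname = f"{sid}_{cond}.csv"
            manifest_rows.append({
                "file": fname, "subject_id": sid, "group": group,
                "condition": cond, "height": height,
                "sample_rate": cfg.sample_rate,
            })
            if out_path is not None:
                write_recording(rec, out_path / fname)
    manifest = pd.DataFrame(manifest_rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        cfg.to_json(out_path / "simconfig.json")
    return recordings, manifest
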