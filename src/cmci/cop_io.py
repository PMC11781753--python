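"""Center-of-pressure (CoP) recordings: data model, file I/O, descriptors.

A recording is a force-platform stabilogram — time plus the medial-lateral
(X) and anterior-posterior (Y) displacement of the CoP, in inches, with
(0, 0) at the subject's balance origin.  Typical trials are 30 s at 100 Hz
under four standing conditions (T1 firm surface, T2 foam, T3 firm with eyes
closed, T4 foam with eyes closed).

Two derived balance descriptors live here as well:

* ``COPLen`` — the instantaneous radial excursion ``sqrt(x**2 + y**2)``;
* ``TiltAngle`` — a body-inclination angle obtained by placing the center
  of mass at 55 % of standing height, ``arccos(COPLen / (0.55 * height))``
  in degrees.  The arccos form is the conventional definition used with
  this descriptor; an ``arcsin`` variant (which reads as inclination away
  from vertical, 0 degrees for a perfectly quiet stance) is available via
  ``mode="arcsin"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "GROUPS",
    "CONDITIONS",
    "SubjectMeta",
    "CopRecording",
    "DerivedSeries",
    "read_recording",
    "write_recording",
    "read_manifest",
    "load_cohort",
    "compute_cop_len",
    "compute_tilt_angle",
    "derive_series",
    "mean_center",
]

GROUPS = ("elite", "expert")
CONDITIONS = ("T1", "T2", "T3", "T4")

#: Center-of-mass height as a fraction of standing height.
COM_HEIGHT_FRACTION = 0.55

#: Allowed jitter of the time axis around uniform spacing, in seconds.
_UNIFORMITY_TOL_S = 1e-9

_TIME_NAMES = {"t", "time", "time_s", "seconds"}
_X_NAMES = {"x", "cop_x", "copx", "ml", "cop_ml"}
_Y_NAMES = {"y", "cop_y", "copy", "ap", "cop_ap"}


@dataclass
class SubjectMeta:
    """Metadata accompanying one recording file."""

    subject_id: str
    group: str
    condition: str
    height: float  # standing height, inches
    sample_rate: float | None = None  # Hz; inferred from timestamps if None


@dataclass
class CopRecording:
    """One subject-condition CoP time series plus metadata.

    Invariants (checked on construction): equal-length finite series of at
    least two samples, strictly increasing uniformly spaced time, positive
    sample rate and height.
    """

    subject_id: str
    group: str
    condition: str
    height: float
    sample_rate: float
    t: np.ndarray
    cop_x: np.ndarray
    cop_y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.cop_x = np.asarray(self.cop_x, dtype=float)
        self.cop_y = np.asarray(self.cop_y, dtype=float)
        n = self.t.size
        if not (self.cop_x.size == self.cop_y.size == n) or n < 2:
            raise ValidationError(
                "t, cop_x, cop_y must share one length >= 2 "
                f"(got {n}, {self.cop_x.size}, {self.cop_y.size})"
            )
        for name, arr in (("t", self.t), ("cop_x", self.cop_x), ("cop_y", self.cop_y)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValidationError(f"non-finite value in {name} at sample {bad}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise ValidationError(f"time not strictly increasing at sample {bad}")
        if np.max(np.abs(dt - np.median(dt))) > _UNIFORMITY_TOL_S:
            raise ValidationError("time axis is not uniformly spaced")
        if not self.sample_rate > 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not self.height > 0:
            raise ValidationError(f"height must be > 0, got {self.height}")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])

    @property
    def meta(self) -> SubjectMeta:
        return SubjectMeta(
            self.subject_id, self.group, self.condition, self.height, self.sample_rate
        )


@dataclass
class DerivedSeries:
    """COPLen and TiltAngle derived from one recording."""

    cop_len: np.ndarray  # inches, >= 0
    tilt_angle: np.ndarray  # degrees, in [0, 180]
    mode: str = "arccos"


def _detect_delimiter(header: str) -> str:
    return "\t" if header.count("\t") > header.count(",") else ","


def _find_column(columns: list[str], names: set[str], what: str) -> str:
    for c in columns:
        if c.strip().lower() in names:
            return c
    raise ParseError(f"no {what} column among {columns!r}")


def read_recording(path: str | Path, meta: SubjectMeta) -> CopRecording:
    """Read one delimited-text recording (CSV or TSV, auto-detected).

    The file must have a header naming time/x/y columns.  Malformed rows,
    non-monotone time or NaN samples raise :class:`ParseError` identifying
    the offending row (1-based, counting the header as row 1).  The sample
    rate is taken from ``meta`` when given (a > 0.1 % mismatch with the
    timestamps triggers a warning; the declared rate wins), otherwise it is
    inferred from the median timestep.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ParseError(f"{path}: empty file")
    sep = _detect_delimiter(header)
    try:
        # round_trip parsing so write/read is bit-exact at full precision
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # malformed rows, ragged lines, ...
        raise ParseError(f"{path}: {exc}") from exc
    tcol = _find_column(list(df.columns), _TIME_NAMES, "time")
    xcol = _find_column(list(df.columns), _X_NAMES, "cop-x")
    ycol = _find_column(list(df.columns), _Y_NAMES, "cop-y")
    for col in (tcol, xcol, ycol):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ParseError(f"{path}: non-numeric or NaN value in column "
                             f"{col!r} at row {int(bad[0]) + 2}")
    t = df[tcol].to_numpy(dtype=float)
    dt = np.diff(t)
    nonmono = np.flatnonzero(dt <= 0)
    if nonmono.size:
        raise ParseError(f"{path}: time not increasing at row {int(nonmono[0]) + 3}")
    inferred = 1.0 / float(np.median(dt))
    rate = meta.sample_rate
    if rate is None:
        rate = inferred
    elif abs(rate - inferred) / rate > 1e-3:
        warnings.warn(
            f"{path}: declared sample rate {rate:g} Hz differs from inferred "
            f"{inferred:g} Hz by more than 0.1%; using the declared rate",
            stacklevel=2,
        )
    try:
        return CopRecording(
            subject_id=meta.subject_id,
            group=meta.group,
            condition=meta.condition,
            height=meta.height,
            sample_rate=float(rate),
            t=t,
            cop_x=df[xcol].to_numpy(dtype=float),
            cop_y=df[ycol].to_numpy(dtype=float),
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_recording(rec: CopRecording, path: str | Path,
                    derived: DerivedSeries | None = None) -> None:
    """Write a recording as CSV at full float precision (round-trip safe).

    When ``derived`` is given, COPLen/TiltAngle are appended as extra
    columns.
    """
    data: dict[str, np.ndarray] = {"t": rec.t, "x": rec.cop_x, "y": rec.cop_y}
    if derived is not None:
        data["cop_len"] = derived.cop_len
        data["tilt_angle"] = derived.tilt_angle
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_manifest(path: str | Path) -> list[tuple[Path, SubjectMeta]]:
    """Read a cohort manifest CSV mapping file -> subject metadata.

    Required columns: ``file, subject_id, group, condition, height``;
    optional ``sample_rate``.  File paths are resolved relative to the
    manifest's directory.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = {"file", "subject_id", "group", "condition", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        rate = float(row["sample_rate"]) if "sample_rate" in df.columns else None
        meta = SubjectMeta(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            condition=str(row["condition"]),
            height=float(row["height"]),
            sample_rate=rate,
        )
        out.append((path.parent / str(row["file"]), meta))
    return out


def load_cohort(manifest_path: str | Path) -> list[CopRecording]:
    """Read every recording listed in a manifest."""
    return [read_recording(p, m) for p, m in read_manifest(manifest_path)]


def compute_cop_len(rec: CopRecording) -> np.ndarray:
    """Radial CoP excursion ``sqrt(cop_x**2 + cop_y**2)``, inches."""
    return np.hypot(rec.cop_x, rec.cop_y)


def compute_tilt_angle(cop_len: np.ndarray, height: float,
                       mode: str = "arccos") -> np.ndarray:
    """Tilt angle in degrees from the radial excursion and standing height.

    ``arccos`` (default): ``arccos(cop_len / (0.55 * height))`` — ~90
    degrees for a quiet stance, decreasing as the CoP moves out.  ``arcsin``
    gives the complementary inclination-from-vertical reading.  The argument
    is clamped to [-1, 1] so excursions beyond 55 % of height stay defined.
    """
    if not height > 0:
        raise ValidationError(f"height must be > 0, got {height}")
    arg = np.clip(np.asarray(cop_len, dtype=float) / (COM_HEIGHT_FRACTION * height),
                  -1.0, 1.0)
    if mode == "arccos":
        return np.degrees(np.arccos(arg))
    if mode == "arcsin":
        return np.degrees(np.arcsin(arg))
    raise ValueError(f"unknown tilt mode {mode!r}")


def derive_series(rec: CopRecording, mode: str = "arccos") -> DerivedSeries:
    """COPLen and TiltAngle for one recording."""
    cop_len = compute_cop_len(rec)
    return DerivedSeries(
        cop_len=cop_len,
        tilt_angle=compute_tilt_angle(cop_len, rec.height, mode=mode),
        mode=mode,
    )


def mean_center(rec: CopRecording) -> CopRecording:
    """A copy of the recording with each CoP channel mean-removed.

    Optional preprocessing for platforms whose origin is not the subject's
    balance point; off by default everywhere in the pipeline.
    """
    return replace(rec, cop_x=rec.cop_x - rec.cop_x.mean(),
                   cop_y=rec.cop_y - rec.cop_y.mean())
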