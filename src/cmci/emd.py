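"""Empirical Mode Decomposition (EMD) with energy-based mode truncation.

EMD adaptively splits a scalar series into intrinsic mode functions (IMFs):
oscillatory components whose extrema and zero-crossing counts differ by at
most one.  Each IMF is isolated by *sifting* — repeatedly subtracting the
mean of the cubic-spline envelopes through the local maxima and minima —
until the normalized squared change between successive siftings falls below
an SD threshold (0.2, the classic criterion) and the candidate satisfies
the IMF count property.  Extraction continues on the running residual until
it is monotone or a mode cap is reached, so the IMFs plus the residual
reconstruct the input exactly up to floating-point bookkeeping.

Envelope boundaries use mirror extension of the two extrema nearest each
endpoint, the standard guard against edge swings.  Plateaus of equal values
count as a single extremum at the plateau's (floor) midpoint.

Mode truncation discards IMFs carrying a negligible share of the total IMF
energy; the retained subset feeds the complexity analysis downstream while
``source`` and ``residual`` are kept untouched (completeness is deliberately
broken once modes are dropped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import EmptyRetentionError, InsufficientExtremaError

__all__ = [
    "ImfSet",
    "find_extrema",
    "zero_crossing_count",
    "is_imf",
    "envelope",
    "sift",
    "decompose",
    "truncate_modes",
]

DEFAULT_SD_THRESHOLD = 0.2
DEFAULT_MAX_ITER = 100
DEFAULT_MAX_IMFS = 10
DEFAULT_MIN_ENERGY_FRACTION = 0.01


@dataclass
class ImfSet:
    """Ordered IMFs plus residual from one decomposition.

    ``sum(imfs) + residual`` reconstructs ``source`` to ~1e-9 relative
    max-norm; ``retained_indices`` tracks which modes survive truncation
    (all of them, before :func:`truncate_modes` is applied).
    """

    source: np.ndarray
    imfs: list[np.ndarray]
    residual: np.ndarray
    sd_threshold: float = DEFAULT_SD_THRESHOLD
    retained_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.retained_indices and self.imfs:
            self.retained_indices = list(range(len(self.imfs)))

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    @property
    def retained_imfs(self) -> list[np.ndarray]:
        return [self.imfs[i] for i in self.retained_indices]

    def energies(self) -> np.ndarray:
        """Per-IMF energy, sum(imf**2)."""
        return np.array([float(np.sum(im * im)) for im in self.imfs])

    def reconstruction_error(self) -> float:
        """Relative max-norm error of sum(IMFs) + residual vs the source."""
        recon = self.residual.copy()
        for im in self.imfs:
            recon = recon + im
        denom = float(np.max(np.abs(self.source))) or 1.0
        return float(np.max(np.abs(self.source - recon))) / denom

    def to_frame(self):
        import pandas as pd

        data = {f"imf{i + 1}": im for i, im in enumerate(self.imfs)}
        data["residual"] = self.residual
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if sidecar:
            meta = {
                "sd_threshold": self.sd_threshold,
                "n_imfs": self.n_imfs,
                "retained_indices": self.retained_indices,
            }
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of ``x``.

    A plateau of equal values flanked by lower (higher) neighbours counts
    once, at the floor midpoint of the plateau.  Returns two int arrays
    (maxima, minima); both empty for monotone or constant input.
    """
    x = np.asarray(x, dtype=float)
    empty = np.array([], dtype=int)
    n = x.size
    if n < 3:
        return empty, empty
    dx = np.diff(x)
    change = np.flatnonzero(dx != 0)
    if change.size == 0:  # constant
        return empty, empty
    starts = np.r_[0, change + 1]  # first index of each equal-value run
    ends = np.r_[change, n - 1]  # last index of each run
    vals = x[starts]
    if vals.size < 3:
        return empty, empty
    v_prev, v_mid, v_next = vals[:-2], vals[1:-1], vals[2:]
    mid_idx = (starts[1:-1] + ends[1:-1]) // 2
    maxima = mid_idx[(v_mid > v_prev) & (v_mid > v_next)]
    minima = mid_idx[(v_mid < v_prev) & (v_mid < v_next)]
    return maxima.astype(int), minima.astype(int)


def zero_crossing_count(x: np.ndarray) -> int:
    """Number of sign changes, ignoring exact zeros."""
    s = np.sign(np.asarray(x, dtype=float))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def is_imf(x: np.ndarray) -> bool:
    """Whether extrema and zero-crossing counts differ by at most one."""
    maxima, minima = find_extrema(x)
    return abs((maxima.size + minima.size) - zero_crossing_count(x)) <= 1


def envelope(x: np.ndarray, extrema: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the given extrema of ``x``.

    The two extrema nearest each endpoint are mirrored about that endpoint
    before fitting, and the spline is evaluated at every sample position.
    Raises :class:`InsufficientExtremaError` for fewer than two extrema.
    """
    x = np.asarray(x, dtype=float)
    idx = np.asarray(extrema, dtype=int)
    if idx.size < 2:
        raise InsufficientExtremaError(
            f"need >= 2 extrema for an envelope, got {idx.size}"
        )
    n = x.size
    pos = idx.astype(float)
    val = x[idx]
    left_pos, left_val = [], []
    # mirrored knots land strictly outside [0, n-1]; extrema already at an
    # endpoint would duplicate and are skipped
    for j in (1, 0):
        if pos[j] > 0:
            left_pos.append(-pos[j])
            left_val.append(val[j])
    right_pos, right_val = [], []
    for j in (-1, -2):
        if pos[j] < n - 1:
            right_pos.append(2.0 * (n - 1) - pos[j])
            right_val.append(val[j])
    xs = np.concatenate([left_pos, pos, right_pos])
    ys = np.concatenate([left_val, val, right_val])
    if xs.size >= 4:
        spline = CubicSpline(xs, ys)
        return spline(np.arange(n, dtype=float))
    # degenerate knot sets (e.g. both extrema at the endpoints): linear
    return np.interp(np.arange(n, dtype=float), xs, ys)


def sift(
    x: np.ndarray,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, bool]:
    """Extract one IMF from ``x`` by iterative envelope-mean subtraction.

    Stops once the normalized squared change between successive candidates,
    ``SD = sum((h_prev - h)**2) / sum(h_prev**2)``, drops below
    ``sd_threshold`` *and* the candidate satisfies the IMF count property;
    ``max_iter`` caps the loop.  Returns ``(imf, converged)``.  Raises
    :class:`InsufficientExtremaError` if the input has too few extrema to
    start sifting at all.
    """
    if not sd_threshold > 0:
        raise ValueError("sd_threshold must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    h = np.asarray(x, dtype=float).copy()
    for it in range(max_iter):
        maxima, minima = find_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            if it == 0:
                raise InsufficientExtremaError(
                    "series has too few extrema to sift"
                )
            return h, True
        mean_env = 0.5 * (envelope(h, maxima) + envelope(h, minima))
        h_new = h - mean_env
        denom = float(np.sum(h * h))
        sd = float(np.sum(mean_env * mean_env)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < sd_threshold and is_imf(h):
            return h, True
    return h, False


def decompose(
    x: np.ndarray,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_imfs: int = DEFAULT_MAX_IMFS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ImfSet:
    """Full EMD of ``x``: IMFs extracted until the residual is monotone.

    Degenerate inputs (monotone, constant, too few extrema) yield zero IMFs
    with ``residual == x``.  The running residual is updated by exact
    subtraction, so completeness holds to float bookkeeping.
    """
    x = np.asarray(x, dtype=float)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs:
        maxima, minima = find_extrema(residual)
        if maxima.size + minima.size == 0:  # monotone/constant residual
            break
        try:
            imf, _converged = sift(residual, sd_threshold, max_iter)
        except InsufficientExtremaError:
            break
        imfs.append(imf)
        residual = residual - imf
    return ImfSet(source=x, imfs=imfs, residual=residual,
                  sd_threshold=sd_threshold)


def truncate_modes(
    s: ImfSet, min_energy_fraction: float = DEFAULT_MIN_ENERGY_FRACTION
) -> ImfSet:
    """Retain IMFs holding at least ``min_energy_fraction`` of IMF energy.

    Returns a new :class:`ImfSet` with ``retained_indices`` updated; the
    IMF list, source and residual are unchanged, so the completeness
    identity still refers to *all* modes.  Raises
    :class:`EmptyRetentionError` when nothing survives (callers may fall
    back to the single highest-energy mode).
    """
    if not 0 <= min_energy_fraction < 1:
        raise ValueError("min_energy_fraction must be in [0, 1)")
    energies = s.energies()
    total = float(energies.sum())
    if s.n_imfs == 0:
        return replace(s, retained_indices=[])
    if total == 0:
        raise EmptyRetentionError("all IMFs have zero energy")
    retained = [i for i, e in enumerate(energies)
                if e >= min_energy_fraction * total]
    if not retained:
        raise EmptyRetentionError(
            f"no IMF reaches {min_energy_fraction:.3g} of total energy"
        )
    return replace(s, retained_indices=retained)
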