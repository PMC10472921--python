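"""Phase extraction and phase-locking against circular-shift surrogates.

The phase-locking value (PLV) between two phase series is

    PLV = | (1/T) * sum_t exp(i * (theta_x(t) - theta_y(t))) |

and lies in [0, 1]: 1 when a perfectly consistent phase lag exists, near
0 for independent phases.  Because the PLV of two narrow-band signals is
biased by their spectral content, each voxel's empirical PLV is
referenced to a surrogate null built by circularly rotating the gastric
phase series in time by at least a minimum lag (+/-60 s by default).
The subject-level outcome is the *PLV-delta*: empirical PLV minus the
median surrogate PLV, averaged over runs.

Conventions:

* The gastric phase is computed on the full (untrimmed) recording,
  decimated to the BOLD sampling grid, and surrogate rotations are
  applied on that full-length decimated grid; the initial `n_trim`
  volumes are dropped from both series only when the PLV is evaluated.
* Admissible rotations are ``lag = L .. N - L - 1`` samples with
  ``L = min_lag_s / TR + n_trim``.  At the defaults (60 s, TR = 2 s,
  15 trimmed volumes) this leaves 360 surrogates for a 15-minute run
  (N = 450) and 210 for a 10-minute run (N = 300).

The all-lags PLV is evaluated through a circular cross-correlation of
the unit phasors via the FFT, which is algebraically identical to
rolling the gastric phase and recomputing the PLV lag by lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "PhaseSeries",
    "PLVMap",
    "NullSpec",
    "DeltaMap",
    "instantaneous_phase",
    "hilbert_phase",
    "gastric_to_bold_grid",
    "plv",
    "make_null_shifts",
    "lagged_plv",
    "delta_map",
    "average_runs",
    "cross_subject_null",
]


@dataclass
class PhaseSeries:
    """Instantaneous phase (radians) sampled on a regular grid.

    `n_trimmed` records how many initial samples are to be excluded
    when the series enters a PLV computation; the stored `theta` is the
    *full* (untrimmed) series so that circular surrogate rotations act
    on the complete grid.
    """

    theta: np.ndarray
    fs: float
    t0_offset: float = 0.0
    n_trimmed: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 1:
            raise ValueError("theta must be one-dimensional")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("phase contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (0 <= self.n_trimmed < self.theta.size):
            raise ValueError("n_trimmed out of range")

    def __len__(self) -> int:
        return self.theta.size

    def trimmed(self) -> np.ndarray:
        """Phase samples with the initial `n_trimmed` dropped."""
        return self.theta[self.n_trimmed:]


@dataclass
class PLVMap:
    """Per-voxel phase-locking values (in [0, 1]) over a mask."""

    values: np.ndarray
    run_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("PLV values must lie in [0, 1]")


@dataclass
class NullSpec:
    """Admissible circular-shift lags for the surrogate null."""

    lags: np.ndarray
    min_lag_s: float
    guard: int
    n_null: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        if np.any(self.lags == 0):
            raise ValueError("zero lag is not an admissible surrogate")
        if self.n_null != self.lags.size:
            raise ValueError("n_null inconsistent with lags")

    def to_dict(self) -> dict:
        return {
            "min_lag_s": self.min_lag_s,
            "guard": int(self.guard),
            "n_null": int(self.n_null),
            "lags": self.lags.tolist(),
        }


@dataclass
class DeltaMap:
    """Empirical PLV minus median surrogate PLV, per voxel."""

    values: np.ndarray
    subject_id: str = ""
    runs_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("delta values must lie in [-1, 1]")


def instantaneous_phase(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Angle of the analytic (Hilbert) signal along `axis`."""
    x = np.asarray(x, dtype=float)
    return np.angle(hilbert(x, axis=axis))


def hilbert_phase(x: np.ndarray, fs: float) -> PhaseSeries:
    """Instantaneous phase of a band-limited 1-D signal.

    Raises on (near-)constant input, whose phase is undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("hilbert_phase expects a 1-D signal")
    if x.size < 16:
        raise ValueError("signal too short for phase estimation")
    if np.ptp(x) == 0 or np.std(x) < 1e-12 * max(1.0, np.abs(x).max()):
        raise ValueError("constant signal: instantaneous phase undefined")
    return PhaseSeries(theta=instantaneous_phase(x), fs=fs)


def gastric_to_bold_grid(
    phase: PhaseSeries, TR: float, n_trim: int = 15
) -> PhaseSeries:
    """Decimate a gastric phase series onto the BOLD volume grid.

    Samples are taken at the volume onset times ``t_k = k * TR`` (every
    20th sample for a 10 Hz phase at TR = 2 s).  The returned series
    covers the *full* run; `n_trim` is recorded so that the initial
    volumes (30 s at the defaults) are excluded only when the PLV is
    evaluated, after any surrogate rotation.
    """
    step = phase.fs * TR
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"TR {TR}s is not an integer number of phase samples "
                         f"at {phase.fs} Hz")
    step = int(round(step))
    theta = phase.theta[::step]
    if theta.size <= n_trim:
        raise ValueError("phase series does not cover the volume grid")
    return PhaseSeries(theta=theta, fs=1.0 / TR, t0_offset=phase.t0_offset,
                       n_trimmed=n_trim)


def _as_theta(x) -> np.ndarray:
    if isinstance(x, PhaseSeries):
        return x.theta
    return np.asarray(x, dtype=float)


def plv(theta_x, theta_y) -> float | np.ndarray:
    """Phase-locking value between two phase series.

    ``theta_y`` may be a (voxels, T) matrix, in which case a vector of
    PLVs is returned.  Both inputs must have the same length T >= 2.
    """
    tx = _as_theta(theta_x)
    ty = _as_theta(theta_y)
    if tx.ndim != 1:
        raise ValueError("theta_x must be one-dimensional")
    if ty.shape[-1] != tx.size:
        raise ValueError(f"length mismatch: {tx.size} vs {ty.shape[-1]}")
    if tx.size < 2:
        raise ValueError("PLV requires at least two time points")
    z = np.exp(1j * (tx - ty))
    out = np.abs(z.mean(axis=-1))
    return float(out) if np.ndim(out) == 0 else out


def make_null_shifts(
    n_samples: int,
    min_lag_s: float = 60.0,
    TR: float = 2.0,
    n_trim: int = 15,
) -> NullSpec:
    """Enumerate admissible circular shifts on the BOLD-rate grid.

    Shifts of at least `min_lag_s` in either direction are admitted,
    with the `n_trim` trim guard added on each side:
    ``lags = L .. n_samples - L - 1`` with ``L = min_lag_s/TR + n_trim``,
    so ``n_null = n_samples - 2 L``.  For 15-minute runs at the defaults
    this yields 360 surrogates; for 10-minute runs, 210.
    """
    L = min_lag_s / TR
    if abs(L - round(L)) > 1e-9:
        raise ValueError("min_lag_s must be an integer number of TRs")
    L = int(round(L)) + int(n_trim)
    if n_samples <= 2 * L:
        raise ValueError(
            f"recording of {n_samples} volumes too short for +/-{min_lag_s}s "
            f"shifts with a {n_trim}-volume trim guard"
        )
    lags = np.arange(L, n_samples - L)
    return NullSpec(lags=lags, min_lag_s=min_lag_s, guard=n_trim, n_null=lags.size)


def lagged_plv(
    bold_theta: np.ndarray,
    gastric_theta: np.ndarray,
    lags: np.ndarray,
    n_trim: int = 0,
) -> np.ndarray:
    """PLV of every voxel against circular rotations of the gastric phase.

    For each lag ``k`` the gastric phase is rotated by ``k`` samples on
    the full grid (``np.roll``), the first `n_trim` samples of both
    series are dropped, and the PLV is evaluated.  Implemented as a
    circular cross-correlation of unit phasors via the FFT, which gives
    all lags at once and is exactly equal (to machine precision) to the
    per-lag loop.

    Parameters
    ----------
    bold_theta : (n_voxels, N) or (N,) array
        Voxel phases on the full volume grid.
    gastric_theta : (N,) array
        Gastric phase on the full volume grid.
    lags : int array
        Rotation lags in samples; 0 yields the empirical PLV.
    n_trim : int
        Initial samples excluded from the PLV sum.

    Returns
    -------
    (n_voxels, n_lags) array of PLVs (or (n_lags,) for 1-D input).
    """
    bt = np.atleast_2d(np.asarray(bold_theta, dtype=float))
    gt = np.asarray(gastric_theta, dtype=float)
    N = gt.size
    if bt.shape[1] != N:
        raise ValueError("BOLD and gastric grids differ in length")
    lags = np.asarray(lags, dtype=int) % N
    T = N - n_trim
    if T < 2:
        raise ValueError("fewer than two samples remain after trimming")
    zx = np.exp(1j * gt)
    wy = np.exp(-1j * bt)
    wy[:, :n_trim] = 0.0
    # c[v, k] = sum_t wy[v, t] * zx[(t - k) mod N]
    c = np.fft.ifft(np.fft.fft(wy, axis=1) * np.conj(np.fft.fft(np.conj(zx))), axis=1)
    out = np.abs(c[:, lags]) / T
    out = np.clip(out, 0.0, 1.0)
    if np.asarray(bold_theta).ndim == 1:
        return out[0]
    return out


def delta_map(
    bold_phases: np.ndarray,
    gastric_phase: PhaseSeries,
    nulls: NullSpec,
    run_id: str = "",
    subject_id: str = "",
) -> tuple[PLVMap, PLVMap, DeltaMap]:
    """Empirical, median-null and delta PLV maps for one run.

    `bold_phases` is a (voxels, N) phase matrix on the full volume grid;
    `gastric_phase` carries the trim count.  Returns the empirical PLV
    map, the per-voxel median over all surrogate rotations, and their
    difference.
    """
    if nulls.n_null < 1:
        raise ValueError("surrogate null requires at least one lag")
    n_trim = gastric_phase.n_trimmed
    gt = gastric_phase.theta
    bp = np.atleast_2d(np.asarray(bold_phases, dtype=float))
    all_lags = np.concatenate(([0], nulls.lags))
    plvs = lagged_plv(bp, gt, all_lags, n_trim=n_trim)
    emp = plvs[:, 0]
    null_med = np.median(plvs[:, 1:], axis=1)
    return (
        PLVMap(values=emp, run_id=run_id, subject_id=subject_id),
        PLVMap(values=null_med, run_id=run_id, subject_id=subject_id),
        DeltaMap(values=emp - null_med, subject_id=subject_id, runs_averaged=1),
    )


def average_runs(deltas: list[DeltaMap]) -> DeltaMap:
    """Subject-level map: mean of the per-run delta maps."""
    if not deltas:
        raise ValueError("no runs to average")
    vals = np.mean([d.values for d in deltas], axis=0)
    return DeltaMap(values=vals, subject_id=deltas[0].subject_id,
                    runs_averaged=len(deltas))


def cross_subject_null(
    bold_phases_by_subject: dict[str, np.ndarray],
    gastric_by_subject: dict[str, PhaseSeries],
    n_trim: int = 15,
) -> dict[str, np.ndarray]:
    """Cross-subject surrogate: each brain vs the stomachs of the others.

    For every subject, the PLV map of its voxel phases against every
    *other* subject's gastric phase is computed (series truncated to the
    common length) and summarized by the per-voxel median.
    """
    subjects = list(bold_phases_by_subject)
    if len(subjects) < 2:
        raise ValueError("cross-subject null requires at least two subjects")
    if set(subjects) != set(gastric_by_subject):
        raise ValueError("subject sets of brain and gastric phases differ")
    n_common = min(
        min(np.atleast_2d(bold_phases_by_subject[s]).shape[1] for s in subjects),
        min(len(gastric_by_subject[s]) for s in subjects),
    )
    out: dict[str, np.ndarray] = {}
    for s in subjects:
        bp = np.atleast_2d(bold_phases_by_subject[s])[:, :n_common]
        if bp.shape[1] != np.atleast_2d(bold_phases_by_subject[s]).shape[1]:
            warnings.warn(f"subject {s}: series truncated to {n_common} samples")
        maps = []
        for other in subjects:
            if other == s:
                continue
            gt = gastric_by_subject[other].theta[:n_common]
            maps.append(plv(gt[n_trim:], bp[:, n_trim:]))
        out[s] = np.median(np.stack(maps), axis=0)
    return out
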