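"""BOLD run preparation for gastric-synchrony analysis.

Handles everything between an already-preprocessed 4-D BOLD volume and
the per-voxel phase matrix: nuisance design construction (four
regression variants), per-voxel ordinary-least-squares confound
regression, mask-normalized Gaussian smoothing, narrow gastric-band
filtering at the volume rate, RETROICOR cardiac regressors derived from
pulse oximetry, and motion-based run exclusion.

The mandated stage order is regression -> smoothing -> band-pass;
because these operators do not commute, the order is part of the
contract and `prepare_run` enforces it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, ndimage, signal

from .egg import bandpass_around_peak

__all__ = [
    "CONFOUND_COLUMNS",
    "MOTION_COLUMNS",
    "ACOMPCOR_COLUMNS",
    "RETROICOR_COLUMNS",
    "DESIGN_VARIANTS",
    "BOLDRun",
    "ConfoundTable",
    "DesignMatrix",
    "PPGRecording",
    "detect_ppg_peaks",
    "retroicor_regressors",
    "build_confound_design",
    "regress_confounds",
    "smooth_gaussian",
    "gastric_band_filter",
    "motion_exclusion",
    "prepare_run",
]

#: The ten nuisance series examined for gastric synchrony.
CONFOUND_COLUMNS = (
    "csf", "white_matter", "global_signal", "framewise_displacement",
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
)
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
ACOMPCOR_COLUMNS = tuple(f"a_comp_cor_{i:02d}" for i in range(6))
RETROICOR_COLUMNS = tuple(f"retroicor_{i:02d}" for i in range(6))
DESIGN_VARIANTS = ("main_gsr", "no_gsr", "gsr_retroicor", "minimal")


@dataclass
class BOLDRun:
    """A masked BOLD run: voxels x volumes matrix plus geometry.

    `data` holds only in-mask voxels, in the order given by
    ``np.flatnonzero(mask.ravel())``; `mask` is the 3-D boolean brain /
    grey-matter mask on the acquisition grid.
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    TR: float
    affine: np.ndarray | None = None
    run_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3-D boolean volume")
        if self.data.ndim != 2 or self.data.shape[0] != int(self.mask.sum()):
            raise ValueError("data rows must match the mask voxel count")
        if self.data.shape[1] < 2:
            raise ValueError("a run needs at least two volumes")
        if self.affine is None:
            self.affine = np.diag((*self.voxel_size, 1.0))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def to_volume(self, values: np.ndarray | None = None) -> np.ndarray:
        """Scatter per-voxel values (default: the data) back onto the grid."""
        if values is None:
            values = self.data
        values = np.asarray(values)
        if values.ndim == 1:
            vol = np.zeros(self.mask.shape, dtype=float)
            vol[self.mask] = values
            return vol
        vol = np.zeros((*self.mask.shape, values.shape[1]), dtype=float)
        vol[self.mask, :] = values
        return vol

    def replace_data(self, data: np.ndarray) -> "BOLDRun":
        return BOLDRun(data=data, mask=self.mask, voxel_size=self.voxel_size,
                       TR=self.TR, affine=self.affine, run_id=self.run_id,
                       subject_id=self.subject_id)


class ConfoundTable:
    """fMRIPrep-style confounds: one row per volume, named columns."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        fd = "framewise_displacement"
        if fd in self.frame and np.any(self.frame[fd].to_numpy() < 0):
            raise ValueError("framewise displacement must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)

    def require(self, columns: Sequence[str]) -> None:
        missing = [c for c in columns if c not in self.frame.columns]
        if missing:
            raise KeyError(f"confounds table is missing column(s): {missing}")

    def column(self, name: str) -> np.ndarray:
        self.require([name])
        return self.frame[name].to_numpy(dtype=float)


@dataclass
class DesignMatrix:
    """Nuisance design: volumes x regressors, named columns."""

    matrix: np.ndarray
    names: list[str]
    variant: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("names do not match design columns")
        if "intercept" not in self.names:
            raise ValueError("design must include an intercept")


@dataclass
class PPGRecording:
    """Pulse-oximetry trace with (optionally) detected systolic peaks."""

    samples: np.ndarray
    fs: float = 500.0
    peak_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.peak_times is not None:
            self.peak_times = np.asarray(self.peak_times, dtype=float)
            if np.any(np.diff(self.peak_times) <= 0):
                raise ValueError("peak_times must be strictly increasing")


def detect_ppg_peaks(ppg: PPGRecording) -> np.ndarray:
    """Detect one systolic peak per cardiac cycle.

    Peaks are local maxima above an adaptive threshold (midpoint of the
    median and the 98th percentile) separated by at least 0.3 s.
    Inter-beat intervals outside the physiologic 0.3-2.0 s range trigger
    a warning.  A flat trace yields an empty list with a warning.
    """
    x = ppg.samples
    if x.size < 10 * ppg.fs:
        raise ValueError("PPG shorter than 10 s")
    if np.ptp(x) < 1e-12:
        warnings.warn("flat PPG trace: no cardiac peaks detected")
        return np.empty(0)
    height = 0.5 * (np.median(x) + np.percentile(x, 98))
    idx, _ = signal.find_peaks(x, height=height, distance=int(0.3 * ppg.fs))
    times = idx / ppg.fs
    ibi = np.diff(times)
    bad = (ibi < 0.3) | (ibi > 2.0)
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} inter-beat interval(s) outside "
                      "the physiologic 0.3-2.0 s range")
    return times


def retroicor_regressors(
    peak_times: np.ndarray,
    frame_times: np.ndarray,
    n_harmonics: int = 3,
) -> np.ndarray:
    """Cardiac-phase harmonic regressors (RETROICOR).

    The cardiac phase at time t is
    ``phi(t) = 2*pi*(t - t_prev) / (t_next - t_prev)`` between
    consecutive systolic peaks; frames before the first or after the
    last peak extrapolate using the nearest cycle length.  Columns are
    ``cos(m*phi), sin(m*phi)`` for m = 1..n_harmonics.
    """
    peaks = np.asarray(peak_times, dtype=float)
    frames = np.asarray(frame_times, dtype=float)
    if peaks.size < 2:
        raise ValueError("RETROICOR requires at least two cardiac peaks")
    phi = np.empty(frames.size)
    for i, t in enumerate(frames):
        j = np.searchsorted(peaks, t, side="right")
        if j == 0:
            period = peaks[1] - peaks[0]
            phi[i] = 2 * np.pi * (((t - peaks[0]) / period) % 1.0)
        elif j == peaks.size:
            period = peaks[-1] - peaks[-2]
            phi[i] = 2 * np.pi * (((t - peaks[-1]) / period) % 1.0)
        else:
            phi[i] = 2 * np.pi * (t - peaks[j - 1]) / (peaks[j] - peaks[j - 1])
    cols = []
    for m in range(1, n_harmonics + 1):
        cols.append(np.cos(m * phi))
        cols.append(np.sin(m * phi))
    return np.column_stack(cols)


def _derivative(x: np.ndarray) -> np.ndarray:
    """Backward difference with a zero first row."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


def build_confound_design(
    tab: ConfoundTable,
    variant: str,
    retroicor: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the nuisance design for one of the four variants.

    * ``main_gsr`` -- intercept, global signal, framewise displacement,
      the six motion estimates, their backward-difference derivatives,
      the squares of the motion estimates and of the derivatives, and
      six aCompCor components (33 columns).
    * ``no_gsr`` -- main_gsr without the global signal.
    * ``gsr_retroicor`` -- main_gsr plus six RETROICOR columns (either
      ``retroicor_00..05`` in the table or the `retroicor` argument).
    * ``minimal`` -- intercept and CSF only.

    Derivatives and squares are scoped to the six motion estimates.
    """
    if variant not in DESIGN_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {DESIGN_VARIANTS}")
    n = len(tab)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    if variant == "minimal":
        cols.append(tab.column("csf"))
        names.append("csf")
        return DesignMatrix(np.column_stack(cols), names, variant)

    if variant in ("main_gsr", "gsr_retroicor"):
        cols.append(tab.column("global_signal"))
        names.append("global_signal")
    cols.append(tab.column("framewise_displacement"))
    names.append("framewise_displacement")

    motion = np.column_stack([tab.column(c) for c in MOTION_COLUMNS])
    deriv = _derivative(motion)
    for j, c in enumerate(MOTION_COLUMNS):
        cols.append(motion[:, j]); names.append(c)
    for j, c in enumerate(MOTION_COLUMNS):
        cols.append(deriv[:, j]); names.append(f"{c}_derivative1")
    for j, c in enumerate(MOTION_COLUMNS):
        cols.append(motion[:, j] ** 2); names.append(f"{c}_power2")
    for j, c in enumerate(MOTION_COLUMNS):
        cols.append(deriv[:, j] ** 2); names.append(f"{c}_derivative1_power2")

    tab.require(ACOMPCOR_COLUMNS)
    for c in ACOMPCOR_COLUMNS:
        cols.append(tab.column(c)); names.append(c)

    if variant == "gsr_retroicor":
        if retroicor is not None:
            retro = np.asarray(retroicor, dtype=float)
            if retro.shape != (n, 6):
                raise ValueError("retroicor must be a volumes x 6 matrix")
            for j in range(6):
                cols.append(retro[:, j]); names.append(RETROICOR_COLUMNS[j])
        else:
            tab.require(RETROICOR_COLUMNS)
            for c in RETROICOR_COLUMNS:
                cols.append(tab.column(c)); names.append(c)

    return DesignMatrix(np.column_stack(cols), names, variant)


def regress_confounds(run: BOLDRun, design: DesignMatrix) -> BOLDRun:
    """Per-voxel OLS residualization against the nuisance design.

    Rank-deficient designs are repaired by dropping collinear columns
    (with a warning); residuals are orthogonal to every retained
    column to numerical precision.
    """
    X = design.matrix
    if X.shape[0] != run.n_volumes:
        raise ValueError("design rows must equal the number of volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        dropped = [design.names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"rank-deficient design: dropping collinear column(s) {dropped}")
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, run.data.T, rcond=None)
    resid = run.data - (X @ beta).T
    return run.replace_data(resid)


def smooth_gaussian(run: BOLDRun, fwhm: float = 3.0) -> BOLDRun:
    """Mask-confined 3-D Gaussian smoothing of every volume.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, scaled by the voxel
    size.  Smoothing is normalized by the smoothed mask so voxels near
    the mask boundary are not dimmed by zeros outside the brain.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return run.replace_data(run.data.copy())
    sigma_mm = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / vs for vs in run.voxel_size]
    mask = run.mask.astype(float)
    norm = ndimage.gaussian_filter(mask, sigma_vox)
    norm[norm <= 0] = 1.0
    vol4d = run.to_volume()  # zero outside the mask by construction
    sm = ndimage.gaussian_filter(vol4d, (*sigma_vox, 0.0)) / norm[..., None]
    return run.replace_data(sm[run.mask, :])


def gastric_band_filter(
    run: BOLDRun, peak_freq: float, halfwidth: float = 0.015
) -> BOLDRun:
    """Band-pass every voxel around the gastric peak at the volume rate.

    Reuses the zero-phase FIR design of the EGG filtering, redesigned at
    the BOLD sampling rate 1/TR.
    """
    fs = 1.0 / run.TR
    filtered = bandpass_around_peak(run.data, fs, peak_freq, halfwidth)
    return run.replace_data(filtered)


def motion_exclusion(mean_fd: np.ndarray) -> np.ndarray:
    """Keep flags: False where mean FD exceeds group mean + 2 SD."""
    fd = np.asarray(mean_fd, dtype=float)
    if fd.size < 3:
        raise ValueError("motion exclusion requires at least three entries")
    threshold = fd.mean() + 2.0 * fd.std(ddof=1)
    return fd <= threshold


def prepare_run(
    run: BOLDRun,
    tab: ConfoundTable,
    variant: str,
    peak_freq: float,
    halfwidth: float = 0.015,
    fwhm: float = 3.0,
    retroicor: np.ndarray | None = None,
) -> BOLDRun:
    """Full preparation chain: regression -> smoothing -> band-pass."""
    design = build_confound_design(tab, variant, retroicor=retroicor)
    out = regress_confounds(run, design)
    out = smooth_gaussian(out, fwhm=fwhm)
    return gastric_band_filter(out, peak_freq, halfwidth)
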