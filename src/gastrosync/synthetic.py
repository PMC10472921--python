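"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without any download: the
generators emit EGG recordings with a narrow-band gastric oscillator in
the normogastric band, BOLD runs in which a known block of voxels holds
a fixed phase lag to that oscillator at a *tuned* phase-locking value,
confound tables that optionally share the gastric rhythm (with or
without leaking it into the BOLD data), and a pulse-oximetry trace with
known beat times.  Ground truth (peak frequency, coupled-voxel mask,
lags, coupling strengths, beat times) is stored losslessly beside the
data so every downstream stage can be scored.

Model choices
-------------
* Gastric oscillator: a sinusoid at the subject's peak frequency whose
  phase drifts as an Ornstein-Uhlenbeck process -- narrow-band, yet
  non-trivial for the Hilbert/PLV chain.
* BOLD noise: AR(1) (rho = 0.3) plus white noise, optionally plus a
  low-rank shared-latent term that gives runs a functional-connectivity
  structure (subject-stable or not, per `subject_stability`).
* Coupling calibration: the coupled-voxel amplitude is derived a priori
  by inverting the expected phase resultant of a constant phasor in
  complex Gaussian noise, with the in-band noise power computed from
  the AR(1)+white spectrum and the analysis band-pass response.  No
  data-dependent tuning is involved.

All generators are pure functions of (config, seed): regeneration is
bitwise identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal
from scipy.special import ive

from .bold_prep import (ACOMPCOR_COLUMNS, BOLDRun, CONFOUND_COLUMNS,
                        ConfoundTable, PPGRecording)
from .egg import EGGRecording, NORMOGASTRIC_BAND, _design_bandpass
from .groupstats import SphereAnnotation

import pandas as pd

__all__ = [
    "SimConfig",
    "SimRun",
    "SimSubject",
    "SimCohort",
    "expected_phase_resultant",
    "snr_for_resultant",
    "gen_egg_recording",
    "gen_coupled_bold",
    "gen_confounds_and_ppg",
    "gen_cohort",
    "gen_sphere_annotation",
]


@dataclass
class SimConfig:
    """Conditions of a simulated cohort.

    Defaults mirror the acquisition this pipeline targets: two
    15-minute runs per subject at TR = 2 s, EGG at 10 Hz with a
    subject-specific gastric peak drawn from N(0.05, 0.005) Hz
    truncated to the normogastric band, and a 12x12x12 grid of 3 mm
    voxels with a 27-voxel coupled block.
    """

    n_subjects: int = 8
    runs_per_subject: int = 2
    run_duration_s: float = 900.0
    egg_fs: float = 10.0
    TR: float = 2.0
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_coupled_voxels: int = 27
    coupling_plv_target: float = 0.5
    coupling_between_sd: float = 0.15
    peak_freq_mean: float = 0.05
    peak_freq_sd: float = 0.005
    peak_freq_band: tuple[float, float] = NORMOGASTRIC_BAND
    freq_jitter_sd: float = 0.003    # Hz, SD of the instantaneous-frequency drift
    freq_jitter_tau: float = 60.0    # s, OU time constant of the drift
    bold_ar1_rho: float = 0.3
    bold_ar1_sd: float = 1.0
    bold_white_sd: float = 0.5
    fc_strength: float = 0.5         # amplitude of shared-latent FC structure
    fc_rank: int = 5
    confound_coupling: float = 0.0
    coupled_confounds: tuple[str, ...] = (
        "csf", "global_signal", "trans_x", "rot_x", "rot_z")
    bold_artifact_gain: float = 1.0  # scale of the confound-shared BOLD artifact
    subject_stability: float = 1.0
    egg_amplitudes: tuple[float, ...] = (3.0, 1.5, 1.0, 0.7)
    egg_amp: float = 0.2             # mV, gastric amplitude on the best channel
    egg_noise_sd: float = 0.05       # mV, 1/f noise per channel
    egg_cardiac_amp: float = 0.02    # mV, cardiac bleed at the heart rate
    heart_rate_mean: float = 70.0    # bpm
    heart_rate_sd: float = 7.0
    ppg_fs: float = 500.0
    filter_halfwidth: float = 0.015
    include_physio: bool = True  # generate EGG and PPG traces (skippable when
                                 # only BOLD/confounds are consumed)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.run_duration_s, self.egg_fs, self.TR) <= 0:
            raise ValueError("rates and durations must be positive")
        if not (0 <= self.coupling_plv_target <= 1):
            raise ValueError("coupling_plv_target must lie in [0, 1]")
        if not (0 <= self.confound_coupling <= 1):
            raise ValueError("confound_coupling must lie in [0, 1]")
        if not (0 <= self.subject_stability <= 1):
            raise ValueError("subject_stability must lie in [0, 1]")

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_duration_s / self.TR))

    @property
    def n_egg_samples(self) -> int:
        return int(round(self.run_duration_s * self.egg_fs))


@dataclass
class SimRun:
    """One simulated run with its ground truth."""

    egg: EGGRecording | None
    bold: BOLDRun
    confounds: ConfoundTable
    ppg: PPGRecording | None
    truth: dict


@dataclass
class SimSubject:
    subject_id: str
    f0_lab: float  # gastric peak of the (out-of-scanner) lab recording
    runs: list[SimRun]


@dataclass
class SimCohort:
    cfg: SimConfig
    subjects: list[SimSubject]

    @property
    def coupled_mask(self) -> np.ndarray:
        return self.subjects[0].runs[0].truth["coupled_mask"]

    def iter_runs(self):
        for sub in self.subjects:
            for run in sub.runs:
                yield sub.subject_id, run


# ---------------------------------------------------------------------------
# coupling calibration


def expected_phase_resultant(gamma: np.ndarray) -> np.ndarray:
    """Expected resultant |E[exp(i*phi)]| of a phasor in Gaussian noise.

    For ``z = gamma + n`` with circular complex Gaussian ``n`` of unit
    power (E|n|^2 = 1), the mean resultant length of the phase of z is

        rho = sqrt(pi * gamma^2 / 4) * exp(-g) * [I0(g) + I1(g)],
        g = gamma^2 / 2

    (the Rice phase distribution).  Evaluated with exponentially scaled
    Bessel functions for numerical stability.
    """
    gamma = np.asarray(gamma, dtype=float)
    g = gamma**2 / 2.0
    # ive(v, x) = iv(v, x) * exp(-x); exp(-g)*(I0+I1)(g) = ive0 + ive1
    return np.sqrt(np.pi) / 2.0 * gamma * (ive(0, g) + ive(1, g))


def snr_for_resultant(rho: float, gamma_max: float = 500.0) -> float:
    """Invert :func:`expected_phase_resultant`: SNR giving resultant `rho`."""
    if not (0 <= rho <= 1):
        raise ValueError("rho must lie in [0, 1]")
    if rho == 0:
        return 0.0
    hi = expected_phase_resultant(gamma_max)
    if rho >= hi:
        warnings.warn(f"coupling target {rho:.3f} infeasible; "
                      f"achieved {hi:.4f} at the SNR cap")
        return gamma_max
    return float(optimize.brentq(
        lambda g: expected_phase_resultant(g) - rho, 0.0, gamma_max, xtol=1e-10))


def _inband_noise_sd(cfg: SimConfig, peak_freq: float) -> float:
    """SD of the AR(1)+white(+FC) BOLD noise inside the analysis band.

    Integrates the noise spectrum against the squared (forward-backward)
    response of the gastric band-pass designed at the volume rate.
    """
    fs = 1.0 / cfg.TR
    b = _design_bandpass(fs, peak_freq, cfg.filter_halfwidth)
    w, h = signal.freqz(b, worN=4096)
    gnet = np.abs(h) ** 2  # filtfilt amplitude response
    rho = cfg.bold_ar1_rho
    ar_var = cfg.bold_ar1_sd**2 + (cfg.fc_strength**2 if cfg.fc_strength else 0.0)
    s_ar = ar_var * (1 - rho**2) / (1 - 2 * rho * np.cos(w) + rho**2)
    s_w = cfg.bold_white_sd**2 * np.ones_like(w)
    var_out = np.trapezoid((s_ar + s_w) * gnet**2, w) / np.pi
    return float(np.sqrt(var_out))


def coupled_amplitude(cfg: SimConfig, peak_freq: float, target: float) -> float:
    """Sinusoid amplitude that yields the target PLV after the analysis chain."""
    sigma_b = _inband_noise_sd(cfg, peak_freq)
    if sigma_b == 0:
        return 1.0 if target > 0 else 0.0
    gamma = snr_for_resultant(target)
    fs = 1.0 / cfg.TR
    b = _design_bandpass(fs, peak_freq, cfg.filter_halfwidth)
    _, h = signal.freqz(b, worN=np.array([2 * np.pi * peak_freq / fs]))
    g_pass = float(np.abs(h[0]) ** 2)
    return gamma * np.sqrt(2.0) * sigma_b / g_pass


# ---------------------------------------------------------------------------
# elementary noise processes


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float,
         size: int | tuple = ()) -> np.ndarray:
    """AR(1) series with marginal SD `sd`, vectorized over leading dims."""
    shape = (size, n) if isinstance(size, int) else (*size, n)
    e = rng.standard_normal(shape) * sd * np.sqrt(1 - rho**2)
    x = signal.lfilter([1.0], [1.0, -rho], e, axis=-1)
    return x if shape[:-1] else x.reshape(n)


def _one_over_f(rng: np.random.Generator, n: int, sd: float,
                n_channels: int = 1) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit-free marginal SD `sd`."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x * sd


def _ou_phase_drift(rng: np.random.Generator, n: int, fs: float,
                    sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck phase drift, SD `sd` rad, time scale `tau` s."""
    dt = 1.0 / fs
    a = np.exp(-dt / tau)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    innov = rng.standard_normal(n - 1) * sd * np.sqrt(1 - a**2)
    x[1:] = signal.lfilter([1.0], [1.0, -a], innov, zi=[a * x[0]])[0]
    return x


def _gastric_oscillator(rng: np.random.Generator, cfg: SimConfig,
                        f0: float) -> tuple[np.ndarray, np.ndarray]:
    """(signal, true phase) of the gastric rhythm at the EGG rate.

    The instantaneous frequency wanders around `f0` as an OU process
    (`freq_jitter_sd`, `freq_jitter_tau`), so the phase diffuses without
    bound -- the narrow spectral peak of a real gastric rhythm, whose
    time-shifted copies progressively lose phase alignment.  This is
    what makes the circular-shift surrogate null meaningful.
    """
    n = cfg.n_egg_samples
    f_inst = f0 + _ou_phase_drift(rng, n, cfg.egg_fs, cfg.freq_jitter_sd,
                                  cfg.freq_jitter_tau)
    phase = 2 * np.pi * np.cumsum(f_inst) / cfg.egg_fs + rng.uniform(0, 2 * np.pi)
    return np.cos(phase), phase


# ---------------------------------------------------------------------------
# generators


def gen_egg_recording(cfg: SimConfig, rng: np.random.Generator, f0: float,
                      subject_id: str = "", run_id: str = "",
                      gastric_signal: np.ndarray | None = None) -> EGGRecording:
    """Four-channel EGG: shared gastric oscillator + 1/f noise + cardiac bleed.

    Channel amplitudes follow `cfg.egg_amplitudes`, so the first channel
    carries the strongest gastric signal (recorded in ground truth by
    the cohort generator).
    """
    n = cfg.n_egg_samples
    if gastric_signal is None:
        gastric_signal, _ = _gastric_oscillator(rng, cfg, f0)
    amps = np.asarray(cfg.egg_amplitudes) * cfg.egg_amp
    noise = _one_over_f(rng, n, cfg.egg_noise_sd, n_channels=amps.size)
    t = np.arange(n) / cfg.egg_fs
    cardiac = cfg.egg_cardiac_amp * np.cos(2 * np.pi * 1.2 * t + rng.uniform(0, 2 * np.pi))
    samples = amps[:, None] * gastric_signal[None, :] + noise + cardiac[None, :]
    return EGGRecording(samples=samples, fs=cfg.egg_fs,
                        subject_id=subject_id, run_id=run_id)


def _central_block_mask(grid_shape: tuple[int, int, int], n_voxels: int) -> np.ndarray:
    side = max(1, int(round(n_voxels ** (1 / 3))))
    mask = np.zeros(grid_shape, dtype=bool)
    start = [max(0, s // 2 - side // 2) for s in grid_shape]
    sl = tuple(slice(st, st + side) for st in start)
    mask[sl] = True
    return mask


def gen_coupled_bold(
    cfg: SimConfig,
    rng: np.random.Generator,
    gastric_phase_bold: np.ndarray,
    coupling_target: float,
    peak_freq: float,
    voxel_lags: np.ndarray | None = None,
    fc_loadings: np.ndarray | None = None,
    artifact: np.ndarray | None = None,
    subject_id: str = "",
    run_id: str = "",
) -> tuple[BOLDRun, dict]:
    """BOLD run with a known coupled block, tuned to `coupling_target` PLV.

    Coupled voxels are ``a * cos(gastric phase + voxel lag)`` plus the
    cohort noise model; `a` comes from :func:`coupled_amplitude`.
    Uncoupled voxels carry matched-spectrum noise only.  An optional
    `artifact` series (shared with the confound table) is added to every
    voxel with voxel-specific gains.
    """
    grid = cfg.grid_shape
    mask = np.ones(grid, dtype=bool)
    n_vox = int(np.prod(grid))
    n_t = gastric_phase_bold.size
    coupled_mask = _central_block_mask(grid, cfg.n_coupled_voxels)
    coupled_flat = coupled_mask[mask]

    data = _ar1(rng, n_t, cfg.bold_ar1_rho, cfg.bold_ar1_sd, size=n_vox)
    data += rng.standard_normal((n_vox, n_t)) * cfg.bold_white_sd
    if cfg.fc_strength > 0:
        if fc_loadings is None:
            fc_loadings = rng.standard_normal((n_vox, cfg.fc_rank)) / np.sqrt(cfg.fc_rank)
        latents = _ar1(rng, n_t, cfg.bold_ar1_rho, 1.0, size=cfg.fc_rank)
        data += cfg.fc_strength * fc_loadings @ latents

    amp = coupled_amplitude(cfg, peak_freq, coupling_target)
    n_coupled = int(coupled_flat.sum())
    if voxel_lags is None:
        voxel_lags = rng.uniform(-np.pi, np.pi, n_coupled)
    if n_coupled and coupling_target > 0:
        data[coupled_flat] += amp * np.cos(gastric_phase_bold[None, :]
                                           + voxel_lags[:, None])
    gains = None
    if artifact is not None:
        gains = np.clip(rng.normal(1.0, 0.3, n_vox), 0.0, None)
        data += cfg.bold_artifact_gain * gains[:, None] * artifact[None, :]

    run = BOLDRun(data=data, mask=mask, voxel_size=cfg.voxel_size, TR=cfg.TR,
                  run_id=run_id, subject_id=subject_id)
    truth = {
        "coupled_mask": coupled_mask,
        "voxel_lags": voxel_lags,
        "coupling_target": coupling_target,
        "coupling_amplitude": amp,
        "artifact_gains": gains,
    }
    return run, truth


def _ppg_template(fs: float) -> np.ndarray:
    """Asymmetric systolic pulse: fast upstroke, slower decay."""
    t = np.arange(int(0.45 * fs)) / fs
    rise = np.clip(t / 0.10, 0, 1) ** 2
    decay = np.exp(-np.clip(t - 0.10, 0, None) / 0.12)
    return rise * decay


def gen_confounds_and_ppg(
    cfg: SimConfig,
    rng: np.random.Generator,
    gastric_phase_bold: np.ndarray,
    heart_rate: float,
    artifact: np.ndarray | None = None,
    artifact_target: float = 0.0,
    include_ppg: bool = True,
    bold_mean: np.ndarray | None = None,
) -> tuple[ConfoundTable, PPGRecording | None, dict]:
    """All ten confound columns, aCompCor components, and a PPG trace.

    The global signal is, as in real data, the spatial mean of the BOLD
    run (plus a little measurement noise) when `bold_mean` is supplied
    -- so any artifact shared between confounds and the brain appears in
    it at full strength, and regressing it out genuinely removes the
    artifact.  With `artifact_target` > 0 the gastric rhythm is injected
    into the coupled confound columns: columns that share the BOLD
    artifact receive the `artifact` series itself; the remaining coupled
    columns (e.g. CSF) get an independent gastric-locked component, so
    they are synchronized with the EGG without leaking into the brain
    data.  Standardized columns are then mapped to realistic units
    (mm / rad / FD >= 0).
    """
    n_t = gastric_phase_bold.size
    base: dict[str, np.ndarray] = {}
    for name in CONFOUND_COLUMNS:
        z = _ar1(rng, n_t, cfg.bold_ar1_rho, 1.0) + \
            rng.standard_normal(n_t) * cfg.bold_white_sd
        base[name] = z
    gs_noise = rng.standard_normal(n_t)

    if artifact_target > 0:
        inj_amp = coupled_amplitude(cfg, cfg.peak_freq_mean, artifact_target)
        for name in cfg.coupled_confounds:
            if name == "global_signal" and bold_mean is not None:
                continue  # the BOLD mean already carries the artifact
            if artifact is not None and name != "csf":
                base[name] = base[name] + artifact
            else:
                lag = rng.uniform(-np.pi, np.pi)
                base[name] = base[name] + inj_amp * np.cos(gastric_phase_bold + lag)

    if bold_mean is not None:
        global_signal = bold_mean + 0.05 * gs_noise
    else:
        global_signal = base["global_signal"]
    cols = {
        "csf": base["csf"],
        "white_matter": base["white_matter"],
        "global_signal": global_signal,
        "framewise_displacement": np.clip(0.10 + 0.03 * base["framewise_displacement"], 0.0, None),
        "trans_x": 0.05 * base["trans_x"],
        "trans_y": 0.05 * base["trans_y"],
        "trans_z": 0.05 * base["trans_z"],
        "rot_x": 0.001 * base["rot_x"],
        "rot_y": 0.001 * base["rot_y"],
        "rot_z": 0.001 * base["rot_z"],
    }
    for name in ACOMPCOR_COLUMNS:
        cols[name] = rng.standard_normal(n_t)
    tab = ConfoundTable(pd.DataFrame(cols))

    if not include_ppg:
        return tab, None, {"heart_rate": heart_rate}

    # PPG with known beat times
    n_ppg = int(round(cfg.run_duration_s * cfg.ppg_fs))
    mean_ibi = 60.0 / heart_rate
    n_beats = int(cfg.run_duration_s / mean_ibi) + 2
    ibis = np.clip(mean_ibi + rng.normal(0, 0.02, n_beats), 0.35, 1.9)
    beat_times = rng.uniform(0, mean_ibi) + np.concatenate(([0.0], np.cumsum(ibis)))
    beat_times = beat_times[beat_times < cfg.run_duration_s - 0.5]
    tmpl = _ppg_template(cfg.ppg_fs)
    x = np.zeros(n_ppg)
    for bt in beat_times:
        i0 = int(round(bt * cfg.ppg_fs))
        seg = min(tmpl.size, n_ppg - i0)
        x[i0:i0 + seg] += tmpl[:seg]
    x += rng.standard_normal(n_ppg) * 0.02
    peak_offset = np.argmax(tmpl) / cfg.ppg_fs
    ppg = PPGRecording(samples=x, fs=cfg.ppg_fs)
    truth = {"beat_times": beat_times, "systole_times": beat_times + peak_offset,
             "heart_rate": heart_rate}
    return tab, ppg, truth


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _blend(stable: float, fresh: float, mean: float, s: float) -> float:
    """Correlate run-level draws across runs with coefficient s^2.

    Returns ``mean + s*(stable-mean) + sqrt(1-s^2)*(fresh-mean)``: at
    s = 1 the subject-stable value, at s = 0 an independent redraw, with
    the marginal variance preserved in between.
    """
    return mean + s * (stable - mean) + np.sqrt(max(0.0, 1 - s**2)) * (fresh - mean)


def gen_cohort(cfg: SimConfig) -> SimCohort:
    """Full multi-subject, multi-run cohort with ground truth.

    `subject_stability` controls whether the gastric peak frequency,
    the coupling strength and the FC loadings are stable within subject
    across runs (1), redrawn per run (0), or partially correlated in
    between.  Deterministic under `cfg.seed`.
    """
    root = np.random.SeedSequence(cfg.seed)
    sub_seeds = root.spawn(cfg.n_subjects)
    n_vox = int(np.prod(cfg.grid_shape))
    lo, hi = cfg.peak_freq_band
    subjects = []
    for si in range(cfg.n_subjects):
        streams = sub_seeds[si].spawn(cfg.runs_per_subject + 1)
        srng = np.random.default_rng(streams[0])
        sid = f"sub-{si:02d}"
        f0_sub = _truncnorm(srng, cfg.peak_freq_mean, cfg.peak_freq_sd, lo, hi)
        f0_lab = float(np.clip(f0_sub + srng.normal(0, 0.002), lo, hi))
        coup_sub = float(np.clip(
            srng.normal(cfg.coupling_plv_target, cfg.coupling_between_sd), 0.0, 0.95))
        hr = float(np.clip(srng.normal(cfg.heart_rate_mean, cfg.heart_rate_sd), 45, 120))
        n_coupled = int(_central_block_mask(cfg.grid_shape, cfg.n_coupled_voxels).sum())
        lags_sub = srng.uniform(-np.pi, np.pi, n_coupled)
        w_sub = srng.standard_normal((n_vox, cfg.fc_rank)) / np.sqrt(cfg.fc_rank)

        runs = []
        for ri in range(cfg.runs_per_subject):
            rng = np.random.default_rng(streams[ri + 1])
            s = cfg.subject_stability
            f0 = float(np.clip(_blend(
                f0_sub, _truncnorm(rng, cfg.peak_freq_mean, cfg.peak_freq_sd, lo, hi),
                cfg.peak_freq_mean, s), lo, hi))
            coup = float(np.clip(_blend(
                coup_sub,
                float(np.clip(rng.normal(cfg.coupling_plv_target,
                                         cfg.coupling_between_sd), 0.0, 0.95)),
                cfg.coupling_plv_target, s), 0.0, 0.95))
            w_run = _blend(w_sub, rng.standard_normal((n_vox, cfg.fc_rank))
                           / np.sqrt(cfg.fc_rank), 0.0, s)

            gastric_sig, gastric_phase = _gastric_oscillator(rng, cfg, f0)
            step = int(round(cfg.egg_fs * cfg.TR))
            phase_bold = gastric_phase[::step][:cfg.n_volumes]
            if phase_bold.size < cfg.n_volumes:
                raise ValueError("gastric series does not cover the volume grid")

            u_run = rng.uniform(0.25, 1.0)
            artifact = None
            art_target = 0.0
            if cfg.confound_coupling > 0:
                art_target = cfg.confound_coupling * u_run
                art_amp = coupled_amplitude(cfg, f0, art_target)
                artifact = art_amp * np.cos(phase_bold + rng.uniform(-np.pi, np.pi))

            egg = None
            if cfg.include_physio:
                egg = gen_egg_recording(cfg, rng, f0, subject_id=sid,
                                        run_id=f"run-{ri + 1}",
                                        gastric_signal=gastric_sig)
            bold, bold_truth = gen_coupled_bold(
                cfg, rng, phase_bold, coup, f0, voxel_lags=lags_sub,
                fc_loadings=w_run, artifact=artifact,
                subject_id=sid, run_id=f"run-{ri + 1}")
            tab, ppg, ppg_truth = gen_confounds_and_ppg(
                cfg, rng, phase_bold, hr, artifact=artifact,
                artifact_target=art_target,
                include_ppg=cfg.include_physio,
                bold_mean=bold.data.mean(axis=0))
            truth = {
                "f0": f0,
                "gastric_phase_bold": phase_bold,
                "gastric_signal": gastric_sig,
                "artifact_target": art_target,
                "artifact_scale": u_run,
                **bold_truth, **ppg_truth,
            }
            runs.append(SimRun(egg=egg, bold=bold, confounds=tab, ppg=ppg,
                               truth=truth))
        subjects.append(SimSubject(subject_id=sid, f0_lab=f0_lab, runs=runs))
    return SimCohort(cfg=cfg, subjects=subjects)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform lattice on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + np.sqrt(5))
    theta = golden * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def gen_sphere_annotation(
    n_vertices: int,
    label_fraction: float,
    symmetry: bool = False,
    seed: int | np.random.Generator | None = None,
) -> tuple[SphereAnnotation, SphereAnnotation]:
    """(left, right) spherical annotations with contiguous label patches.

    Vertices form a deterministic Fibonacci lattice on each hemisphere's
    full sphere; the left lattice is the sagittal mirror of the right,
    so vertex i on the left corresponds to vertex i on the right.  The
    patch comprises the ``round(label_fraction * n)`` vertices nearest a
    random seed vertex.  With `symmetry`, the left labels equal the
    right labels at mirrored vertices.
    """
    if n_vertices < 100:
        raise ValueError("need at least 100 vertices per hemisphere")
    if not (0 <= label_fraction <= 1):
        raise ValueError("label_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    coords_r = _fibonacci_sphere(n_vertices)
    coords_l = coords_r * np.array([-1.0, 1.0, 1.0])
    n_lab = int(round(label_fraction * n_vertices))

    def _patch(coords: np.ndarray) -> np.ndarray:
        labels = np.zeros(n_vertices, dtype=bool)
        if n_lab == 0:
            return labels
        center = coords[rng.integers(n_vertices)]
        order = np.argsort(-coords @ center)
        labels[order[:n_lab]] = True
        return labels

    labels_r = _patch(coords_r)
    labels_l = labels_r.copy() if symmetry else _patch(coords_l)
    return (SphereAnnotation(coords=coords_l, labels=labels_l, hemisphere="L"),
            SphereAnnotation(coords=coords_r, labels=labels_r, hemisphere="R"))
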