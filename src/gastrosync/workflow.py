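"""Dataset assembly, configuration and pipeline orchestration.

Ties the stages together: load (or simulate) per-run bundles of BOLD +
confounds + EGG (+ PPG), apply the exclusion rules (EGG quality level 3,
excessive mean framewise displacement), run the per-run synchrony chain
(EGG peak -> band-pass -> phase -> PLV / surrogate null / delta), and
assemble group-level inputs.  Every artifact is stamped with the
configuration hash and seed so identical reruns reproduce stochastic
outputs exactly.

On-disk formats are deliberately plain: NIfTI-1 for volumes,
tab-separated tables for everything sample-wise, JSON sidecars for
metadata and ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import egg as egg_mod
from .bold_prep import (BOLDRun, ConfoundTable, PPGRecording,
                        build_confound_design, gastric_band_filter,
                        motion_exclusion, regress_confounds, smooth_gaussian)
from .egg import EGGRecording, GastricPeak, QualityReport
from .groupstats import GroupSample
from .sync import (DeltaMap, NullSpec, PhaseSeries, average_runs, delta_map,
                   gastric_to_bold_grid, hilbert_phase, instantaneous_phase,
                   make_null_shifts)
from .synthetic import SimCohort

logger = logging.getLogger("gastrosync")

__all__ = [
    "PipelineConfig",
    "RunBundle",
    "RunResult",
    "gastric_phase_chain",
    "bold_phase_matrix",
    "process_run",
    "cohort_group_sample",
    "write_cohort",
    "load_run_bundle",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Every analysis default in one serializable place.

    The hash of the serialized config is stamped into outputs for
    provenance.
    """

    band: tuple[float, float] = (0.033, 0.066)
    window_s: float = 200.0
    overlap_s: float = 150.0
    clear_ratio: float = 4.0
    consistency_tol: float = 0.01
    halfwidth: float = 0.015
    min_lag_s: float = 60.0
    n_trim: int = 15
    fwhm: float = 3.0
    variant: str = "no_gsr"
    t_threshold: float = 2.3
    n_perm: int = 10_000
    connectivity: int = 26
    fd_exclusion_sd: float = 2.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class RunBundle:
    """One run's aligned inputs plus its QC status."""

    bold: BOLDRun
    confounds: ConfoundTable
    egg: EGGRecording
    ppg: PPGRecording | None = None
    subject_id: str = ""
    run_id: str = ""
    egg_quality: QualityReport | None = None
    mean_fd: float = float("nan")
    keep: bool = True
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if len(self.confounds) != self.bold.n_volumes:
            raise ValueError(
                f"{self.subject_id}/{self.run_id}: confounds have "
                f"{len(self.confounds)} rows for {self.bold.n_volumes} volumes")
        fd = self.confounds.column("framewise_displacement")
        self.mean_fd = float(np.nanmean(fd))


@dataclass
class RunResult:
    """Per-run synchrony outputs."""

    subject_id: str
    run_id: str
    peak: GastricPeak
    empirical: np.ndarray
    null_median: np.ndarray
    delta: np.ndarray
    nulls: NullSpec
    brainwide_delta: float


def gastric_phase_chain(
    egg: EGGRecording,
    TR: float,
    cfg: PipelineConfig,
    override_channel: int | None = None,
) -> tuple[PhaseSeries, GastricPeak]:
    """EGG recording -> gastric phase on the BOLD grid.

    Welch spectrum, in-band peak per channel, channel selection,
    +/-`halfwidth` zero-phase band-pass, Hilbert phase at the EGG rate,
    decimation to the volume grid with the trim count recorded.
    """
    spec = egg_mod.welch_spectrum(egg, cfg.window_s, cfg.overlap_s)
    peaks = egg_mod.find_gastric_peak(spec, cfg.band, cfg.clear_ratio)
    ch, peak = egg_mod.select_gastric_channel(peaks, override=override_channel)
    filtered = egg_mod.bandpass_around_peak(
        egg.samples[ch], egg.fs, peak.peak_freq, cfg.halfwidth)
    phase10 = hilbert_phase(filtered, egg.fs)
    return gastric_to_bold_grid(phase10, TR, cfg.n_trim), peak


def bold_phase_matrix(
    bold: BOLDRun,
    peak_freq: float,
    cfg: PipelineConfig,
    confounds: ConfoundTable | None = None,
    variant: str | None = None,
) -> np.ndarray:
    """BOLD run -> (voxels, volumes) phase matrix on the full grid.

    Stage order is fixed: confound regression (when a variant and table
    are given), spatial smoothing, gastric-band filtering, Hilbert
    phase.
    """
    run = bold
    if variant is not None:
        if confounds is None:
            raise ValueError("confound regression requires a confounds table")
        design = build_confound_design(confounds, variant)
        run = regress_confounds(run, design)
    run = smooth_gaussian(run, cfg.fwhm)
    run = gastric_band_filter(run, peak_freq, cfg.halfwidth)
    return instantaneous_phase(run.data, axis=-1)


def process_run(
    bundle: RunBundle,
    cfg: PipelineConfig,
    variant: str | None = None,
) -> RunResult:
    """Full per-run synchrony chain on one bundle."""
    if not bundle.keep:
        raise ValueError(
            f"{bundle.subject_id}/{bundle.run_id} is excluded "
            f"({bundle.exclusion_reason}); synchrony analysis refused")
    variant = cfg.variant if variant is None else variant
    gastric, peak = gastric_phase_chain(bundle.egg, bundle.bold.TR, cfg)
    theta = bold_phase_matrix(bundle.bold, peak.peak_freq, cfg,
                              confounds=bundle.confounds, variant=variant)
    n = len(gastric)
    if theta.shape[1] != n:
        raise ValueError("BOLD and gastric series lengths differ after alignment")
    nulls = make_null_shifts(n, cfg.min_lag_s, bundle.bold.TR, cfg.n_trim)
    emp, nul, dlt = delta_map(theta, gastric, nulls,
                              run_id=bundle.run_id, subject_id=bundle.subject_id)
    return RunResult(subject_id=bundle.subject_id, run_id=bundle.run_id,
                     peak=peak, empirical=emp.values, null_median=nul.values,
                     delta=dlt.values, nulls=nulls,
                     brainwide_delta=float(dlt.values.mean()))


def cohort_group_sample(
    cohort: SimCohort,
    cfg: PipelineConfig,
    variant: str | None = None,
) -> tuple[GroupSample, list[RunResult]]:
    """Run the per-run chain over a simulated cohort; average within subject."""
    results: list[RunResult] = []
    emp_rows, null_rows = [], []
    for sub in cohort.subjects:
        emps, nulls = [], []
        for run in sub.runs:
            bundle = RunBundle(bold=run.bold, confounds=run.confounds,
                               egg=run.egg, ppg=run.ppg,
                               subject_id=sub.subject_id, run_id=run.bold.run_id)
            res = process_run(bundle, cfg, variant=variant)
            results.append(res)
            emps.append(res.empirical)
            nulls.append(res.null_median)
        emp_rows.append(np.mean(emps, axis=0))
        null_rows.append(np.mean(nulls, axis=0))
    return GroupSample(np.array(emp_rows), np.array(null_rows)), results


# ---------------------------------------------------------------------------
# on-disk formats


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_egg(egg: EGGRecording, stem: Path) -> None:
    df = pd.DataFrame(egg.samples.T, columns=egg.channel_labels)
    df.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)
    _write_json(stem.with_suffix(".json"), {
        "fs": egg.fs, "channel_labels": egg.channel_labels,
        "subject": egg.subject_id, "run": egg.run_id})


def read_egg(stem: Path) -> EGGRecording:
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".tsv"), sep="\t", float_precision="round_trip")
    return EGGRecording(samples=df.to_numpy().T, fs=meta["fs"],
                        channel_labels=list(df.columns),
                        subject_id=meta.get("subject", ""),
                        run_id=meta.get("run", ""))


def write_bold(bold: BOLDRun, stem: Path) -> None:
    img = nib.Nifti1Image(bold.to_volume(), bold.affine)
    img.header.set_zooms((*bold.voxel_size, bold.TR))
    nib.save(img, stem.parent / (stem.name + "_bold.nii"))
    mimg = nib.Nifti1Image(bold.mask.astype(np.uint8), bold.affine)
    nib.save(mimg, stem.parent / (stem.name + "_mask.nii"))


def read_bold(stem: Path, subject_id: str = "", run_id: str = "") -> BOLDRun:
    img = nib.load(stem.parent / (stem.name + "_bold.nii"))
    mask = nib.load(stem.parent / (stem.name + "_mask.nii")).get_fdata() > 0
    zooms = img.header.get_zooms()
    data4d = np.asarray(img.dataobj, dtype=float)
    return BOLDRun(data=data4d[mask, :], mask=mask, voxel_size=tuple(zooms[:3]),
                   TR=float(zooms[3]), affine=img.affine,
                   subject_id=subject_id, run_id=run_id)


def write_ppg(ppg: PPGRecording, stem: Path) -> None:
    pd.DataFrame({"ppg": ppg.samples}).to_csv(
        stem.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6g")
    _write_json(stem.with_suffix(".json"), {"fs": ppg.fs})


def read_ppg(stem: Path) -> PPGRecording:
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
    return PPGRecording(samples=df["ppg"].to_numpy(), fs=meta["fs"])


def write_cohort(cohort: SimCohort, outdir: Path) -> None:
    """Materialize a simulated cohort in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(outdir / "sim_config.json", dataclasses.asdict(cohort.cfg))
    for sub in cohort.subjects:
        for run in sub.runs:
            rdir = outdir / sub.subject_id / run.bold.run_id
            rdir.mkdir(parents=True, exist_ok=True)
            write_bold(run.bold, rdir / "func")
            run.confounds.frame.to_csv(rdir / "confounds.tsv", sep="\t",
                                       index=False)
            if run.egg is not None:
                write_egg(run.egg, rdir / "egg")
            if run.ppg is not None:
                write_ppg(run.ppg, rdir / "ppg")
            truth = {k: v for k, v in run.truth.items()
                     if k not in ("gastric_signal",)}
            truth["coupled_mask"] = np.flatnonzero(
                run.truth["coupled_mask"].ravel())
            _write_json(rdir / "truth.json", truth)
        (outdir / sub.subject_id / "subject.json").write_text(
            json.dumps({"f0_lab": sub.f0_lab}))


def load_run_bundle(run_dir: Path, cfg: PipelineConfig,
                    subject_id: str = "", run_id: str = "") -> RunBundle:
    """Load and validate one run directory written by :func:`write_cohort`.

    EGG quality is graded on this run alone (cross-run consistency is
    re-assessed at the subject level by `run_pipeline`); level-3 EGG
    marks the bundle excluded.
    """
    run_dir = Path(run_dir)
    subject_id = subject_id or run_dir.parent.name
    run_id = run_id or run_dir.name
    bold = read_bold(run_dir / "func", subject_id, run_id)
    conf_path = run_dir / "confounds.tsv"
    if not conf_path.exists():
        raise FileNotFoundError(f"missing confounds table: {conf_path}")
    confounds = ConfoundTable(pd.read_csv(conf_path, sep="\t",
                                          float_precision="round_trip"))
    from .bold_prep import CONFOUND_COLUMNS
    confounds.require(CONFOUND_COLUMNS)
    egg = read_egg(run_dir / "egg")
    ppg = read_ppg(run_dir / "ppg") if (run_dir / "ppg.tsv").exists() else None
    bundle = RunBundle(bold=bold, confounds=confounds, egg=egg, ppg=ppg,
                       subject_id=subject_id, run_id=run_id)
    spec = egg_mod.welch_spectrum(egg, cfg.window_s, cfg.overlap_s)
    peaks = egg_mod.find_gastric_peak(spec, cfg.band, cfg.clear_ratio)
    bundle.egg_quality = egg_mod.assess_egg_quality([spec], [peaks],
                                                    cfg.consistency_tol)
    if bundle.egg_quality.excluded:
        bundle.keep = False
        bundle.exclusion_reason = "EGG quality level 3"
    return bundle


def run_pipeline(bundles: list[RunBundle], cfg: PipelineConfig,
                 outdir: Path) -> dict:
    """Execute the per-run and group stages over validated bundles.

    Applies motion exclusion across runs, processes every kept run,
    averages within subject, runs the sign-flip cluster test, and writes
    all artifacts (tab-separated tables, NIfTI maps, JSON provenance)
    under `outdir`.  Returns a summary dictionary.
    """
    from .groupstats import signflip_cluster_test

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not bundles:
        raise ValueError("no bundles supplied")
    provenance = {"config": cfg.to_dict(), "config_hash": cfg.hash(),
                  "seed": cfg.seed, "n_bundles": len(bundles)}

    fds = np.array([b.mean_fd for b in bundles])
    if fds.size >= 3:
        keep_fd = motion_exclusion(fds)
        for b, k in zip(bundles, keep_fd):
            if not k and b.keep:
                b.keep = False
                b.exclusion_reason = "mean FD above group mean + 2 SD"
    kept = [b for b in bundles if b.keep]
    logger.info("%d of %d runs kept after exclusion", len(kept), len(bundles))
    if not kept:
        raise ValueError("all runs excluded")

    results = []
    for b in kept:
        try:
            results.append(process_run(b, cfg))
        except Exception as exc:  # noqa: BLE001 - annotate stage and bundle
            raise RuntimeError(
                f"synchrony stage failed for {b.subject_id}/{b.run_id}: {exc}"
            ) from exc

    per_sub: dict[str, list[RunResult]] = {}
    for r in results:
        per_sub.setdefault(r.subject_id, []).append(r)
    emp = np.array([np.mean([r.empirical for r in rs], axis=0)
                    for rs in per_sub.values()])
    nul = np.array([np.mean([r.null_median for r in rs], axis=0)
                    for rs in per_sub.values()])
    sample = GroupSample(emp, nul)

    mask = kept[0].bold.mask
    summary = dict(provenance)
    summary["n_kept"] = len(kept)
    summary["excluded"] = [
        {"subject": b.subject_id, "run": b.run_id, "reason": b.exclusion_reason}
        for b in bundles if not b.keep]
    run_table = pd.DataFrame([{
        "subject": r.subject_id, "run": r.run_id,
        "peak_freq": r.peak.peak_freq, "n_null": r.nulls.n_null,
        "brainwide_delta": r.brainwide_delta} for r in results])
    run_table.to_csv(outdir / "runs.tsv", sep="\t", index=False)

    if sample.n_subjects >= 5:
        clusters = signflip_cluster_test(
            sample, mask.shape, mask, n_perm=cfg.n_perm,
            threshold=cfg.t_threshold, connectivity=cfg.connectivity,
            seed=cfg.seed)
        cl_table = pd.DataFrame({
            "label": np.arange(1, clusters.n_clusters + 1),
            "size": clusters.sizes, "mass": clusters.masses,
            "p_fwe": clusters.p_fwe})
        cl_table.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        img = nib.Nifti1Image(clusters.labels.astype(np.int16),
                              kept[0].bold.affine)
        nib.save(img, outdir / "cluster_labels.nii")
        summary["n_clusters"] = int(clusters.n_clusters)
        summary["min_p_fwe"] = (float(np.min(clusters.p_fwe))
                                if clusters.n_clusters else None)
    _write_json(outdir / "summary.json", summary)
    return summary
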