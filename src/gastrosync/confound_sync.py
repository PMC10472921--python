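"""EGG-confound synchrony and its relation to brain-wide PLV.

Head motion, CSF, white-matter and global signals can share rhythmic
structure with the EGG (e.g. through breathing-related abdominal
motion).  This module quantifies the phase synchrony of each of the ten
nuisance series with the gastric rhythm, tests it against the same
circular-shift surrogate null used for voxels, and relates per-run
EGG-confound synchrony to the run's brain-wide PLV-delta under
different confound-regression variants -- the diagnostic that shows how
unregressed confounds inflate apparent stomach-brain coupling.

Each confound series is filtered and phase-extracted exactly like a
voxel (band-pass around the gastric peak at the volume rate, Hilbert
phase, trim), which is what makes its PLV comparable to the voxel PLVs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .bold_prep import CONFOUND_COLUMNS, ConfoundTable
from .egg import bandpass_around_peak
from .groupstats import TMap, fdr_bh
from .sync import NullSpec, PhaseSeries, instantaneous_phase, lagged_plv

__all__ = [
    "confound_plv_delta",
    "confound_sync_ttests",
    "sync_brainwide_correlation",
    "compare_variants",
]


def confound_plv_delta(
    tab: ConfoundTable,
    gastric_phase: PhaseSeries,
    peak_freq: float,
    nulls: NullSpec,
    halfwidth: float = 0.015,
    confounds: tuple[str, ...] = CONFOUND_COLUMNS,
) -> pd.DataFrame:
    """Empirical and median-null PLV of every confound with the EGG.

    Returns a frame with one row per confound: ``empirical_plv``,
    ``null_plv`` (median over surrogate lags) and a ``flagged`` column
    marking confounds whose PLV is undefined (constant series); flagged
    rows carry NaN and are skipped by downstream tests.
    """
    tab.require(confounds)
    fs = gastric_phase.fs
    n_trim = gastric_phase.n_trimmed
    gt = gastric_phase.theta
    rows = []
    series = []
    flagged = []
    for name in confounds:
        x = tab.column(name)
        if x.size != gt.size:
            raise ValueError(f"confound {name!r} has {x.size} rows, "
                             f"expected {gt.size} volumes")
        if np.ptp(x) < 1e-12:
            flagged.append(True)
            series.append(np.zeros_like(x))
            warnings.warn(f"confound {name!r} is constant: PLV undefined, flagged")
        else:
            flagged.append(False)
            series.append(bandpass_around_peak(x, fs, peak_freq, halfwidth))
    theta = instantaneous_phase(np.vstack(series), axis=-1)
    all_lags = np.concatenate(([0], nulls.lags))
    plvs = lagged_plv(theta, gt, all_lags, n_trim=n_trim)
    for i, name in enumerate(confounds):
        emp = np.nan if flagged[i] else float(plvs[i, 0])
        nul = np.nan if flagged[i] else float(np.median(plvs[i, 1:]))
        rows.append({"confound": name, "empirical_plv": emp,
                     "null_plv": nul, "flagged": flagged[i]})
    return pd.DataFrame(rows)


def confound_sync_ttests(per_run: list[pd.DataFrame], q: float = 0.05) -> pd.DataFrame:
    """Paired t-test of empirical vs median-null PLV per confound.

    `per_run` holds one :func:`confound_plv_delta` frame per run; runs
    are the paired unit.  P-values are Benjamini-Hochberg corrected
    across the tested confounds.  Confounds flagged as undefined in any
    run are skipped with a note.
    """
    if len(per_run) < 3:
        raise ValueError("paired t-tests require at least three runs")
    wide_emp = pd.DataFrame({i: df.set_index("confound")["empirical_plv"]
                             for i, df in enumerate(per_run)})
    wide_null = pd.DataFrame({i: df.set_index("confound")["null_plv"]
                              for i, df in enumerate(per_run)})
    rows = []
    for name in wide_emp.index:
        e = wide_emp.loc[name].to_numpy()
        m = wide_null.loc[name].to_numpy()
        if np.any(np.isnan(e)) or np.any(np.isnan(m)):
            rows.append({"confound": name, "t": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        d = e - m
        if np.ptp(d) < 1e-15:  # zero-variance differences
            t, p = (0.0, 1.0) if abs(d[0]) < 1e-15 else (np.sign(d[0]) * np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(e, m)
        rows.append({"confound": name, "t": float(t), "p": float(p),
                     "skipped": False})
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    sig = np.zeros(len(out), dtype=bool)
    if tested.any():
        sig[tested.to_numpy()] = fdr_bh(out.loc[tested, "p"].to_numpy(), q=q)
    out["fdr_significant"] = sig
    return out


def sync_brainwide_correlation(
    confound_plv: pd.DataFrame,
    brainwide_delta: dict[str, np.ndarray],
    q: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of EGG-confound synchrony with brain-wide PLV-delta.

    Parameters
    ----------
    confound_plv : DataFrame, runs x confounds
        Empirical PLV of each confound per run.
    brainwide_delta : dict variant -> (n_runs,) array
        Mean PLV-delta within the brain mask per run, one entry per
        preprocessing variant (typically ``minimal`` and ``main_gsr``).

    Ties are handled by average ranks (the Spearman default).  FDR
    correction is applied across confounds within each variant.
    """
    n_runs = len(confound_plv)
    if n_runs < 5:
        raise ValueError("Spearman correlation requires at least five runs")
    rows = []
    for variant, bw in brainwide_delta.items():
        bw = np.asarray(bw, dtype=float)
        if bw.size != n_runs:
            raise ValueError(f"variant {variant!r}: {bw.size} brain-wide values "
                             f"for {n_runs} runs")
        for name in confound_plv.columns:
            x = confound_plv[name].to_numpy(dtype=float)
            if np.any(np.isnan(x)):
                rows.append({"confound": name, "variant": variant,
                             "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(x, bw)
            rows.append({"confound": name, "variant": variant,
                         "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr_significant"] = False
    for variant in out["variant"].unique():
        m = (out["variant"] == variant) & out["p"].notna()
        if m.any():
            out.loc[m, "fdr_significant"] = fdr_bh(out.loc[m, "p"].to_numpy(), q=q)
    return out


def compare_variants(
    tmap_minimal: TMap,
    tmap_strict: TMap,
    threshold: float = 2.3,
) -> dict:
    """Contrast group t-maps from minimal vs strict confound regression.

    Returns the paired t over voxels of the two t-maps, and the count
    and percentage of suprathreshold (t > `threshold`) voxels under each
    variant -- the 'inflation' summary.
    """
    a = np.asarray(tmap_minimal.t, dtype=float)
    b = np.asarray(tmap_strict.t, dtype=float)
    if a.shape != b.shape:
        raise ValueError("t-maps are defined on different masks")
    diff = a - b
    if np.ptp(diff) < 1e-12:
        warnings.warn("t-map difference has zero variance across voxels")
        t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(a, b)
    n = a.size
    n_min = int(np.sum(a > threshold))
    n_str = int(np.sum(b > threshold))
    return {
        "t": float(t),
        "p": float(p),
        "n_voxels": n,
        "n_suprathreshold_minimal": n_min,
        "n_suprathreshold_strict": n_str,
        "pct_suprathreshold_minimal": 100.0 * n_min / n,
        "pct_suprathreshold_strict": 100.0 * n_str / n,
    }
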