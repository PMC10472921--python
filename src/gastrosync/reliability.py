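"""Test-retest reliability of gastric-brain synchrony and its inputs.

Four complementary checks of whether a measure behaves like a stable
within-subject trait across two runs:

* run-to-run Pearson correlation of a scalar synchrony summary (mean
  PLV-delta within a mask) across subjects;
* parcelwise similarity -- the correlation of parcel-mean PLV profiles
  between every pair of runs, summarized by a one-sample t-test against
  zero;
* reliability of the EGG peak frequency between two recording settings;
* functional-connectivity fingerprinting -- whether edge vectors from
  two runs of the same subject are more similar than those of different
  subjects (independent-samples t-test).

The one-sample t over run pairs is reported with df = n_pairs - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .bold_prep import BOLDRun

__all__ = [
    "Parcellation",
    "ReliabilityResult",
    "grid_parcellation",
    "parcel_means",
    "run_retest_correlation",
    "parcelwise_similarity",
    "egg_peak_reliability",
    "fc_fingerprint",
]


@dataclass
class Parcellation:
    """Integer parcel labels on the acquisition grid (0 = unassigned)."""

    labels: np.ndarray  # 3-D int volume
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D volume")
        ids = np.unique(self.labels)
        self.parcel_ids = ids[ids > 0]
        if self.parcel_ids.size == 0:
            raise ValueError("parcellation has no parcels")
        if self.names is None:
            self.names = [f"parcel_{i}" for i in self.parcel_ids]

    @property
    def n_parcels(self) -> int:
        return self.parcel_ids.size


@dataclass
class ReliabilityResult:
    statistic: str
    value: float
    df: int
    p: float
    n: int
    grouping: str = ""


def grid_parcellation(mask: np.ndarray, block: tuple[int, int, int] = (2, 2, 2)) -> Parcellation:
    """Blocked parcellation of a grid mask (synthetic Schaefer stand-in).

    Partitions the grid into rectangular blocks and keeps blocks that
    contain at least one mask voxel.  Purely geometric; used to emulate
    an atlas on simulated volumes.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    nb = [int(np.ceil(s / b)) for s, b in zip(mask.shape, block)]
    nxt = 1
    for i in range(nb[0]):
        for j in range(nb[1]):
            for k in range(nb[2]):
                sl = (slice(i * block[0], (i + 1) * block[0]),
                      slice(j * block[1], (j + 1) * block[1]),
                      slice(k * block[2], (k + 1) * block[2]))
                if mask[sl].any():
                    labels[sl] = nxt
                    nxt += 1
    labels[~mask] = 0
    return Parcellation(labels=labels)


def parcel_means(values: np.ndarray, mask: np.ndarray, parc: Parcellation) -> np.ndarray:
    """Mean of a per-voxel map (or voxels x T matrix) within each parcel.

    Parcels empty within the mask are dropped with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values, dtype=float)
    lab_flat = parc.labels[mask]
    out = []
    for pid in parc.parcel_ids:
        sel = lab_flat == pid
        if not sel.any():
            warnings.warn(f"parcel {pid} empty within mask: dropped")
            continue
        out.append(values[sel].mean(axis=0))
    return np.asarray(out)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def run_retest_correlation(
    values_run1: np.ndarray, values_run2: np.ndarray
) -> ReliabilityResult:
    """Pearson correlation of a per-subject summary across two runs."""
    x = np.asarray(values_run1, dtype=float)
    y = np.asarray(values_run2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired per-subject vectors required")
    n = x.size
    if n < 4:
        raise ValueError("retest correlation requires at least four subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = _pearson(x, y)
    return ReliabilityResult(statistic="pearson_r", value=r, df=n - 2, p=p,
                             n=n, grouping="within")


def parcelwise_similarity(
    maps_per_run: list[np.ndarray], mask: np.ndarray, parc: Parcellation
) -> tuple[np.ndarray, ReliabilityResult]:
    """Pairwise similarity of parcel-mean maps across all runs.

    For every unordered run pair, the Pearson correlation of the two
    parcel-mean vectors; returns the pair correlations and a one-sample
    t-test of those correlations against zero (df = n_pairs - 1, no
    Fisher transform).
    """
    if len(maps_per_run) < 3:
        raise ValueError("parcelwise similarity requires at least three runs")
    profiles = [parcel_means(m, mask, parc) for m in maps_per_run]
    rs = []
    for a, b in combinations(profiles, 2):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn("zero-variance parcel profile: pair skipped")
            continue
        rs.append(_pearson(a, b)[0])
    rs = np.asarray(rs)
    t, p = stats.ttest_1samp(rs, 0.0)
    res = ReliabilityResult(statistic="one_sample_t", value=float(t),
                            df=rs.size - 1, p=float(p), n=rs.size,
                            grouping="all-pairs")
    return rs, res


def egg_peak_reliability(
    lab_peaks: np.ndarray, scanner_peaks: np.ndarray
) -> ReliabilityResult:
    """Pearson correlation of gastric peak frequency across settings."""
    return run_retest_correlation(lab_peaks, scanner_peaks)


def _edge_vector(run: BOLDRun, parc: Parcellation) -> np.ndarray:
    ts = parcel_means(run.data, run.mask, parc)  # parcels x T
    sd = ts.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance parcel series dropped "
                      "from the edge set")
        ts = ts[keep]
    fc = np.corrcoef(ts)
    iu = np.triu_indices_from(fc, k=1)
    return fc[iu]


def fc_fingerprint(
    runs: list[BOLDRun],
    subject_ids: list[str],
    parc: Parcellation,
    exclude_shared_run: bool = False,
) -> tuple[ReliabilityResult, np.ndarray, np.ndarray]:
    """Functional-connectivity fingerprinting across runs.

    Each run is reduced to its vector of unique functional-connectivity
    edges (upper triangle of the parcel-mean correlation matrix); for
    every unordered run pair the Pearson correlation of the two edge
    vectors is computed.  Pairs of runs from the same subject form the
    *within* group, all others the *between* group, and the difference
    is assessed with an independent two-sample t-test.

    By default every cross-subject run pair enters the between group,
    so the same run contributes to many pairs; with
    `exclude_shared_run` the between group is restricted to each
    subject's first run, a stricter bookkeeping in which no run is
    reused across the between pairs of a given subject pair.
    """
    if len(runs) != len(subject_ids):
        raise ValueError("one subject id per run is required")
    if len(set(subject_ids)) < 2:
        raise ValueError("fingerprinting requires at least two subjects")
    edges = [_edge_vector(r, parc) for r in runs]
    first_run = {}
    for i, s in enumerate(subject_ids):
        first_run.setdefault(s, i)
    within, between = [], []
    for (i, j) in combinations(range(len(runs)), 2):
        same = subject_ids[i] == subject_ids[j]
        if exclude_shared_run and not same:
            if i != first_run[subject_ids[i]] or j != first_run[subject_ids[j]]:
                continue
        r = _pearson(edges[i], edges[j])[0]
        if same:
            within.append(r)
        else:
            between.append(r)
    within = np.asarray(within)
    between = np.asarray(between)
    if within.size < 2 or between.size < 2:
        raise ValueError("need at least two pairs in each group")
    t, p = stats.ttest_ind(within, between)
    res = ReliabilityResult(statistic="independent_t", value=float(t),
                            df=within.size + between.size - 2, p=float(p),
                            n=within.size + between.size,
                            grouping="within-vs-between")
    return res, within, between
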