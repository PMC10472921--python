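"""Group-level inference for gastric-brain synchrony maps.

Implements the second-level battery: a paired t-test between subjects'
empirical and median-surrogate PLV maps, extraction of suprathreshold
clusters and their *mass* (the sum of t-values over a connected
component), family-wise-error control by a sign-flip max-mass
permutation test, Benjamini-Hochberg FDR for vectors of p-values, Dice
similarity between binary maps, and a hemisphere-symmetric spin
permutation test for spatial similarity of surface maps.

The cluster test is one-sided (t > threshold, positive synchrony only),
uses 26-connectivity by default, and reports permutation p-values with
the +1 correction so no p can be exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, spatial
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSample",
    "TMap",
    "ClusterSet",
    "SphereAnnotation",
    "SpinResult",
    "paired_t_map",
    "clusters_and_mass",
    "signflip_cluster_test",
    "fdr_bh",
    "dice_similarity",
    "random_rotation",
    "spin_test",
]


@dataclass
class GroupSample:
    """Per-subject empirical and median-null PLV maps (runs averaged)."""

    empirical: np.ndarray  # (subjects, voxels)
    null_median: np.ndarray

    def __post_init__(self) -> None:
        self.empirical = np.atleast_2d(np.asarray(self.empirical, dtype=float))
        self.null_median = np.atleast_2d(np.asarray(self.null_median, dtype=float))
        if self.empirical.shape != self.null_median.shape:
            raise ValueError("empirical and null_median shapes differ")

    @property
    def n_subjects(self) -> int:
        return self.empirical.shape[0]

    @property
    def differences(self) -> np.ndarray:
        return self.empirical - self.null_median


@dataclass
class TMap:
    """Voxelwise t statistics with degrees of freedom."""

    t: np.ndarray
    df: int
    zero_variance: np.ndarray | None = None


@dataclass
class ClusterSet:
    """Suprathreshold clusters of a t-map.

    `labels` is an integer volume (0 = background); `masses` and `sizes`
    are indexed by cluster label - 1.  `p_fwe` is filled in by the
    permutation test.
    """

    labels: np.ndarray
    masses: np.ndarray
    sizes: np.ndarray
    threshold: float
    connectivity: int
    p_fwe: np.ndarray | None = None
    null_max_mass: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def n_clusters(self) -> int:
        return len(self.masses)

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean volume of voxels in FWE-significant clusters."""
        if self.p_fwe is None:
            raise ValueError("run the permutation test first")
        out = np.zeros(self.labels.shape, dtype=bool)
        for k in range(self.n_clusters):
            if self.p_fwe[k] < alpha:
                out |= self.labels == k + 1
        return out


def paired_t_map(sample: GroupSample) -> TMap:
    """Paired t-test of empirical vs median-null PLV across subjects.

    ``t = mean(d) / (sd(d) / sqrt(n))`` per voxel with the n-1
    denominator in the SD; zero-variance voxels get t = 0 and are
    flagged.
    """
    n = sample.n_subjects
    if n < 3:
        raise ValueError("paired t-map requires at least three subjects")
    d = sample.differences
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~zero)
    return TMap(t=t, df=n - 1, zero_variance=zero)


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def clusters_and_mass(
    tmap: TMap | np.ndarray,
    grid_shape: tuple[int, int, int],
    mask: np.ndarray,
    threshold: float = 2.3,
    connectivity: int = 26,
) -> ClusterSet:
    """Connected components of {t > threshold} and their masses.

    `tmap` may be a TMap or a flat vector over mask voxels.  An empty
    cluster set (no suprathreshold voxel) is a valid outcome.
    """
    t = tmap.t if isinstance(tmap, TMap) else np.asarray(tmap, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(grid_shape):
        raise ValueError("mask does not match grid_shape")
    if t.size != int(mask.sum()):
        raise ValueError("t-map length does not match mask voxel count")
    tvol = np.zeros(grid_shape, dtype=float)
    tvol[mask] = t
    supra = tvol > threshold
    labels, n = ndimage.label(supra, structure=_structure(connectivity))
    if n == 0:
        return ClusterSet(labels=labels, masses=np.empty(0), sizes=np.empty(0, int),
                          threshold=threshold, connectivity=connectivity)
    masses = ndimage.sum_labels(tvol, labels, index=np.arange(1, n + 1))
    sizes = ndimage.sum_labels(supra.astype(int), labels, index=np.arange(1, n + 1))
    return ClusterSet(labels=labels, masses=np.asarray(masses, float),
                      sizes=np.asarray(sizes, int),
                      threshold=threshold, connectivity=connectivity)


def _max_cluster_mass(tvol: np.ndarray, threshold: float, structure: np.ndarray) -> float:
    supra = tvol > threshold
    if not supra.any():
        return 0.0
    labels, n = ndimage.label(supra, structure=structure)
    masses = ndimage.sum_labels(tvol, labels, index=np.arange(1, n + 1))
    return float(np.max(masses))


def signflip_cluster_test(
    sample: GroupSample,
    grid_shape: tuple[int, int, int],
    mask: np.ndarray,
    n_perm: int = 10_000,
    threshold: float = 2.3,
    connectivity: int = 26,
    seed: int | np.random.Generator | None = None,
) -> ClusterSet:
    """Max-mass sign-flip permutation test, FWE corrected.

    Each permutation multiplies every subject's difference map by an
    independent random sign (equivalent to swapping that subject's
    empirical and null maps), recomputes the one-sided t-map, and
    records the maximum cluster mass.  For each observed cluster,
    ``p_fwe = (1 + #{null max >= mass}) / (1 + n_perm)``.
    """
    n = sample.n_subjects
    if n < 2:
        raise ValueError("sign-flip test is degenerate with fewer than two subjects")
    if n < 5:
        warnings.warn("fewer than five subjects: permutation p-values are coarse")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    observed = paired_t_map(sample)
    clusters = clusters_and_mass(observed, grid_shape, mask, threshold, connectivity)

    d = sample.differences
    sq_sum = np.sum(d * d, axis=0)  # invariant under sign flips
    structure = _structure(connectivity)
    mask = np.asarray(mask, dtype=bool)

    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = (flips @ d) / n
    # sample variance from the flip-invariant sum of squares
    var = np.maximum(sq_sum[None, :] - n * means**2, 0.0) / (n - 1)
    sd = np.sqrt(var)
    tnull = np.zeros_like(means)
    np.divide(means, sd / np.sqrt(n), out=tnull, where=sd > 0)

    null_max = np.empty(n_perm)
    tvol = np.zeros(grid_shape, dtype=float)
    for p in range(n_perm):
        tvol[mask] = tnull[p]
        null_max[p] = _max_cluster_mass(tvol, threshold, structure)

    if clusters.n_clusters:
        # ties (e.g. a sign pattern reproducing the identity) count as
        # exceedances; the tolerance makes the tie count robust to
        # summation-order float noise
        tol = 1e-9 * np.maximum(1.0, np.abs(clusters.masses[:, None]))
        exceed = (null_max[None, :] >= clusters.masses[:, None] - tol).sum(axis=1)
        clusters.p_fwe = (1.0 + exceed) / (1.0 + n_perm)
    else:
        clusters.p_fwe = np.empty(0)
    clusters.null_max_mass = null_max
    return clusters


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level `q`."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def dice_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A&B| / (|A| + |B|) of two boolean maps.

    Returns 0 (with a warning) when both maps are empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("both maps empty: Dice defined as 0")
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / denom


@dataclass
class SphereAnnotation:
    """Binary label map on unit-sphere vertices of one hemisphere."""

    coords: np.ndarray  # (n_vertices, 3), unit norm
    labels: np.ndarray  # boolean
    hemisphere: str  # "L" or "R"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("vertex coordinates must be unit vectors")
        if self.labels.shape != (self.coords.shape[0],):
            raise ValueError("labels must match vertex count")


@dataclass
class SpinResult:
    dice_empirical: float
    dice_null: np.ndarray
    p: float
    n_perm: int


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation (QR of a Gaussian matrix, det +1)."""
    g = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(g)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q

#: Sagittal mirror: negate the left-right (x) coordinate.
_MIRROR = np.diag([-1.0, 1.0, 1.0])


def _rotate_labels(ann: SphereAnnotation, R: np.ndarray,
                   tree: spatial.cKDTree | None = None,
                   method: str = "kdtree") -> np.ndarray:
    """Labels of the annotation after rotating its map by `R`.

    The rotated map's value at vertex v is the original label at the
    vertex nearest to R^T v (nearest-neighbour reassignment on the same
    vertex set, so labels never leave the vertex set).
    """
    query = ann.coords @ R  # row i = R^T coords[i]
    if method == "exact":
        # argmax of dot products; ties broken at the lowest vertex index
        idx = np.argmax(query @ ann.coords.T, axis=1)
    else:
        if tree is None:
            tree = spatial.cKDTree(ann.coords)
        _, idx = tree.query(query, k=1)
    return ann.labels[idx]


def spin_test(
    fixed: tuple[SphereAnnotation, SphereAnnotation],
    target: tuple[SphereAnnotation, SphereAnnotation],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    method: str = "kdtree",
) -> SpinResult:
    """Hemisphere-symmetric spin permutation test of spatial similarity.

    The empirical statistic is the Dice similarity of the fixed and
    target annotations over both hemispheres.  Each permutation draws a
    uniform random rotation R, applies it to the right-hemisphere target
    sphere and the sagittally mirrored rotation M R M to the left (so a
    bilaterally symmetric map stays symmetric), reassigns labels by
    nearest neighbour, and recomputes the Dice;
    ``p = (1 + #{null >= empirical}) / (1 + n_perm)``.
    """
    fl, fr = fixed
    tl, tr = target
    if fl.hemisphere != "L" or fr.hemisphere != "R":
        raise ValueError("fixed pair must be ordered (L, R)")
    if tl.hemisphere != "L" or tr.hemisphere != "R":
        raise ValueError("target pair must be ordered (L, R)")
    if tl.coords.shape != fl.coords.shape or tr.coords.shape != fr.coords.shape:
        raise ValueError("fixed and target vertex sets must match")
    if not (tl.labels.any() or tr.labels.any()):
        raise ValueError("target annotation has no labelled vertex")
    if not (fl.labels.any() or fr.labels.any()):
        raise ValueError("fixed annotation has no labelled vertex")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    fixed_labels = np.concatenate([fl.labels, fr.labels])
    emp = dice_similarity(fixed_labels, np.concatenate([tl.labels, tr.labels]))

    tree_l = spatial.cKDTree(tl.coords) if method == "kdtree" else None
    tree_r = spatial.cKDTree(tr.coords) if method == "kdtree" else None
    null = np.empty(n_perm)
    for p in range(n_perm):
        R = random_rotation(rng)
        R_left = _MIRROR @ R @ _MIRROR
        lab_r = _rotate_labels(tr, R, tree_r, method)
        lab_l = _rotate_labels(tl, R_left, tree_l, method)
        null[p] = dice_similarity(fixed_labels, np.concatenate([lab_l, lab_r]))
    pval = (1.0 + np.sum(null >= emp)) / (1.0 + n_perm)
    return SpinResult(dice_empirical=emp, dice_null=null, p=pval, n_perm=n_perm)
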