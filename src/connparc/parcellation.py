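"""Connectivity-driven parcellation of the seed and cross-subject consensus.

Each subject's seed voxels are clustered with k-means (k-means++ / Lloyd,
best of several restarts) in the feature space of their CCM rows — a voxel's
correlation profile to every other seed voxel. Because k-means labels are
arbitrary per subject, labels are harmonized across the cohort by Hungarian
assignment of cluster-mean connectivity fingerprints to a reference (or, as a
fallback, by ranking clusters along the medial->lateral anatomical axis).
Harmonized labels are then summed voxelwise into per-cluster consensus count
maps; thresholding at a fraction of the cohort defines the final population
cluster boundaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .connectivity import ConnectivityMatrix, CrossCorrelation, CrossCorrelationMatrix
from .volio import voxel_volume_mm3, world_coordinates

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectParcellation",
    "ConsensusMap",
    "PatternResult",
    "ConnectivityParcellator",
    "ConsensusLabeler",
    "kmeans_parcellate",
    "harmonize_labels",
    "build_consensus",
    "classify_pattern",
    "cluster_volumes",
    "consensus_ari",
]


@dataclass
class SubjectParcellation:
    """Per-subject cluster labels over the seed voxel index.

    ``labels[i]`` is in 1..k for voxels clustered from the CCM and 0 for
    voxels excluded from the CCM (constant/zero fingerprints). ``inertia`` is
    the k-means within-cluster sum of squared distances of the winning
    restart. ``cluster_fingerprints`` (k x T mean streamline counts) supports
    connectivity-based label harmonization.
    """

    subject_id: str
    seed_voxel_index: np.ndarray  # (V, 3)
    labels: np.ndarray  # (V,) ints in 0..k
    k: int
    inertia: float
    affine: np.ndarray | None = None
    cluster_fingerprints: np.ndarray | None = None  # (k, T)

    def label_volume(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        vol = np.zeros(grid_shape, dtype=np.int16)
        v = self.seed_voxel_index
        vol[v[:, 0], v[:, 1], v[:, 2]] = self.labels
        return vol

    def relabeled(self, permutation: np.ndarray) -> "SubjectParcellation":
        """Return a copy with cluster c renamed to ``permutation[c-1]``."""
        lut = np.zeros(self.k + 1, dtype=self.labels.dtype)
        lut[1:] = np.asarray(permutation)
        fp = None
        if self.cluster_fingerprints is not None:
            fp = np.empty_like(self.cluster_fingerprints)
            fp[np.asarray(permutation) - 1] = self.cluster_fingerprints
        return SubjectParcellation(
            subject_id=self.subject_id,
            seed_voxel_index=self.seed_voxel_index,
            labels=lut[self.labels],
            k=self.k,
            inertia=self.inertia,
            affine=self.affine,
            cluster_fingerprints=fp,
        )


@dataclass
class ConsensusMap:
    """Cross-subject consensus: per-cluster subject counts and final labels.

    ``counts[c-1, x, y, z]`` is the number of subjects carrying label c at
    that voxel. A voxel joins cluster c's final mask iff its count reaches
    ``ceil(threshold_fraction * n_subjects)``; a voxel eligible for several
    clusters goes to the one with the highest count (tie -> lowest cluster
    index). ``final_labels`` is 0 where no cluster passes the threshold.
    """

    counts: np.ndarray  # (k, X, Y, Z) ints
    n_subjects: int
    threshold_fraction: float
    final_labels: np.ndarray  # (X, Y, Z) ints in 0..k
    affine: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.counts.shape[0]


@dataclass
class PatternResult:
    """Outcome of the medial->lateral arrangement check (per hemisphere)."""

    is_mediolateral: bool
    centroid_abs_x: dict[str, np.ndarray]  # hemisphere -> per-cluster |x| (mm)
    contiguous: dict[str, np.ndarray]  # hemisphere -> per-cluster bool
    order: dict[str, tuple[int, ...]] = field(default_factory=dict)


class ConnectivityParcellator(ClusterMixin, BaseEstimator):
    """K-means parcellation of seed voxels from their connectivity.

    Fit on a (V, T) seed-voxel x target fingerprint matrix. By default the
    matrix is first turned into its cross-correlation matrix (CCM) and the
    CCM *rows* are the clustering features, so voxels cluster together when
    they correlate with the rest of the seed in the same way. Lloyd's
    algorithm with k-means++ initialization is run ``n_restarts`` times and
    the restart with the lowest inertia wins; deterministic given
    ``random_state``.

    Parameters
    ----------
    n_clusters : int, default 3
    n_restarts : int, default 20
        Number of k-means++ restarts (scikit-learn's ``n_init``).
    random_state : int or None
    feature_space : {"ccm", "counts"}, default "ccm"
        Cluster CCM rows (default) or raw fingerprints.

    Attributes
    ----------
    labels_ : (V,) int — cluster labels 0..k-1; -1 for voxels excluded from
        the CCM (constant/zero fingerprints), following the scikit-learn
        noise-label convention.
    inertia_ : float — within-cluster sum of squared distances.
    usable_mask_ : (V,) bool.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_restarts: int = 20,
        random_state: int | None = None,
        feature_space: str = "ccm",
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.feature_space = feature_space

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.feature_space not in ("ccm", "counts"):
            raise ValueError("feature_space must be 'ccm' or 'counts'")
        if self.feature_space == "ccm":
            cc = CrossCorrelation().fit(X)
            features = cc.transform(X)
            usable = cc.used_mask_
        else:
            features = X
            usable = np.ones(len(X), dtype=bool)
        if self.n_clusters > features.shape[0]:
            raise ValueError(
                f"k={self.n_clusters} exceeds the {features.shape[0]} usable seed voxels"
            )
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_restarts,
            algorithm="lloyd",
            random_state=self.random_state,
        ).fit(features)
        self.usable_mask_ = usable
        self.labels_ = np.full(len(X), -1, dtype=int)
        self.labels_[usable] = km.labels_
        self.inertia_ = float(km.inertia_)
        self.cluster_centers_ = km.cluster_centers_
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class ConsensusLabeler(BaseEstimator):
    """Consensus estimator over a stack of harmonized label volumes.

    Fit on an (N, X, Y, Z) integer array of per-subject label volumes
    (values 0..k). Produces per-cluster subject-count maps and the
    thresholded, overlap-resolved final label volume.

    Attributes
    ----------
    counts_ : (k, X, Y, Z) int
    final_labels_ : (X, Y, Z) int in 0..k
    min_subjects_ : int — ceil(threshold_fraction * n_subjects).
    """

    def __init__(self, threshold_fraction: float = 0.5):
        self.threshold_fraction = threshold_fraction

    def fit(self, X, y=None):
        L = np.asarray(X)
        if L.ndim != 4:
            raise ValueError("expected an (n_subjects, X, Y, Z) label array")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")
        n = L.shape[0]
        k = int(L.max())
        counts = np.stack([(L == c).sum(axis=0) for c in range(1, k + 1)]).astype(np.int32)
        thr = math.ceil(self.threshold_fraction * n)
        eligible = counts >= thr
        # highest count wins among eligible clusters; np.argmax resolves ties
        # toward the lowest cluster index
        masked = np.where(eligible, counts, -1)
        winner = masked.argmax(axis=0) + 1
        final = np.where(eligible.any(axis=0), winner, 0).astype(np.int16)
        ties = (eligible.sum(axis=0) > 1) & (
            (counts == counts.max(axis=0)).sum(axis=0) > 1
        )
        if ties.any():
            logger.info("consensus: %d voxels with tied top counts -> lowest index", ties.sum())
        for c in range(1, k + 1):
            if not np.any(final == c):
                logger.warning("consensus: final cluster %d is empty", c)
        self.n_subjects_ = n
        self.min_subjects_ = thr
        self.counts_ = counts
        self.final_labels_ = final
        return self


def kmeans_parcellate(
    ccm: CrossCorrelationMatrix,
    k: int = 3,
    seed: int | None = 0,
    restarts: int = 20,
    cm: ConnectivityMatrix | None = None,
) -> SubjectParcellation:
    """Cluster a subject's usable seed voxels from the rows of its CCM.

    Labels are 1..k over usable voxels, 0 for excluded ones. If the source
    connectivity matrix *cm* is supplied, per-cluster mean fingerprints are
    attached (needed by connectivity-based harmonization).
    """
    n_used = ccm.ccm.shape[0]
    if k > n_used:
        raise ValueError(f"k={k} exceeds the {n_used} usable seed voxels")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=restarts,
        algorithm="lloyd", random_state=seed,
    ).fit(ccm.ccm)

    n_total = n_used + len(ccm.excluded_voxels)
    labels = np.zeros(n_total, dtype=np.int16)
    labels[ccm.used_voxels] = km.labels_ + 1

    fingerprints = None
    voxel_index = np.zeros((n_total, 3), dtype=np.intp)
    affine = None
    if cm is not None:
        voxel_index = cm.seed_voxel_index
        affine = cm.affine
        fingerprints = np.stack(
            [cm.counts[labels == c].mean(axis=0) for c in range(1, k + 1)]
        )
    return SubjectParcellation(
        subject_id=ccm.subject_id,
        seed_voxel_index=voxel_index,
        labels=labels,
        k=k,
        inertia=float(km.inertia_),
        affine=affine,
        cluster_fingerprints=fingerprints,
    )


def _fingerprint_cost(sub_fp: np.ndarray, ref_fp: np.ndarray) -> np.ndarray:
    """Squared-distance cost between proportion-normalized fingerprints."""
    a = sub_fp / sub_fp.sum(axis=1, keepdims=True)
    b = ref_fp / ref_fp.sum(axis=1, keepdims=True)
    return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)


def _assign(cost: np.ndarray) -> np.ndarray:
    """Minimum-cost assignment; rows = subject clusters, cols = reference.
    Returns permutation p with subject cluster c -> reference label p[c-1]."""
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(cost.shape[0], dtype=int)
    perm[rows] = cols + 1
    k = cost.shape[0]
    if k <= 5:  # cheap exact tie audit on small k
        best = cost[rows, cols].sum()
        minima = [
            p for p in itertools.permutations(range(k))
            if abs(cost[np.arange(k), p].sum() - best) < 1e-12
        ]
        if len(minima) > 1:
            perm = np.asarray(minima[0]) + 1  # lowest-label-first tie break
            logger.info("harmonization: %d tied optimal assignments; "
                        "taking lexicographically first", len(minima))
    return perm


def _anatomical_rank(parc: SubjectParcellation) -> np.ndarray:
    """Permutation renaming clusters by increasing |world x| of centroid."""
    if parc.affine is None:
        raise ValueError("anatomical-x harmonization needs voxel coordinates and affine")
    absx = np.empty(parc.k)
    for c in range(1, parc.k + 1):
        vox = parc.seed_voxel_index[parc.labels == c]
        if len(vox) == 0:
            raise ValueError(f"cluster {c} empty; cannot rank anatomically")
        absx[c - 1] = np.abs(world_coordinates(vox, parc.affine)[:, 0]).mean()
    perm = np.empty(parc.k, dtype=int)
    perm[np.argsort(absx, kind="stable")] = np.arange(1, parc.k + 1)
    return perm


def harmonize_labels(
    parcellations: list[SubjectParcellation],
    reference: str | np.ndarray = "cohort-median",
) -> list[SubjectParcellation]:
    """Make cluster labels comparable across subjects.

    ``reference`` may be:

    * an explicit (k, T) fingerprint-centroid array — each subject's
      cluster-mean fingerprints are matched to it by minimum-cost Hungarian
      assignment on proportion-normalized squared distances;
    * ``"cohort-median"`` (default) — subjects are first aligned to the first
      subject, the elementwise median of the aligned fingerprints becomes the
      reference, and all subjects are re-aligned to it; finally one *global*
      permutation (shared by every subject, so agreement is unaffected)
      renames the cohort's clusters by their pooled medial->lateral centroid
      order, giving label 1 = most medial. Idempotent;
    * ``"anatomical-x"`` — clusters are ranked by the mean |world x| of their
      voxels, so label 1 is the most medial cluster and label k the most
      lateral.
    """
    ks = {p.k for p in parcellations}
    if len(ks) != 1:
        raise ValueError(f"parcellations disagree on k: {sorted(ks)}")

    if isinstance(reference, str) and reference == "anatomical-x":
        return [p.relabeled(_anatomical_rank(p)) for p in parcellations]

    for p in parcellations:
        if p.cluster_fingerprints is None:
            raise ValueError(
                f"subject {p.subject_id} lacks cluster fingerprints; "
                "connectivity-based harmonization needs them"
            )
    if isinstance(reference, np.ndarray):
        ref = reference
    else:
        if reference != "cohort-median":
            raise ValueError(f"unknown reference {reference!r}")
        first = parcellations[0].cluster_fingerprints
        aligned = [
            p.relabeled(_assign(_fingerprint_cost(p.cluster_fingerprints, first)))
            for p in parcellations
        ]
        ref = np.median([p.cluster_fingerprints for p in aligned], axis=0)
    out = [
        p.relabeled(_assign(_fingerprint_cost(p.cluster_fingerprints, ref)))
        for p in parcellations
    ]
    if not isinstance(reference, np.ndarray) and all(
        p.affine is not None and p.seed_voxel_index.any() for p in out
    ):
        out = _orient_medial_lateral(out)
    return out


def _orient_medial_lateral(parcs: list[SubjectParcellation]) -> list[SubjectParcellation]:
    """Apply one cohort-wide permutation so label 1 is the most medial
    cluster (smallest pooled mean |world x|) and label k the most lateral."""
    k = parcs[0].k
    absx = np.zeros(k)
    weight = np.zeros(k)
    for p in parcs:
        xw = np.abs(world_coordinates(p.seed_voxel_index, p.affine)[:, 0])
        for c in range(1, k + 1):
            sel = p.labels == c
            absx[c - 1] += xw[sel].sum()
            weight[c - 1] += sel.sum()
    mean_absx = np.where(weight > 0, absx / np.maximum(weight, 1), np.inf)
    perm = np.empty(k, dtype=int)
    perm[np.argsort(mean_absx, kind="stable")] = np.arange(1, k + 1)
    return [p.relabeled(perm) for p in parcs]


def build_consensus(
    parcellations: list[SubjectParcellation],
    threshold_fraction: float = 0.5,
    grid_shape: tuple[int, int, int] | None = None,
) -> ConsensusMap:
    """Sum harmonized per-subject labels into consensus count maps and
    threshold them into the final population parcellation."""
    if grid_shape is None:
        mx = np.max([p.seed_voxel_index.max(axis=0) for p in parcellations], axis=0)
        grid_shape = tuple(int(m) + 1 for m in mx)
    stack = np.stack([p.label_volume(grid_shape) for p in parcellations])
    est = ConsensusLabeler(threshold_fraction=threshold_fraction).fit(stack)
    k = parcellations[0].k
    counts = est.counts_
    if counts.shape[0] < k:  # some label absent everywhere
        pad = np.zeros((k - counts.shape[0],) + counts.shape[1:], dtype=counts.dtype)
        counts = np.concatenate([counts, pad])
    return ConsensusMap(
        counts=counts,
        n_subjects=len(parcellations),
        threshold_fraction=threshold_fraction,
        final_labels=est.final_labels_,
        affine=parcellations[0].affine,
    )


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def classify_pattern(
    label_volume: np.ndarray, affine: np.ndarray, k: int | None = None
) -> PatternResult:
    """Check for the medial->lateral cluster arrangement.

    Per hemisphere (sign of world x), cluster centroids are computed as mean
    |x| (distance from the midline); the pattern holds when |x| increases
    strictly with the cluster label (1 = most medial ... k = most lateral),
    every cluster is present, and each cluster is a single 6-connected
    component. The overall flag is the conjunction over hemispheres that
    contain labeled voxels. Passing *k* explicitly makes a fully absent
    cluster fail the check instead of silently shrinking the problem.
    """
    label_volume = np.asarray(label_volume)
    if k is None:
        k = int(label_volume.max())
    if k < 2:
        raise ValueError("need at least 2 clusters to classify an arrangement")
    if not np.any(label_volume > 0):
        return PatternResult(False, {}, {}, {})
    vox = np.argwhere(label_volume > 0)
    x_world = world_coordinates(vox, affine)[:, 0]
    labels_flat = label_volume[vox[:, 0], vox[:, 1], vox[:, 2]]

    centroid, contig, order = {}, {}, {}
    ok = True
    for hemi, sel in (("left", x_world < 0), ("right", x_world >= 0)):
        if not sel.any():
            continue
        absx = np.full(k, np.nan)
        cont = np.zeros(k, dtype=bool)
        hemi_vol = np.zeros_like(label_volume)
        hv = vox[sel]
        hemi_vol[hv[:, 0], hv[:, 1], hv[:, 2]] = labels_flat[sel]
        for c in range(1, k + 1):
            in_c = sel & (labels_flat == c)
            if in_c.any():
                absx[c - 1] = np.abs(x_world[in_c]).mean()
                _, ncomp = ndimage.label(hemi_vol == c, structure=_SIX_CONN)
                cont[c - 1] = ncomp == 1
        centroid[hemi] = absx
        contig[hemi] = cont
        present = ~np.isnan(absx)
        order[hemi] = tuple(int(c) + 1 for c in np.argsort(absx[present]))
        hemi_ok = (
            present.all()
            and cont.all()
            and bool(np.all(np.diff(absx) > 0))
        )
        ok = ok and bool(hemi_ok)
    return PatternResult(
        is_mediolateral=bool(ok), centroid_abs_x=centroid, contiguous=contig, order=order
    )


def cluster_volumes(final_labels: np.ndarray, affine: np.ndarray, k: int | None = None) -> np.ndarray:
    """Per-cluster volume in mm^3: voxel count x |det| of the affine block."""
    final_labels = np.asarray(final_labels)
    if k is None:
        k = int(final_labels.max())
    vv = voxel_volume_mm3(affine)
    return np.array([(final_labels == c).sum() * vv for c in range(1, k + 1)])


def consensus_ari(final_labels: np.ndarray, truth_labels: np.ndarray) -> float:
    """Adjusted Rand index between two label volumes over the voxels the
    truth marks as seed (chance-corrected recovery of the planted clusters)."""
    m = np.asarray(truth_labels) > 0
    return float(adjusted_rand_score(np.asarray(truth_labels)[m], np.asarray(final_labels)[m]))
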