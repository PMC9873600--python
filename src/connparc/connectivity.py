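"""Seed-to-target connectivity matrices, cross-correlation matrices and
connection-probability maps.

The connectivity matrix tabulates, per seed voxel, the streamline count
reaching each target region (the region-collapsed form of a tractography
"matrix 2"). The cross-correlation matrix (CCM) is the voxel-by-voxel Pearson
correlation of those connectivity fingerprints and is the feature space for
the parcellation. ``proj_thresh`` converts counts to per-voxel connection
probabilities on voxels with sufficient total samples, mirroring the FSL
utility of the same name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .volio import check_same_grid, seed_scan_order

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "CrossCorrelationMatrix",
    "ConnectionProbabilityMaps",
    "CrossCorrelation",
    "ProjThresh",
    "build_connectivity_matrix",
    "build_ccm",
    "proj_thresh",
    "mean_probability_per_target",
]

DEFAULT_PROJ_THRESHOLD = 1250


@dataclass
class ConnectivityMatrix:
    """Per-subject seed-voxel x target streamline-count table.

    ``counts[i, j]`` is the number of streamline samples seeded at
    ``seed_voxel_index[i]`` that terminated in target ``target_names[j]``.
    Rows follow the deterministic x-fastest scan order of the seed mask.
    """

    subject_id: str
    seed_voxel_index: np.ndarray  # (V, 3) int voxel coordinates
    counts: np.ndarray  # (V, T) nonnegative ints
    target_names: tuple[str, ...]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("streamline counts must be nonnegative")
        if self.counts.shape != (len(self.seed_voxel_index), len(self.target_names)):
            raise ValueError("counts shape inconsistent with voxel index / target names")


@dataclass
class CrossCorrelationMatrix:
    """Pearson correlations between seed-voxel connectivity fingerprints.

    ``ccm`` covers only *usable* voxels (nonconstant, nonzero fingerprints);
    ``used_voxels``/``excluded_voxels`` index into the parent connectivity
    matrix's row order, with a reason code per exclusion.
    """

    subject_id: str
    ccm: np.ndarray  # (V_used, V_used)
    used_voxels: np.ndarray  # (V_used,) int indices
    excluded_voxels: dict[int, str] = field(default_factory=dict)


@dataclass
class ConnectionProbabilityMaps:
    """proj_thresh output: per-voxel, per-target connection probabilities.

    Probabilities sum to 1 across targets on suprathreshold voxels (total
    samples > threshold) and are identically 0 on sub-threshold voxels.
    """

    subject_id: str
    seed_voxel_index: np.ndarray  # (V, 3)
    probabilities: np.ndarray  # (V, T) in [0, 1]
    suprathreshold_mask: np.ndarray  # (V,) bool
    target_names: tuple[str, ...]
    threshold: float = DEFAULT_PROJ_THRESHOLD
    affine: np.ndarray | None = None


class CrossCorrelation(TransformerMixin, BaseEstimator):
    """Transformer mapping a (V, T) fingerprint matrix to the (V_used, V_used)
    Pearson cross-correlation matrix of its rows.

    Rows that are constant (zero variance, including all-zero rows) carry no
    correlation information and are excluded; their indices and reason codes
    are exposed as fitted attributes.

    Parameters
    ----------
    row_normalize : bool, default False
        Divide each fingerprint by its total count before correlating.
        Pearson correlation is invariant to positive row scaling, so this is
        exposed for parity with probability-space workflows but does not
        change the CCM.

    Attributes
    ----------
    used_mask_ : (V,) bool — rows entering the CCM.
    excluded_reasons_ : dict row index -> reason code ("zero" | "constant").
    """

    def __init__(self, row_normalize: bool = False):
        self.row_normalize = row_normalize

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 targets to correlate fingerprints")
        zero = ~np.any(X != 0, axis=1)
        constant = np.ptp(X, axis=1) == 0
        self.excluded_reasons_ = {
            int(i): ("zero" if zero[i] else "constant")
            for i in np.nonzero(constant)[0]
        }
        self.used_mask_ = ~constant
        if self.used_mask_.sum() < 2:
            raise ValueError(
                f"fewer than 2 usable fingerprint rows ({self.used_mask_.sum()})"
            )
        if self.excluded_reasons_:
            logger.info(
                "CCM: excluding %d constant/zero fingerprint voxels: %s",
                len(self.excluded_reasons_), self.excluded_reasons_,
            )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "used_mask_")
        X = check_array(X, dtype=float)[self.used_mask_]
        if self.row_normalize:
            X = X / X.sum(axis=1, keepdims=True)
        c = np.corrcoef(X)
        c = np.clip((c + c.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry/range
        np.fill_diagonal(c, 1.0)
        return c


class ProjThresh(TransformerMixin, BaseEstimator):
    """Transformer converting (V, T) counts to per-voxel target proportions.

    A voxel is *suprathreshold* when its total sample count strictly exceeds
    ``threshold``; its row becomes ``counts / total`` (summing to 1). Other
    rows are zeroed. Ties (total == threshold) are sub-threshold.

    Attributes
    ----------
    suprathreshold_mask_ : (V,) bool, set on transform.
    """

    def __init__(self, threshold: float = DEFAULT_PROJ_THRESHOLD):
        self.threshold = threshold

    def fit(self, X, y=None):
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        totals = X.sum(axis=1)
        supra = totals > self.threshold
        out = np.zeros_like(X, dtype=float)
        out[supra] = X[supra] / totals[supra, None]
        self.suprathreshold_mask_ = supra
        return out


def build_connectivity_matrix(
    count_volumes,
    seed_mask: np.ndarray,
    target_names=None,
    affines=None,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """Assemble the seed-voxel x target connectivity matrix from per-target
    count volumes.

    Parameters
    ----------
    count_volumes : (X, Y, Z, T) array, or sequence of T (X, Y, Z) arrays.
    seed_mask : boolean volume on the same grid; must be nonempty.
    affines : optional list of per-volume affines, checked for agreement
        (the offending volume is named on mismatch).
    """
    if isinstance(count_volumes, np.ndarray) and count_volumes.ndim == 4:
        vols = count_volumes
    else:
        vols = np.stack(list(count_volumes), axis=-1)
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if vols.shape[:3] != seed_mask.shape:
        raise ValueError(
            f"count volumes grid {vols.shape[:3]} != seed mask grid {seed_mask.shape}"
        )
    if affines is not None:
        names = (
            [f"target volume '{t}'" for t in target_names]
            if target_names is not None
            else None
        )
        check_same_grid([(vols.shape[:3], a) for a in affines], names=names)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if target_names is None:
        target_names = tuple(f"target{j}" for j in range(vols.shape[-1]))
    voxels = seed_scan_order(seed_mask)
    counts = vols[voxels[:, 0], voxels[:, 1], voxels[:, 2], :]
    affine = np.asarray(affines[0]) if affines is not None else None
    return ConnectivityMatrix(
        subject_id=subject_id,
        seed_voxel_index=voxels,
        counts=counts,
        target_names=tuple(target_names),
        affine=affine,
    )


def build_ccm(cm: ConnectivityMatrix) -> CrossCorrelationMatrix:
    """Pearson-correlate every pair of usable fingerprint rows of *cm*."""
    est = CrossCorrelation().fit(cm.counts)
    return CrossCorrelationMatrix(
        subject_id=cm.subject_id,
        ccm=est.transform(cm.counts),
        used_voxels=np.nonzero(est.used_mask_)[0],
        excluded_voxels=est.excluded_reasons_,
    )


def proj_thresh(
    cm: ConnectivityMatrix, threshold: float = DEFAULT_PROJ_THRESHOLD
) -> ConnectionProbabilityMaps:
    """Per-voxel connection probabilities on voxels with total samples
    strictly above *threshold* (others zeroed and flagged)."""
    est = ProjThresh(threshold=threshold).fit(cm.counts)
    probs = est.transform(cm.counts)
    return ConnectionProbabilityMaps(
        subject_id=cm.subject_id,
        seed_voxel_index=cm.seed_voxel_index,
        probabilities=probs,
        suprathreshold_mask=est.suprathreshold_mask_,
        target_names=cm.target_names,
        threshold=threshold,
        affine=cm.affine,
    )


def mean_probability_per_target(
    maps: ConnectionProbabilityMaps, region_mask: np.ndarray
) -> np.ndarray:
    """Arithmetic mean of each target's probability map over a region.

    *region_mask* is a boolean volume; only its voxels that are part of the
    seed index are averaged. Raises on an empty region.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    v = maps.seed_voxel_index
    in_region = region_mask[v[:, 0], v[:, 1], v[:, 2]]
    if not in_region.any():
        raise ValueError("region contains no seed voxels")
    return maps.probabilities[in_region].mean(axis=0)
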