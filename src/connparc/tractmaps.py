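"""Group tract-map algebra for cluster-seeded visitation maps.

Mirrors the fslmaths workflow applied to per-subject tractograms seeded from
each population cluster: each subject's visitation map is normalized to its
maximum, thresholded at a high fraction of that maximum (default 0.95),
binarized, and the binaries are summed voxelwise across subjects; a final
subject-count threshold extracts the group-consistent pathway.

"Normalized" here means division by the map maximum, so the default
threshold keeps voxels visited at >= 95% of the peak rate. The final group
threshold is study-specific (in practice chosen on anatomical grounds) and
therefore has no default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import check_same_grid

__all__ = [
    "VisitationMap",
    "GroupTractMap",
    "normalize_map",
    "threshold_binarize",
    "group_sum",
]


@dataclass
class VisitationMap:
    """Per-subject, per-cluster streamline visitation (or probability) map."""

    subject_id: str
    cluster: int
    volume: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("visitation values must be finite and nonnegative")
        self.volume = v


@dataclass
class GroupTractMap:
    """Voxelwise subject counts for one cluster's pathway plus the final
    group-thresholded mask."""

    cluster: int
    volume: np.ndarray  # ints in 0..n_subjects
    n_subjects: int
    final_mask: np.ndarray | None = None


def normalize_map(m: VisitationMap) -> VisitationMap:
    """Divide by the map maximum so values lie in [0, 1]. Idempotent.

    Raises on an all-zero map (no visitation to normalize)."""
    peak = m.volume.max()
    if peak == 0:
        raise ValueError(f"subject {m.subject_id} cluster {m.cluster}: all-zero map")
    return VisitationMap(m.subject_id, m.cluster, m.volume / peak)


def threshold_binarize(m: VisitationMap, q: float = 0.95) -> np.ndarray:
    """Binary volume: 1 where the normalized value is >= q, else 0."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    return (m.volume >= q).astype(np.uint8)


def group_sum(
    binaries: list[np.ndarray],
    cluster: int = 0,
    min_subjects: int | None = None,
) -> GroupTractMap:
    """Voxelwise integer sum of per-subject binary maps; if *min_subjects*
    is given, also compute the final mask (sum >= min_subjects)."""
    if not binaries:
        raise ValueError("no binary maps given")
    check_same_grid([(np.asarray(b).shape, np.eye(4)) for b in binaries])
    total = np.sum([np.asarray(b, dtype=np.int32) for b in binaries], axis=0)
    final = None
    if min_subjects is not None:
        final = total >= min_subjects
    return GroupTractMap(
        cluster=cluster, volume=total, n_subjects=len(binaries), final_mask=final
    )
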