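"""Synthetic tractography-phantom cohorts with planted cluster structure.

The phantom emulates the per-subject output of probabilistic tractography run
from every voxel of a seed structure (an amygdala-like ellipsoid) to a set of
target regions: for each seed voxel, a fixed number of streamline samples is
drawn and each sample terminates in exactly one target, so the per-voxel
target counts are a multinomial draw from that voxel's connectivity profile.

Ground truth is a k-way partition of the seed into spatially contiguous slabs
arranged medial-to-lateral along the world x axis, each slab carrying its own
probability profile over the targets. Two nuisance processes stand in for the
variability of a real multi-subject study:

* **profile noise** — per subject and voxel, the cluster profile is perturbed
  by a logistic-normal jitter (Gaussian noise on the log-profile, then
  renormalised by softmax), modelling biological and tracking variability of
  the connectivity fingerprint;
* **spatial jitter** — each subject's anatomy is rigidly displaced by a random
  translation relative to the common space, modelling residual registration
  error. Mirroring the native-space tractography workflow, each subject's
  seed mask is their *own* displaced copy of the seed (so per-subject data
  are internally consistent), and the misalignment only bites when subjects
  are combined on the common grid: label maps no longer line up, consensus
  boundaries smear, and the common-space (atlas-masked) view of a subject can
  clip a displaced cluster.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volio import read_volume, seed_scan_order, world_coordinates, write_volume

__all__ = [
    "DEFAULT_TARGETS",
    "DEFAULT_PROFILES",
    "PhantomConfig",
    "GroundTruth",
    "SyntheticSubject",
    "PhantomGeometryError",
    "generate_cohort",
    "generate_visitation_cohort",
    "apply_exclusions",
    "drop_malformed",
    "save_cohort",
    "load_cohort",
]

#: Target region names, medial circuit order used throughout the package.
DEFAULT_TARGETS: tuple[str, ...] = ("NAc", "BS", "HC", "DLPFC", "insula", "OFC", "rACC")

#: Default per-cluster connectivity profiles (rows: medial, basal, lateral;
#: columns follow DEFAULT_TARGETS). Hippocampus dominates everywhere, the
#: medial cluster leans on brainstem, the lateral cluster on cortical targets.
DEFAULT_PROFILES: np.ndarray = np.array(
    [
        [0.05, 0.25, 0.40, 0.02, 0.10, 0.13, 0.05],  # medial
        [0.08, 0.10, 0.50, 0.05, 0.07, 0.15, 0.05],  # basal
        [0.05, 0.08, 0.20, 0.15, 0.22, 0.25, 0.05],  # lateral
    ]
)


class PhantomGeometryError(ValueError):
    """A planted cluster became empty (degenerate geometry after jitter)."""


@dataclass
class PhantomConfig:
    """Generator settings for one synthetic cohort.

    Defaults reproduce the reference phantom used by the test-bench: a
    ~500-voxel ellipsoidal seed at 1.25 mm isotropic resolution, 3 planted
    clusters over 7 targets, 5000 streamline samples per seed voxel.
    """

    grid_shape: tuple[int, int, int] = (24, 18, 18)
    voxel_size: float = 1.25
    n_targets: int = 7
    n_clusters: int = 3
    samples_per_voxel: int = 5000
    cluster_profiles: np.ndarray | None = None
    profile_noise: float = 0.08
    jitter_sd: float = 0.5
    n_subjects: int = 30
    rng_seed: int = 0
    target_names: tuple[str, ...] = DEFAULT_TARGETS
    #: semi-axes of the ellipsoidal seed, mm (x = medial->lateral axis)
    seed_semi_axes: tuple[float, float, float] = (9.0, 5.5, 5.5)

    def __post_init__(self) -> None:
        if self.cluster_profiles is None:
            if self.n_clusters == 3 and self.n_targets == 7:
                self.cluster_profiles = DEFAULT_PROFILES.copy()
            else:
                raise ValueError(
                    "cluster_profiles must be given unless n_clusters=3 and n_targets=7"
                )
        self.cluster_profiles = np.asarray(self.cluster_profiles, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.samples_per_voxel <= 0:
            raise ValueError("samples_per_voxel must be > 0")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.profile_noise < 0 or self.jitter_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        p = self.cluster_profiles
        if p.shape != (self.n_clusters, self.n_targets):
            raise ValueError(
                f"cluster_profiles shape {p.shape} != ({self.n_clusters}, {self.n_targets})"
            )
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each cluster profile must be a probability simplex vector")
        if len(self.target_names) != self.n_targets:
            raise ValueError("target_names length must equal n_targets")

    @property
    def affine(self) -> np.ndarray:
        """Diagonal RAS affine placing the seed in the right hemisphere
        (all seed world-x > 0, +x = lateral)."""
        a = np.diag([self.voxel_size] * 3 + [1.0])
        a[:3, 3] = (2.0, -self.grid_shape[1] * self.voxel_size / 2,
                    -self.grid_shape[2] * self.voxel_size / 2)
        return a


@dataclass
class GroundTruth:
    """Planted parcellation: label volume (0 outside the seed, 1..k inside,
    slabs ordered medial->lateral) plus the per-cluster world-x centroids."""

    label_volume: np.ndarray
    affine: np.ndarray
    cluster_centroid_x: np.ndarray

    @property
    def seed_mask(self) -> np.ndarray:
        return self.label_volume > 0

    @property
    def n_clusters(self) -> int:
        return int(self.label_volume.max())


@dataclass
class SyntheticSubject:
    """One simulated subject: per-target streamline-count volumes, the
    subject's own (rigidly displaced) seed mask, and the post-jitter true
    labels on that mask — all rasterized on the common grid."""

    subject_id: str
    count_volumes: np.ndarray  # (X, Y, Z, n_targets) nonnegative ints
    seed_mask: np.ndarray
    true_labels: np.ndarray
    affine: np.ndarray
    target_names: tuple[str, ...] = DEFAULT_TARGETS
    jitter_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _build_ground_truth(config: PhantomConfig) -> GroundTruth:
    shape = config.grid_shape
    center = (np.asarray(shape) - 1) / 2.0
    semi_vox = np.asarray(config.seed_semi_axes) / config.voxel_size
    idx = np.indices(shape).transpose(1, 2, 3, 0)
    d2 = (((idx - center) / semi_vox) ** 2).sum(axis=-1)
    mask = d2 <= 1.0

    labels = np.zeros(shape, dtype=np.int16)
    voxels = seed_scan_order(mask)
    xs = voxels[:, 0]
    # split into k slabs of (near-)equal voxel count along x
    edges = np.quantile(xs, np.linspace(0, 1, config.n_clusters + 1)[1:-1])
    slab = np.searchsorted(edges, xs, side="right") + 1
    labels[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = slab

    affine = config.affine
    centroids = np.array(
        [
            world_coordinates(np.argwhere(labels == c), affine)[:, 0].mean()
            for c in range(1, config.n_clusters + 1)
        ]
    )
    if np.any(np.diff(centroids) <= 0):
        raise PhantomGeometryError("ground-truth cluster centroids not ordered along x")
    for c in range(1, config.n_clusters + 1):
        if not np.any(labels == c):
            raise PhantomGeometryError(f"ground-truth cluster {c} is empty")
    return GroundTruth(label_volume=labels, affine=affine, cluster_centroid_x=centroids)


def _subject_rng(rng_seed: int, subject_index: int) -> np.random.Generator:
    # stable per-subject stream: reproducible under subject-parallel generation
    return np.random.default_rng(np.random.SeedSequence([int(rng_seed), int(subject_index)]))


def _noised_profiles(base: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Logistic-normal perturbation: softmax(log p + N(0, sd^2)) per row."""
    if sd == 0:
        return base.copy()
    with np.errstate(divide="ignore"):
        w = np.log(base) + rng.normal(0.0, sd, size=base.shape)
    w -= w.max(axis=1, keepdims=True)
    p = np.exp(w)
    return p / p.sum(axis=1, keepdims=True)


def generate_cohort(
    config: PhantomConfig,
) -> tuple[GroundTruth, list[SyntheticSubject]]:
    """Generate a cohort of synthetic subjects with planted cluster structure.

    Deterministic given ``config.rng_seed`` (each subject has its own stream
    derived from ``(rng_seed, subject_index)``). Every common-mask seed voxel
    receives exactly ``samples_per_voxel`` streamline samples distributed over
    targets by a multinomial draw from its (noised) profile.

    Raises
    ------
    PhantomGeometryError
        If jitter empties a planted cluster for some subject.
    """
    gt = _build_ground_truth(config)
    inv3 = np.linalg.inv(gt.affine[:3, :3])
    shape = config.grid_shape
    all_voxels = np.indices(shape).reshape(3, -1).T

    subjects: list[SyntheticSubject] = []
    for i in range(config.n_subjects):
        sid = f"sub-{i:03d}"
        rng = _subject_rng(config.rng_seed, i)
        t_mm = rng.normal(0.0, config.jitter_sd, size=3) if config.jitter_sd > 0 else np.zeros(3)
        offset = inv3 @ t_mm
        # subject anatomy = ground truth rigidly displaced by t_mm, NN-resampled
        src = np.rint(all_voxels - offset).astype(np.intp)
        inside = np.all((src >= 0) & (src < np.asarray(shape)), axis=1)
        labels_vol = np.zeros(shape, dtype=np.int16)
        lv = np.zeros(len(all_voxels), dtype=np.int16)
        lv[inside] = gt.label_volume[src[inside, 0], src[inside, 1], src[inside, 2]]
        labels_vol = lv.reshape(shape)

        for c in range(1, config.n_clusters + 1):
            if not np.any(labels_vol == c):
                raise PhantomGeometryError(
                    f"subject {sid}: cluster {c} has no voxels after jitter "
                    f"(translation {t_mm.round(2)} mm)"
                )

        voxels = seed_scan_order(labels_vol > 0)
        lab = labels_vol[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        base = config.cluster_profiles[lab - 1]
        profiles = _noised_profiles(base, config.profile_noise, rng)
        counts = rng.multinomial(config.samples_per_voxel, profiles)

        vols = np.zeros(shape + (config.n_targets,), dtype=np.int32)
        vols[voxels[:, 0], voxels[:, 1], voxels[:, 2], :] = counts
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                count_volumes=vols,
                seed_mask=labels_vol > 0,
                true_labels=labels_vol,
                affine=gt.affine.copy(),
                target_names=tuple(config.target_names),
                jitter_mm=t_mm,
            )
        )
    return gt, subjects


def generate_visitation_cohort(
    gt: GroundTruth,
    n_subjects: int,
    rng_seed: int = 0,
    noise_rate: float = 0.02,
    core_dilation: int = 1,
) -> tuple[dict[int, np.ndarray], list[dict[int, np.ndarray]]]:
    """Synthetic per-cluster visitation maps with a planted core pathway.

    For each cluster the "pathway core" is the cluster mask dilated by
    ``core_dilation`` voxels. Every subject's map puts near-maximal values on
    the core; each non-core voxel independently becomes a bright false
    positive with probability ``noise_rate``, and dim background otherwise.
    Returns ``(core_masks, per-subject {cluster: map})``.
    """
    from scipy.ndimage import binary_dilation

    cores = {
        c: binary_dilation(gt.label_volume == c, iterations=core_dilation)
        for c in range(1, gt.n_clusters + 1)
    }
    subjects = []
    for i in range(n_subjects):
        rng = _subject_rng(rng_seed, i)
        maps = {}
        for c, core in cores.items():
            m = rng.uniform(0.0, 500.0, size=core.shape)
            fp = rng.random(core.shape) < noise_rate
            bright = rng.uniform(960.0, 1000.0, size=core.shape)
            m = np.where(core | fp, bright, m)
            maps[c] = m
        subjects.append(maps)
    return cores, subjects


def apply_exclusions(n_selected: int, n_incomplete: int, n_missing: int) -> int:
    """Subject accounting: selected minus exclusions for incomplete diffusion
    data and for missing tractography-classification output.

    >>> apply_exclusions(200, 3, 29)
    168
    """
    for name, v in [
        ("n_selected", n_selected),
        ("n_incomplete", n_incomplete),
        ("n_missing", n_missing),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    remaining = n_selected - n_incomplete - n_missing
    if remaining < 0:
        raise ValueError(
            f"exclusions ({n_incomplete} + {n_missing}) exceed selected subjects ({n_selected})"
        )
    return remaining


def drop_malformed(
    subjects: list[SyntheticSubject],
) -> tuple[list[SyntheticSubject], list[str]]:
    """Cohort filter: drop subjects whose count volumes are absent, negative,
    or inconsistent with their seed mask. Returns (kept, dropped_ids)."""
    kept, dropped = [], []
    for s in subjects:
        ok = (
            s.count_volumes is not None
            and s.count_volumes.ndim == 4
            and s.count_volumes.shape[:3] == s.seed_mask.shape
            and not np.any(s.count_volumes < 0)
            and np.any(s.count_volumes[s.seed_mask] > 0)
        )
        (kept if ok else dropped).append(s if ok else s.subject_id)
    return kept, dropped


def save_cohort(
    gt: GroundTruth,
    subjects: list[SyntheticSubject],
    out_dir: str | os.PathLike,
) -> Path:
    """Write a cohort as NIfTI-1 volumes plus a JSON manifest.

    Layout: ``seed_mask.nii.gz``, ``truth_labels.nii.gz``, one
    ``<sub>/counts_<target>.nii.gz`` per subject and target, one
    ``<sub>/true_labels.nii.gz`` per subject, and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(gt.seed_mask, gt.affine, out / "seed_mask.nii.gz")
    write_volume(gt.label_volume, gt.affine, out / "truth_labels.nii.gz")
    manifest = {
        "targets": list(subjects[0].target_names) if subjects else [],
        "subjects": [],
        "cluster_centroid_x": [float(x) for x in gt.cluster_centroid_x],
    }
    for s in subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        for j, t in enumerate(s.target_names):
            write_volume(s.count_volumes[..., j], s.affine, sdir / f"counts_{t}.nii.gz")
        write_volume(s.true_labels, s.affine, sdir / "true_labels.nii.gz")
        manifest["subjects"].append(
            {"subject_id": s.subject_id, "jitter_mm": [float(v) for v in s.jitter_mm]}
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def load_cohort(in_dir: str | os.PathLike) -> tuple[GroundTruth, list[SyntheticSubject]]:
    """Read back a cohort written by :func:`save_cohort`."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    labels, affine = read_volume(src / "truth_labels.nii.gz")
    labels = labels.astype(np.int16)
    gt = GroundTruth(
        label_volume=labels,
        affine=affine,
        cluster_centroid_x=np.asarray(manifest["cluster_centroid_x"]),
    )
    targets = tuple(manifest["targets"])
    subjects = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        sdir = src / sid
        vols = []
        for t in targets:
            v, aff = read_volume(sdir / f"counts_{t}.nii.gz")
            if not np.allclose(aff, affine):
                raise ValueError(f"{sid}/counts_{t}: affine differs from cohort grid")
            vols.append(v)
        true_labels, _ = read_volume(sdir / "true_labels.nii.gz")
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                count_volumes=np.stack(vols, axis=-1).astype(np.int32),
                seed_mask=true_labels > 0,
                true_labels=true_labels.astype(np.int16),
                affine=affine,
                target_names=targets,
                jitter_mm=np.asarray(entry["jitter_mm"]),
            )
        )
    return gt, subjects
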