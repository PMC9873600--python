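"""End-to-end pipeline driver: phantom -> connectivity -> parcellation ->
consensus -> cluster statistics -> group tract maps."""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import (
    build_connectivity_matrix,
    build_ccm,
    proj_thresh,
)
from .groupstats import anova_all, build_profile_table
from .parcellation import (
    build_consensus,
    classify_pattern,
    cluster_volumes,
    consensus_ari,
    harmonize_labels,
    kmeans_parcellate,
)
from .phantom import (
    PhantomConfig,
    generate_cohort,
    generate_visitation_cohort,
    save_cohort,
)
from .tractmaps import VisitationMap, group_sum, normalize_map, threshold_binarize
from .volio import write_volume

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config", "save_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage (and subject)."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one run.

    Defaults carry the study parameters: k = 3 clusters, consensus threshold
    50%, proj_thresh threshold 1250 samples, tract threshold 95% of peak,
    alpha 0.05 on Bonferroni-corrected p values.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    k: int = 3
    consensus_threshold: float = 0.5
    proj_threshold: float = 1250
    tract_q: float = 0.95
    tract_min_fraction: float = 0.75
    rng_seed: int = 0
    restarts: int = 20
    alpha: float = 0.05
    harmonize_reference: str = "cohort-median"

    def __post_init__(self) -> None:
        if not 0 < self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must be in (0, 1]")
        if not 0 <= self.tract_q <= 1:
            raise ValueError("tract_q must be in [0, 1]")
        if self.proj_threshold < 0:
            raise ValueError("proj_threshold must be >= 0")


def save_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    d = dataclasses.asdict(config)
    d["phantom"]["cluster_profiles"] = np.asarray(
        d["phantom"]["cluster_profiles"]
    ).tolist()
    for key in ("grid_shape", "target_names", "seed_semi_axes"):
        d["phantom"][key] = list(d["phantom"][key])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    ph = d.pop("phantom", {})
    for key in ("grid_shape", "target_names", "seed_semi_axes"):
        if key in ph:
            ph[key] = tuple(ph[key])
    if ph.get("cluster_profiles") is not None:
        ph["cluster_profiles"] = np.asarray(ph["cluster_profiles"])
    return PipelineConfig(phantom=PhantomConfig(**ph), **d)


def subject_pattern_flag(parc, gt, k: int) -> bool:
    """Mediolateral-pattern flag for one subject's harmonized parcellation,
    evaluated on the subject's own seed voxels. False when a cluster is
    absent, non-contiguous, or out of medial->lateral centroid order."""
    lv = parc.label_volume(gt.label_volume.shape)
    try:
        return classify_pattern(lv, gt.affine, k=k).is_mediolateral
    except ValueError:
        return False


def _subject_kmeans_seed(root: int, index: int) -> int:
    return int(np.random.SeedSequence([int(root), int(index), 7]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike | None = None) -> dict:
    """Run every stage on a synthetic cohort and return a results dict.

    If *out_dir* is given, volumes (consensus counts, final labels, subject
    labels), tables (profile table, ANOVA) and a JSON manifest are written
    there. Fully reproducible given ``config.rng_seed``: outputs of two runs
    with the same config are numerically identical.
    """
    phantom_cfg = dataclasses.replace(config.phantom, rng_seed=config.rng_seed)

    def stage(name, fn, subject=None):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            who = f" (subject {subject})" if subject else ""
            raise PipelineError(f"stage '{name}'{who}: {e}") from e

    gt, subjects = stage("phantom", lambda: generate_cohort(phantom_cfg))

    parcs = []
    prob_maps = []
    for i, s in enumerate(subjects):
        cm = stage(
            "connectivity",
            lambda s=s: build_connectivity_matrix(
                s.count_volumes, s.seed_mask, s.target_names,
                affines=[s.affine] * len(s.target_names), subject_id=s.subject_id,
            ),
            subject=s.subject_id,
        )
        ccm = stage("ccm", lambda cm=cm: build_ccm(cm), subject=s.subject_id)
        parc = stage(
            "parcellation",
            lambda ccm=ccm, cm=cm, i=i: kmeans_parcellate(
                ccm, k=config.k, seed=_subject_kmeans_seed(config.rng_seed, i),
                restarts=config.restarts, cm=cm,
            ),
            subject=s.subject_id,
        )
        parcs.append(parc)
        prob_maps.append(
            stage(
                "proj_thresh",
                lambda cm=cm: proj_thresh(cm, threshold=config.proj_threshold),
                subject=s.subject_id,
            )
        )

    parcs = stage("harmonize", lambda: harmonize_labels(parcs, config.harmonize_reference))
    consensus = stage(
        "consensus",
        lambda: build_consensus(
            parcs, threshold_fraction=config.consensus_threshold,
            grid_shape=gt.label_volume.shape,
        ),
    )

    table = stage(
        "groupstats", lambda: build_profile_table(prob_maps, consensus.final_labels)
    )
    anova = stage("groupstats", lambda: anova_all(table, alpha=config.alpha))

    pattern_flags = [subject_pattern_flag(p, gt, config.k) for p in parcs]
    consensus_pattern = classify_pattern(consensus.final_labels, gt.affine, k=config.k)
    volumes = cluster_volumes(consensus.final_labels, gt.affine, k=config.k)
    ari = consensus_ari(consensus.final_labels, gt.label_volume)

    n_subj = len(subjects)
    min_subjects = max(1, math.ceil(config.tract_min_fraction * n_subj))
    cores, vis_subjects = stage(
        "tractmaps",
        lambda: generate_visitation_cohort(gt, n_subj, rng_seed=config.rng_seed + 1),
    )
    tract = {}
    for c in cores:
        binaries = [
            threshold_binarize(
                normalize_map(VisitationMap(f"sub-{i:03d}", c, maps[c])), config.tract_q
            )
            for i, maps in enumerate(vis_subjects)
        ]
        tract[c] = group_sum(binaries, cluster=c, min_subjects=min_subjects)

    results = {
        "ground_truth": gt,
        "subjects": subjects,
        "parcellations": parcs,
        "prob_maps": prob_maps,
        "consensus": consensus,
        "profile_table": table,
        "anova": anova,
        "pattern_fraction": float(np.mean(pattern_flags)),
        "consensus_pattern": consensus_pattern,
        "cluster_volumes_mm3": volumes,
        "consensus_ari": ari,
        "tract_maps": tract,
        "tract_cores": cores,
    }

    if out_dir is not None:
        _write_outputs(config, results, Path(out_dir))
    return results


def null_typeI_pvalues(
    n_cohorts: int,
    seed: int,
    n_subjects: int = 12,
    profile_noise: float = 0.08,
) -> np.ndarray:
    """Uncorrected per-target ANOVA p values under the null phantom.

    Every cluster shares one connectivity profile, so the per-target
    cluster-difference ANOVA tests a true null; cluster membership is the
    planted (fixed) partition, keeping the grouping independent of the data.
    Uses a small seed (~100 voxels) to make many cohorts cheap. Returns the
    flattened array of ``n_cohorts * n_targets`` uncorrected p values, whose
    sub-alpha fraction estimates the test's type-I error rate.
    """
    from .groupstats import anova_per_target

    profiles = np.tile(PhantomConfig().cluster_profiles[1], (3, 1))
    pvals = []
    for i in range(n_cohorts):
        cohort_seed = int(
            np.random.SeedSequence([int(seed), int(i)]).generate_state(1)[0] % (2**31)
        )
        cfg = PhantomConfig(
            grid_shape=(12, 10, 10),
            seed_semi_axes=(5.0, 3.2, 3.2),
            cluster_profiles=profiles,
            profile_noise=profile_noise,
            jitter_sd=0.0,
            n_subjects=n_subjects,
            rng_seed=cohort_seed,
        )
        gt, subjects = generate_cohort(cfg)
        maps = [
            proj_thresh(
                build_connectivity_matrix(
                    s.count_volumes, s.seed_mask, s.target_names, subject_id=s.subject_id
                )
            )
            for s in subjects
        ]
        table = build_profile_table(maps, gt.label_volume)
        for t in subjects[0].target_names:
            pvals.append(anova_per_target(table, t).p)
    return np.asarray(pvals)


def _write_outputs(config: PipelineConfig, results: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    gt = results["ground_truth"]
    save_cohort(gt, results["subjects"], out / "cohort")
    cons = results["consensus"]
    write_volume(cons.final_labels, gt.affine, out / "consensus_labels.nii.gz")
    for c in range(1, cons.k + 1):
        write_volume(cons.counts[c - 1], gt.affine, out / f"consensus_count_cluster{c}.nii.gz")
    labdir = out / "subject_labels"
    labdir.mkdir(exist_ok=True)
    for p in results["parcellations"]:
        write_volume(
            p.label_volume(gt.label_volume.shape), gt.affine,
            labdir / f"{p.subject_id}_labels.nii.gz",
        )
    results["profile_table"].to_csv(out / "profile_table.tsv", sep="\t", index=False)
    results["anova"].to_csv(out / "anova.tsv", sep="\t", index=False)
    for c, gm in results["tract_maps"].items():
        write_volume(gm.volume, gt.affine, out / f"tract_sum_cluster{c}.nii.gz")
        write_volume(gm.final_mask, gt.affine, out / f"tract_mask_cluster{c}.nii.gz")
    save_config(config, out / "config.yaml")
    manifest = {
        "package": "connparc",
        "version": __version__,
        "rng_seed": config.rng_seed,
        "k": config.k,
        "consensus_threshold": config.consensus_threshold,
        "proj_threshold": config.proj_threshold,
        "tract_q": config.tract_q,
        "n_subjects": len(results["subjects"]),
        "consensus_ari": results["consensus_ari"],
        "pattern_fraction": results["pattern_fraction"],
        "cluster_volumes_mm3": [float(v) for v in results["cluster_volumes_mm3"]],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
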