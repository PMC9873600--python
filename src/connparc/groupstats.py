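"""Cluster-level connection-probability statistics.

Per subject, hemisphere and final consensus cluster, the connection
probability to each target is the mean of the proj_thresh map over that
cluster's voxels. Cluster differences are tested per target with a one-way
fixed-effects ANOVA across clusters (observations are subject-level cluster
means, not voxels, so spatially correlated voxels never enter as independent
observations), followed by pairwise two-sided t-tests with a Bonferroni
correction over the cluster pairs within each (target, hemisphere) family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectionProbabilityMaps

logger = logging.getLogger(__name__)

__all__ = ["AnovaResult", "build_profile_table", "anova_per_target", "anova_all"]


@dataclass
class PairwiseComparison:
    cluster_a: int
    cluster_b: int
    mean_difference: float
    p_raw: float
    p_corrected: float


@dataclass
class AnovaResult:
    """One-way ANOVA of cluster effect on connection probability for one
    target (and hemisphere), plus Bonferroni-corrected pairwise post-hocs."""

    target: str
    hemisphere: str
    F: float
    df_between: int
    df_within: int
    p: float
    posthoc: list[PairwiseComparison] = field(default_factory=list)


def build_profile_table(
    prob_maps: list[ConnectionProbabilityMaps],
    final_labels: np.ndarray,
    hemisphere: str = "right",
) -> pd.DataFrame:
    """Tabulate per-(subject, cluster, target) mean connection probabilities.

    The mean for cluster c is taken over the consensus cluster's voxels that
    appear in the subject's seed index (sub-threshold voxels contribute their
    zeros, matching the proj_thresh contract). Clusters empty in the
    consensus are omitted with a warning.
    """
    final_labels = np.asarray(final_labels)
    k = int(final_labels.max())
    rows = []
    warned: set[int] = set()
    for m in prob_maps:
        v = m.seed_voxel_index
        vox_labels = final_labels[v[:, 0], v[:, 1], v[:, 2]]
        for c in range(1, k + 1):
            sel = vox_labels == c
            if not sel.any():
                if c not in warned:
                    logger.warning("profile table: cluster %d has no voxels; omitted", c)
                    warned.add(c)
                continue
            means = m.probabilities[sel].mean(axis=0)
            for t, p in zip(m.target_names, means):
                rows.append(
                    {
                        "subject_id": m.subject_id,
                        "hemisphere": hemisphere,
                        "cluster": c,
                        "target": t,
                        "probability": float(p),
                    }
                )
    return pd.DataFrame(rows)


def _groups(table: pd.DataFrame, target: str, hemisphere: str | None) -> list[np.ndarray]:
    t = table[table["target"] == target]
    if hemisphere is not None:
        t = t[t["hemisphere"] == hemisphere]
    if t.empty:
        raise ValueError(f"no rows for target {target!r}, hemisphere {hemisphere!r}")
    return [g["probability"].to_numpy() for _, g in t.groupby("cluster", sort=True)]


def anova_per_target(
    table: pd.DataFrame, target: str, hemisphere: str | None = None
) -> AnovaResult:
    """One-way ANOVA across clusters for one target's connection probability.

    Degenerate inputs are resolved explicitly: zero within-group variance
    with equal group means gives F = 0 (p = 1); with unequal means, F = inf
    (p = 0). Post-hoc p values are Bonferroni-multiplied by the number of
    cluster pairs and clipped at 1.
    """
    groups = _groups(table, target, hemisphere)
    clusters = sorted(table[table["target"] == target]["cluster"].unique())
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 clusters with >= 2 observations each")
    n = sum(len(g) for g in groups)
    dfb, dfw = len(groups) - 1, n - len(groups)

    grand = np.concatenate(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ss_within == 0:
        means = [g.mean() for g in groups]
        if np.allclose(means, means[0], rtol=1e-12, atol=1e-12):
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
    else:
        F, p = stats.f_oneway(*groups)
        F, p = float(F), float(p)

    pairs = list(combinations(range(len(groups)), 2))
    posthoc = []
    for i, j in pairs:
        a, b = groups[i], groups[j]
        diff = float(a.mean() - b.mean())
        if np.var(a) == 0 and np.var(b) == 0:
            praw = 1.0 if diff == 0 else 0.0
        else:
            praw = float(stats.ttest_ind(a, b).pvalue)
        posthoc.append(
            PairwiseComparison(
                cluster_a=int(clusters[i]),
                cluster_b=int(clusters[j]),
                mean_difference=diff,
                p_raw=praw,
                p_corrected=min(1.0, praw * len(pairs)),
            )
        )
    return AnovaResult(
        target=target,
        hemisphere=hemisphere if hemisphere is not None else "all",
        F=F,
        df_between=dfb,
        df_within=dfw,
        p=p,
        posthoc=posthoc,
    )


def anova_all(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run the per-target ANOVA for every (target, hemisphere) in the table
    and return a tidy frame with significance at the corrected level."""
    rows = []
    for (hemi, target), _ in table.groupby(["hemisphere", "target"], sort=True):
        r = anova_per_target(table, target, hemi)
        for ph in r.posthoc:
            rows.append(
                {
                    "target": target,
                    "hemisphere": hemi,
                    "F": r.F,
                    "df_between": r.df_between,
                    "df_within": r.df_within,
                    "p": r.p,
                    "cluster_a": ph.cluster_a,
                    "cluster_b": ph.cluster_b,
                    "mean_difference": ph.mean_difference,
                    "p_raw": ph.p_raw,
                    "p_corrected": ph.p_corrected,
                    "significant": ph.p_corrected < alpha,
                }
            )
    return pd.DataFrame(rows)
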