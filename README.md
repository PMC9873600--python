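# connparc

Connectivity-based parcellation of a seed structure from seed-to-target
tractography streamline counts — with a fully synthetic tractography phantom
so the whole pipeline is testable end-to-end on a laptop.

## The problem

Probabilistic tractography from every voxel of a deep grey structure (the
motivating case is the amygdala) to a set of target regions yields, per seed
voxel, a *connectivity fingerprint*: the number of streamline samples (5000
per voxel) terminating in each target — nucleus accumbens (NAc), brainstem
(BS), hippocampus (HC), dorsolateral prefrontal cortex (DLPFC), insula,
orbitofrontal cortex (OFC) and rostral anterior cingulate (rACC). Voxels with
similar fingerprints belong to the same connectional subdivision. The
pipeline implemented here:

1. **Connectivity matrix** — per subject, the seed-voxel × target count
   matrix *C* (the region-collapsed tractography "matrix 2").
2. **Cross-correlation matrix (CCM)** — *R*ᵢⱼ = Pearson r between
   fingerprint rows *C*ᵢ. and *C*ⱼ.; rows of *R* are the clustering features.
3. **k-means parcellation** — Lloyd's algorithm with k-means++ starts,
   k = 3 (the centromedial / basal / lateral nuclear groups), best of
   *n* restarts by inertia.
4. **Label harmonization** — k-means labels are arbitrary per subject, so
   cluster-mean fingerprints are matched across subjects by Hungarian
   assignment to a cohort-median reference, then oriented once
   medial → lateral.
5. **Consensus maps** — per cluster, a voxelwise count of subjects carrying
   that label; thresholding at 50 % of the cohort defines the population
   cluster boundaries.
6. **Connection probabilities** — `proj_thresh`-style maps: on voxels whose
   total samples exceed 1250, each target's count becomes a probability
   count/total in [0, 1]; cluster means across subjects feed a one-way
   ANOVA per target with Bonferroni-corrected pairwise post-hocs.
7. **Group tract maps** — per-subject cluster-seeded visitation maps are
   normalized to their peak, thresholded at 95 %, binarized, and summed
   across subjects.

Real tractography is *not* run: a phantom module generates multinomial
seed-to-target counts with planted, spatially contiguous medial-to-lateral
clusters, per-subject fingerprint noise, and rigid spatial jitter standing in
for registration error — so recovery of the planted truth (adjusted Rand
index, pattern fraction, test calibration) is measurable exactly.

## Worked example

```bash
connparc run-all --out demo/ --seed 17 --subjects 30
```

runs the full pipeline on the default phantom (30 subjects, ~580 seed voxels
at 1.25 mm, 7 targets, 5000 samples/voxel) and prints:

```json
{
  "consensus_ari": 1.0,
  "pattern_fraction": 0.8666666666666667,
  "cluster_volumes_mm3": [335.94, 351.56, 453.13]
}
```

* `consensus_ari` — adjusted Rand index between the 50 %-thresholded
  consensus parcellation and the planted ground truth (1.0 = the population
  boundaries are recovered exactly despite per-subject noise).
* `pattern_fraction` — fraction of subjects whose three connectivity-defined
  clusters are each 6-connected and ordered medial → basal → lateral by
  centroid (0.87 here: fingerprint noise occasionally detaches a stray voxel).
* `cluster_volumes_mm3` — consensus cluster volumes (voxel count × 1.25³).

`demo/` contains the cohort and consensus volumes as NIfTI, the per-subject
label maps, `profile_table.tsv` (subject × cluster × target connection
probabilities) and `anova.tsv`. In `anova.tsv` the planted profiles make
every target separate the clusters decisively (e.g. HC:
F(2, 87) = 2978, corrected p ≈ 1e-80) except rACC, which was planted
identical across clusters and is correctly non-significant
(F(2, 87) = 0.24, p = 0.79).

Each stage is also exposed as its own subcommand (`simulate`, `parcellate`,
`consensus`, `stats`, `tractmap`) over NIfTI files on disk, and as
scikit-learn-style estimators in the library (`CrossCorrelation`,
`ConnectivityParcellator`, `ProjThresh`, `ConsensusLabeler`) for use in
Python.

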