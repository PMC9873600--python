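import numpy as np
import pytest

from connparc.connectivity import build_ccm, build_connectivity_matrix
from connparc.parcellation import harmonize_labels, kmeans_parcellate
from connparc.phantom import PhantomConfig, generate_cohort


def small_phantom_config(**overrides) -> PhantomConfig:
    """A ~200-voxel seed: big enough for stable CCM clustering, small enough
    to keep the suite fast."""
    defaults = dict(
        grid_shape=(14, 12, 12),
        seed_semi_axes=(6.0, 4.0, 4.0),
        n_subjects=4,
        rng_seed=7,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_phantom_config()
    gt, subjects = generate_cohort(cfg)
    return cfg, gt, subjects


@pytest.fixture(scope="session")
def small_parcellations(small_cohort):
    """Harmonized per-subject parcellations of the small cohort."""
    cfg, gt, subjects = small_cohort
    parcs = []
    for i, s in enumerate(subjects):
        cm = build_connectivity_matrix(
            s.count_volumes, s.seed_mask, s.target_names,
            affines=[s.affine] * len(s.target_names), subject_id=s.subject_id,
        )
        parcs.append(kmeans_parcellate(build_ccm(cm), k=3, seed=i, restarts=10, cm=cm))
    return cfg, gt, subjects, harmonize_labels(parcs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
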