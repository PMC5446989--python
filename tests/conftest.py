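import logging

import pytest
from hypothesis import HealthCheck, settings

from gradfam.synthetic_data import AtlasConfig, generate_atlas, generate_family_annotations

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

logging.getLogger("gradfam").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_atlas_truth():
    """Default-condition atlas (2000 genes, 10 tissues, 3 reps, seed 1)."""
    return generate_atlas(AtlasConfig(seed=1))


@pytest.fixture(scope="session")
def small_atlas_truth():
    """Quick 400-gene atlas for structural tests."""
    return generate_atlas(AtlasConfig(n_genes=400, seed=7))


@pytest.fixture(scope="session")
def annotated_run(default_atlas_truth):
    """Atlas + truth + annotation table under default planting."""
    atlas, truth = default_atlas_truth
    annotations = generate_family_annotations(list(atlas.values.index), truth, seed=2)
    return atlas, truth, annotations
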