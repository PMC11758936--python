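import numpy as np
import pytest

from msnets import SimConfig, generate_cohort, make_parcellation, make_streamline_atlas


def small_config(**overrides) -> SimConfig:
    """Desk-scale study conditions for unit tests (structure preserved,
    sizes reduced)."""
    kw = dict(
        n_patients=12,
        n_controls=6,
        n_cortical=26,
        n_subcortical=6,
        vertices_per_region=60,
        streamlines_per_pair=3,
        visits_per_subject=(2, 3),
        seed=7,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_parcellation(small_cfg):
    return make_parcellation(small_cfg)


@pytest.fixture(scope="session")
def small_atlas(small_cfg, small_parcellation):
    return make_streamline_atlas(small_parcellation, small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
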