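"""Shared fixtures: small simulated datasets reused across test modules."""

import pytest

from l1mosaic import synthetic as syn


@pytest.fixture(scope="session")
def de_sim():
    """Default-size DE simulation with planted categories and overlap."""
    return syn.simulate_de_tables(syn.DeSimConfig(seed=11))


@pytest.fixture(scope="session")
def spatial_sim():
    """Default unilateral-contiguous section-count cohort."""
    return syn.simulate_section_counts(syn.SpatialSimConfig(seed=11))


@pytest.fixture(scope="session")
def small_stack_cfg():
    """A small, sparse, noise-free stack: exact recovery regime."""
    return syn.StackSimConfig(
        shape_xyz=(400, 200, 5),
        n_nuclei=120,
        min_separation_um=12.0,
        gfp_cluster_edge_x_um=60.0,
        background_level=0.0,
        noise_sd=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_stack(small_stack_cfg):
    return syn.simulate_tissue_stack(small_stack_cfg)
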