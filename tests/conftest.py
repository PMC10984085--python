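"""Shared fixtures: small synthetic worlds reused across the suite.

Session-scoped generation keeps the suite fast; every fixture is a pure
function of a fixed seed, so tests are reproducible run to run.
"""

from __future__ import annotations

import numpy as np
import pytest

from lnmap.lesion_mapping import cohort_connectivity
from lnmap.synthetic import SimConfig, make_connectome, make_lesion_cohort
from lnmap.volumes import BinaryMask, ScalarMap, VolumeGrid


@pytest.fixture(scope="session")
def grid10() -> VolumeGrid:
    return VolumeGrid((10, 10, 10), np.diag([2.0, 2.0, 2.0, 1.0]), "synthetic")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(shape=(12, 14, 12), n_connectome=8, T=80,
                     n_lesions=40, seed=3)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    conn, truth = make_connectome(small_cfg)
    return conn, truth


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_world):
    conn, truth = small_world
    return make_lesion_cohort(small_cfg, conn, truth)


@pytest.fixture(scope="session")
def small_maps(small_world, small_cohort):
    conn, _ = small_world
    return cohort_connectivity(small_cohort, conn)


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    """The study-condition configuration (full desk scale)."""
    return SimConfig()


@pytest.fixture(scope="session")
def default_world(default_cfg):
    conn, truth = make_connectome(default_cfg)
    return conn, truth


@pytest.fixture(scope="session")
def default_cohort(default_cfg, default_world):
    conn, truth = default_world
    return make_lesion_cohort(default_cfg, conn, truth)


@pytest.fixture(scope="session")
def default_maps(default_world, default_cohort):
    conn, _ = default_world
    return cohort_connectivity(default_cohort, conn)


def random_scalar_map(grid: VolumeGrid, rng: np.random.Generator,
                      mask: np.ndarray | None = None) -> ScalarMap:
    return ScalarMap(grid, rng.standard_normal(grid.shape), mask)


def ball_mask(grid: VolumeGrid, centre, radius) -> BinaryMask:
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid.shape), indexing="ij")
    c = np.asarray(centre)
    ind = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2 <= radius ** 2
    return BinaryMask(grid, ind)
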