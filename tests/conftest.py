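"""Shared fixtures: scenes at two scales, generated once per session.

The default scene matches the benchmark's standard conditions (16-unit
tree on a 40-unit ground, ~1.4e5 points). The small scene keeps the same
structure at reduced extent/density for tests that sweep many evaluations.
"""

import numpy as np
import pytest

from treebench import SceneParams, assemble_scene


@pytest.fixture(scope="session")
def default_scene():
    return assemble_scene(SceneParams(seed=11))


@pytest.fixture(scope="session")
def small_params():
    return SceneParams(
        tree_height=8.0,
        branching_depth=3,
        foliage_points_per_tip=200,
        ground_extent=20.0,
        points_per_unit_area=40.0,
        seed=23,
    )


@pytest.fixture(scope="session")
def small_scene(small_params):
    return assemble_scene(small_params)


@pytest.fixture(scope="session")
def _warm_numba():
    # compile the voxel-distance kernel once so timed tests measure compute
    from treebench._voxdist import bucketize_grid_distances

    bucketize_grid_distances(
        np.zeros((1, 3)), np.array([[-1.0, -1.0, -1.0], [1.0, 1.0, 1.0]]),
        0.5, np.array([0.1]),
    )
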