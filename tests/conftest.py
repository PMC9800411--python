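"""Shared fixtures: small analytic meshes and coarse synthetic specimens.

All fixtures are generated programmatically; session scope is used for the
synthetic specimens because their generation (icosphere subdivision, region
growth) dominates test runtime.
"""

import numpy as np
import pytest
import trimesh

from hydroform.synthetic import SyntheticConfig, generate_specimen

# coarse study conditions used throughout the suite: generator defaults for
# every deformation/noise magnitude, mesh resolution reduced to keep the
# geometry tractable on one CPU
SKULL_EDGE = 2.0
MANDIBLE_EDGE = 1.5


@pytest.fixture(scope="session")
def unit_cube():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)


@pytest.fixture(scope="session")
def octahedron():
    verts = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    faces = np.array(
        [[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
         [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]]
    )
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


@pytest.fixture(scope="session")
def skull_pair_noisefree():
    """Clean skull dry/wet pair with rigid jitter but no scan noise."""
    cfg = SyntheticConfig(
        specimen_type="skull", target_edge_length=SKULL_EDGE,
        noise_sd=0.0, shape_jitter=0.0, effect_scale_sd=0.0, seed=42,
    )
    return generate_specimen(cfg, "SKF")


@pytest.fixture(scope="session")
def mandible_pair_noisefree():
    cfg = SyntheticConfig(
        specimen_type="mandible", target_edge_length=MANDIBLE_EDGE,
        noise_sd=0.0, shape_jitter=0.0, effect_scale_sd=0.0, seed=42,
    )
    return generate_specimen(cfg, "MNF")


@pytest.fixture(scope="session")
def skull_shell_coarse():
    from hydroform.synthetic import make_skull_shell

    cfg = SyntheticConfig(
        specimen_type="skull", target_edge_length=SKULL_EDGE,
        shape_jitter=0.0, seed=0,
    )
    mesh, seeds = make_skull_shell(cfg)
    return mesh, seeds
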