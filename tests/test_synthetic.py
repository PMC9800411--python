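"""Synthetic specimen generator: shapes, deformation ground truth, noise,
misalignment, determinism."""

import numpy as np
import pytest
import trimesh

from hydroform.errors import HydroformError
from hydroform.mesh_io import boundary_edge_count, validate
from hydroform.regions import MANDIBLE_AREAS, SKULL_AREAS, grow_region
from hydroform.synthetic import (
    SyntheticConfig,
    add_scan_noise,
    apply_hydration_deformation,
    generate_specimen,
    generate_study,
    make_mandible_arch,
    make_skull_shell,
    perturb_rigid,
    region_triangle_count,
)

SKULL_CFG = SyntheticConfig(specimen_type="skull", target_edge_length=2.0, shape_jitter=0.0, seed=0)
MAND_CFG = SyntheticConfig(specimen_type="mandible", target_edge_length=1.5, shape_jitter=0.0, seed=0)


class TestSkullShell:
    def test_watertight(self, skull_shell_coarse):
        mesh, _ = skull_shell_coarse
        assert validate(mesh).watertight

    def test_hosts_protocol_regions(self, skull_shell_coarse):
        mesh, seeds = skull_shell_coarse
        n = region_triangle_count(mesh)
        assert n * 10 < len(mesh.faces)
        for name in SKULL_AREAS:
            r = grow_region(mesh, seeds[name], n, name)
            assert len(r) == n

    def test_resolution_tracks_target(self, skull_shell_coarse):
        mesh, _ = skull_shell_coarse
        edge = validate(mesh).mean_edge_length
        assert 0.5 * 2.0 <= edge <= 1.5 * 2.0

    def test_deterministic(self):
        m1, s1 = make_skull_shell(SKULL_CFG)
        m2, s2 = make_skull_shell(SKULL_CFG)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    def test_overall_size(self, skull_shell_coarse):
        mesh, _ = skull_shell_coarse
        extents = mesh.extents
        assert np.all(extents > [150, 120, 100])
        assert np.all(extents < [210, 170, 150])

    def test_too_coarse_rejected(self):
        with pytest.raises(HydroformError, match="resolve"):
            SyntheticConfig(target_edge_length=2.5)


class TestMandibleArch:
    def test_single_open_component(self):
        mesh, _ = make_mandible_arch(MAND_CFG)
        assert boundary_edge_count(mesh) > 0  # open condylar cuts
        import scipy.sparse.csgraph as csg
        from scipy.sparse import coo_matrix

        adj = mesh.face_adjacency
        g = coo_matrix((np.ones(len(adj)), (adj[:, 0], adj[:, 1])),
                       shape=(len(mesh.faces),) * 2)
        n_comp, _ = csg.connected_components(g, directed=False)
        assert n_comp == 1

    def test_watertight_flag_caps_ends(self):
        mesh, _ = make_mandible_arch(MAND_CFG, watertight=True)
        assert validate(mesh).watertight
        assert mesh.volume > 0

    def test_arch_width_matches_config(self):
        mesh, _ = make_mandible_arch(MAND_CFG)
        tips = mesh.metadata["ramus_tips"]
        width = np.linalg.norm(tips["R"] - tips["L"])
        assert width == pytest.approx(mesh.metadata["arch_width"], abs=1.0)

    def test_seeds_on_surface(self):
        mesh, seeds = make_mandible_arch(MAND_CFG)
        from hydroform.proximity import ClosestPointQuery

        q = ClosestPointQuery(mesh)
        pts = np.array([seeds[n] for n in MANDIBLE_AREAS])
        _, d, _, _ = q.query(pts)
        assert np.max(d) < 1.0

    def test_deterministic(self):
        m1, _ = make_mandible_arch(MAND_CFG)
        m2, _ = make_mandible_arch(MAND_CFG)
        assert np.array_equal(m1.vertices, m2.vertices)


class TestHydrationDeformation:
    def test_uniform_enlargement_on_sphere(self):
        # mandible mode with only the enlargement term active degenerates to
        # a uniform outward offset: expected MAD 0.2 everywhere
        cfg = SyntheticConfig(
            specimen_type="mandible", target_edge_length=1.0, enlargement=0.2,
            bilateral_expansion=0.0, flattening=0.0, shape_jitter=0.0, seed=0,
        )
        sphere = trimesh.creation.icosphere(3, radius=30.0)
        wet, gt = apply_hydration_deformation(sphere, cfg)
        mags = gt.normal_magnitudes()
        assert np.allclose(mags, 0.2, atol=1e-6)
        assert gt.expected_whole_mad == pytest.approx(0.2, abs=1e-6)

    def test_zero_magnitudes_identity(self):
        cfg = SyntheticConfig(
            specimen_type="skull", target_edge_length=2.0, enlargement=0.0,
            shape_jitter=0.0, seed=0,
        )
        mesh, _ = make_skull_shell(cfg)
        wet, gt = apply_hydration_deformation(mesh, cfg)
        assert np.allclose(wet.vertices, mesh.vertices, atol=1e-12)
        assert gt.expected_whole_mad == pytest.approx(0.0, abs=1e-12)

    def test_skull_zygoma_doubling(self, skull_pair_noisefree):
        gt = skull_pair_noisefree.ground_truth["dry-vs-wet"]
        e = gt.expected_mads
        for z in ("ZR", "ZL"):
            for f in ("FM", "FR", "FL"):
                assert e[z] > 1.5 * e[f]

    def test_mandible_regional_ordering(self, mandible_pair_noisefree):
        e = mandible_pair_noisefree.ground_truth["dry-vs-wet"].expected_mads
        assert e["BR"] > e["BC"] and e["BL"] > e["BC"]
        assert e["LC"] > e["BC"]

    def test_expected_mads_recomputable(self, skull_pair_noisefree):
        sp = skull_pair_noisefree
        gt = sp.ground_truth["dry-vs-wet"]
        cfg = SyntheticConfig(specimen_type="skull", target_edge_length=2.0,
                              shape_jitter=0.0, seed=42)
        base, seeds = make_skull_shell(cfg)
        n = region_triangle_count(base)
        r = grow_region(base, seeds["FM"], n, "FM")
        assert gt.expected_regional_mad(r, base) == pytest.approx(gt.expected_mads["FM"], abs=1e-12)


class TestScanNoise:
    def test_zero_sd_is_identity(self, icosphere):
        out = add_scan_noise(icosphere, 0.0, seed=1)
        assert np.array_equal(out.vertices, icosphere.vertices)

    def test_sample_sd_converges(self):
        mesh = trimesh.creation.icosphere(5, radius=50.0)  # 10242 vertices
        out = add_scan_noise(mesh, 0.04, seed=2)
        offsets = np.einsum(
            "ij,ij->i", out.vertices - mesh.vertices, np.asarray(mesh.vertex_normals)
        )
        assert np.std(offsets) == pytest.approx(0.04, abs=0.002)

    def test_seeds_differ(self, icosphere):
        a = add_scan_noise(icosphere, 0.04, seed=1)
        b = add_scan_noise(icosphere, 0.04, seed=2)
        assert not np.array_equal(a.vertices, b.vertices)

    def test_negative_sd_rejected(self, icosphere):
        with pytest.raises(ValueError):
            add_scan_noise(icosphere, -0.1, seed=0)


class TestPerturbRigid:
    def test_zero_bounds_identity(self, icosphere):
        out, t = perturb_rigid(icosphere, 0.0, 0.0, seed=0)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-12)
        assert np.allclose(out.vertices, icosphere.vertices, atol=1e-12)

    def test_inverse_restores(self, icosphere):
        out, t = perturb_rigid(icosphere, 10.0, 10.0, seed=3)
        back = t.inverse().apply(out.vertices)
        assert np.max(np.abs(back - icosphere.vertices)) <= 1e-9

    def test_angle_distribution_respects_bound(self, icosphere):
        angles = [
            perturb_rigid(icosphere, 7.0, 0.0, seed=s)[1].rotation_angle_deg()
            for s in range(1000)
        ]
        assert max(angles) <= 7.0
        assert max(angles) >= 7.0 * 0.99


class TestGenerate:
    def test_specimen_determinism(self):
        cfg = SyntheticConfig(specimen_type="mandible", target_edge_length=2.0, seed=5)
        a = generate_specimen(cfg, "m")
        b = generate_specimen(cfg, "m")
        assert np.array_equal(a.dry.vertices, b.dry.vertices)
        assert np.array_equal(a.wet["wet"].vertices, b.wet["wet"].vertices)

    def test_study_specimens_differ(self):
        cfg = SyntheticConfig(specimen_type="mandible", target_edge_length=2.0, seed=5)
        specs = generate_study(cfg, 3)
        assert len({s.specimen_id for s in specs}) == 3
        assert not np.array_equal(specs[0].dry.vertices, specs[1].dry.vertices)

    def test_embedding_conditions_and_diff_truth(self):
        cfg = SyntheticConfig(specimen_type="skull", target_edge_length=2.0,
                              shape_jitter=0.0, seed=8)
        sp = generate_specimen(cfg, "s", conditions=("wet5", "wet15"))
        assert set(sp.wet) == {"wet5", "wet15"}
        assert set(sp.ground_truth) == {"dry-vs-wet5", "dry-vs-wet15", "wet5-vs-wet15"}
        # the embedding-time contrast is far smaller than the hydration effect
        diff = sp.ground_truth["wet5-vs-wet15"].expected_whole_mad
        main = sp.ground_truth["dry-vs-wet5"].expected_whole_mad
        assert 0 < diff < 0.5 * main
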