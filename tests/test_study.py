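"""Study orchestration: pairing, exclusion, determinism, reporting, CLI."""

import json

import numpy as np
import pytest
import trimesh

from hydroform.deviation import signed_distance_field, regional_mad
from hydroform.errors import StudyError
from hydroform.regions import grow_region
from hydroform.registration import ICPConfig
from hydroform.study import HydrationStudy, Specimen, run_pair
from hydroform.synthetic import (
    SyntheticConfig,
    generate_specimen,
    generate_study,
    perturb_rigid,
    region_triangle_count,
)


@pytest.fixture(scope="module")
def tiny_mandible_specimens():
    cfg = SyntheticConfig(specimen_type="mandible", target_edge_length=2.0, seed=21)
    return [Specimen.from_synthetic(s) for s in generate_study(cfg, 3)]


class TestRunPair:
    def test_identical_pair_zero_mad(self, mandible_pair_noisefree):
        sp = mandible_pair_noisefree
        n = region_triangle_count(sp.dry)
        regions = [grow_region(sp.dry, sp.seeds[k], n, k) for k in sp.seeds]
        reg, field, measures = run_pair(sp.dry, sp.dry.copy(), regions)
        assert all(m.mad <= 1e-9 for m in measures)

    def test_pure_rigid_motion_removed(self, mandible_pair_noisefree):
        sp = mandible_pair_noisefree
        moved, _ = perturb_rigid(sp.dry, 5.0, 5.0, seed=77)
        n = region_triangle_count(sp.dry)
        regions = [grow_region(sp.dry, sp.seeds[k], n, k) for k in sp.seeds]
        reg, field, measures = run_pair(sp.dry, moved, regions)
        assert all(m.mad <= 1e-3 for m in measures)

    def test_registration_neutrality_noise_free(self, mandible_pair_noisefree):
        """Pipeline MADs with jitter + ICP match direct measurement of the
        clean, un-misaligned pair within 2%."""
        sp = mandible_pair_noisefree
        gt = sp.ground_truth["dry-vs-wet"]
        clean_wet = trimesh.Trimesh(
            vertices=sp.dry.vertices + gt.displacement, faces=sp.dry.faces, process=False
        )
        n = region_triangle_count(sp.dry)
        regions = [grow_region(sp.dry, sp.seeds[k], n, k) for k in sp.seeds]
        _, _, piped = run_pair(sp.dry, sp.wet["wet"], regions)
        direct_field = signed_distance_field(sp.dry, clean_wet)
        for m in piped:
            region = next(r for r in regions if r.name == m.region)
            direct = regional_mad(direct_field, region, sp.dry).mad
            assert m.mad == pytest.approx(direct, rel=0.02, abs=0.005)


class TestHydrationStudy:
    def test_fit_produces_full_table(self, tiny_mandible_specimens):
        res = HydrationStudy(tiny_mandible_specimens).fit()
        assert len(res.study_table) == 3 * 6
        assert set(res.study_table["region"]) == {"BC", "BR", "BL", "LC", "LR", "LL"}
        assert (res.study_table["mad_mm"] >= 0).all()

    def test_single_specimen_gives_descriptives_without_tests(self):
        cfg = SyntheticConfig(specimen_type="mandible", target_edge_length=2.0, seed=3)
        spec = Specimen.from_synthetic(generate_specimen(cfg, "only"))
        res = HydrationStudy([spec]).fit()
        assert "mandible:dry-vs-wet" in res.descriptives
        assert not any("kruskal" in k for k in res.tests)
        assert res.exemplars == {}

    def test_duplicate_ids_rejected(self, tiny_mandible_specimens):
        s = tiny_mandible_specimens[0]
        with pytest.raises(StudyError, match="unique"):
            HydrationStudy([s, s])

    def test_dropping_specimen_leaves_other_rows_unchanged(self, tiny_mandible_specimens):
        full = HydrationStudy(tiny_mandible_specimens).fit().study_table
        partial = HydrationStudy(tiny_mandible_specimens[:2]).fit().study_table
        kept = full[full["specimen_id"].isin(partial["specimen_id"])].reset_index(drop=True)
        assert kept.equals(partial)

    def test_bad_specimen_excluded_with_log(self, tiny_mandible_specimens, caplog):
        bad = Specimen(
            specimen_id="BAD",
            specimen_type="mandible",
            dry=tiny_mandible_specimens[0].dry,
            wet=dict(tiny_mandible_specimens[0].wet),
            seeds={k: v + 500.0 for k, v in tiny_mandible_specimens[0].seeds.items()},
        )
        res = HydrationStudy(tiny_mandible_specimens + [bad]).fit()
        assert [f["specimen_id"] for f in res.failures] == ["BAD"]
        assert set(res.study_table["specimen_id"]) == {
            s.specimen_id for s in tiny_mandible_specimens
        }

    def test_exemplars_are_true_extremes(self, tiny_mandible_specimens):
        res = HydrationStudy(tiny_mandible_specimens).fit()
        lo, mid, hi = res.exemplars["mandible:dry-vs-wet"]
        per_spec = res.study_table.groupby("specimen_id")["mad_mm"].mean()
        assert per_spec[lo] == per_spec.min()
        assert per_spec[hi] == per_spec.max()

    def test_volume_correlation_on_watertight_dry_models(self):
        cfg = SyntheticConfig(specimen_type="skull", target_edge_length=2.0, seed=17)
        specs = [Specimen.from_synthetic(s) for s in generate_study(cfg, 3)]
        res = HydrationStudy(specs).fit()
        sp = res.volume_correlation()
        assert sp is not None
        assert -1.0 <= sp.statistic <= 1.0


class TestDeterminismAndReports:
    def test_refit_is_identical(self, tiny_mandible_specimens):
        a = HydrationStudy(tiny_mandible_specimens, seed=1).fit().study_table
        b = HydrationStudy(tiny_mandible_specimens, seed=1).fit().study_table
        assert a.equals(b)

    def test_save_twice_is_byte_identical(self, tiny_mandible_specimens, tmp_path):
        res = HydrationStudy(tiny_mandible_specimens).fit()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        res.save(d1)
        res.save(d2)
        for name in ("study_table.csv", "results.json", "boxplot_data.csv", "summary.txt"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_exemplar_maps_parse_as_ply(self, tiny_mandible_specimens, tmp_path):
        res = HydrationStudy(tiny_mandible_specimens).fit()
        res.save(tmp_path)
        maps = sorted(tmp_path.glob("map_*.ply"))
        assert maps
        back = trimesh.load(maps[0], process=False)
        assert len(back.vertices) > 0

    def test_summary_mentions_descriptives(self, tiny_mandible_specimens):
        res = HydrationStudy(tiny_mandible_specimens).fit()
        text = res.summary()
        assert "median MAD" in text and "mandible:dry-vs-wet" in text

    def test_boxplot_png(self, tiny_mandible_specimens, tmp_path):
        res = HydrationStudy(tiny_mandible_specimens).fit()
        res.plot_boxes(tmp_path / "boxes.png")
        assert (tmp_path / "boxes.png").stat().st_size > 0


class TestCLI:
    def test_generate_then_run_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from hydroform.cli import main

        runner = CliRunner()
        gen = runner.invoke(
            main,
            ["generate", str(tmp_path / "study"), "--type", "mandible",
             "--n", "1", "--edge", "2.0", "--seed", "4"],
        )
        assert gen.exit_code == 0, gen.output
        assert (tmp_path / "study" / "manifest.json").exists()
        spec_dirs = [p for p in (tmp_path / "study").iterdir() if p.is_dir()]
        for f in ("dry.stl", "wet.stl", "seeds.json", "regions.json", "ground_truth.json"):
            assert (spec_dirs[0] / f).exists()
        run = runner.invoke(
            main,
            ["run", str(tmp_path / "study" / "study.json"),
             "--out", str(tmp_path / "out"), "--maps", "none"],
        )
        assert run.exit_code == 0, run.output
        assert (tmp_path / "out" / "study_table.csv").exists()

    def test_compare_command(self, tmp_path):
        from click.testing import CliRunner

        from hydroform.cli import main
        from hydroform.mesh_io import write_stl

        cfg = SyntheticConfig(specimen_type="mandible", target_edge_length=2.0,
                              shape_jitter=0.0, seed=9)
        sp = generate_specimen(cfg, "c")
        write_stl(sp.dry, tmp_path / "dry.stl")
        write_stl(sp.wet["wet"], tmp_path / "wet.stl")
        (tmp_path / "seeds.json").write_text(
            json.dumps({k: list(map(float, v)) for k, v in sp.seeds.items()})
        )
        runner = CliRunner()
        out = runner.invoke(
            main,
            ["compare", str(tmp_path / "dry.stl"), str(tmp_path / "wet.stl"),
             "--seeds", str(tmp_path / "seeds.json"), "--type", "mandible"],
        )
        assert out.exit_code == 0, out.output
        assert "MAD" in out.output
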