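"""End-to-end study orchestration: pair, register, measure, map, test.

The entry point mirrors a statistical modelling API: a
:class:`HydrationStudy` is built from specimen data (meshes in memory, file
paths, or a config file) and ``fit()`` runs the full measurement pipeline —
landmark initialisation where available, ICP restricted to the
superimposition reference area, signed deviation fields on the reference
model, MAD per measurement area — and returns a :class:`StudyResults`
object carrying the long-format study table, registration diagnostics,
descriptives, the nonparametric test battery and exemplar selection, with
``summary()`` and ``save()`` for reporting.

Pair convention throughout: in a ``dry-vs-wet`` comparison the dry model is
the fixed reference and measurement surface; in the embedding-time
comparison ``wet5-vs-wet15`` the short-embedding model is the reference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import stats as hstats
from .deviation import (
    DEFAULT_D_MAX_MM,
    DeviationField,
    RegionDeviation,
    regional_mad,
    select_exemplars,
    signed_distance_field,
    whole_mesh_summary,
)
from .errors import StudyError
from .mesh_io import DEFAULT_CLAMP_MM, boundary_edge_count, mesh_volume, read_stl, write_distance_map
from .proximity import ClosestPointQuery
from .regions import MANDIBLE_AREAS, SKULL_AREAS, Region, grow_region, region_from_mask
from .registration import ICPConfig, RegistrationResult, apply_transform, icp_register, landmark_align
from .synthetic import SyntheticSpecimen, region_triangle_count

__all__ = ["Specimen", "HydrationStudy", "StudyResults", "run_pair", "run_study"]

log = logging.getLogger("hydroform.study")


@dataclass
class Specimen:
    """One specimen entry: a dry reference model plus wet test model(s)."""

    specimen_id: str
    specimen_type: str  # "skull" | "mandible"
    dry: trimesh.Trimesh
    wet: Dict[str, trimesh.Trimesh]  # condition -> mesh
    seeds: Dict[str, np.ndarray]  # measurement-area name -> 3D seed point
    landmarks: Optional[tuple] = None  # (wet-frame points, dry-frame points)
    reference_faces: Optional[np.ndarray] = None  # superimposition mask on the reference

    @classmethod
    def from_synthetic(cls, s: SyntheticSpecimen) -> "Specimen":
        return cls(s.specimen_id, s.specimen_type, s.dry, dict(s.wet), dict(s.seeds))


@dataclass
class PairOutcome:
    specimen_id: str
    comparison: str
    registration: RegistrationResult
    field: DeviationField
    regional: List[RegionDeviation]
    reference_mesh: trimesh.Trimesh
    whole: RegionDeviation


def run_pair(
    reference: trimesh.Trimesh,
    test: trimesh.Trimesh,
    regions: List[Region],
    icp: Optional[ICPConfig] = None,
    d_max: float = DEFAULT_D_MAX_MM,
    landmarks: Optional[tuple] = None,
    reference_region: Optional[Region] = None,
):
    """Superimpose one model pair and measure regional MADs.

    The test model is aligned onto the fixed reference (landmark
    initialisation when given, then ICP optionally restricted to the
    reference area); the deviation field is sampled on the reference mesh.
    Raises :class:`StudyError` if the registration diverges (final rms
    worse than initial).
    """
    init = None
    if landmarks is not None:
        init = landmark_align(np.asarray(landmarks[0]), np.asarray(landmarks[1]))
    reg = icp_register(
        test, reference, config=icp, init=init, target_region=reference_region
    )
    if len(reg.rms_history) >= 2 and reg.rms_history[-1] > reg.rms_history[0]:
        raise StudyError(
            f"registration diverged: rms {reg.rms_history[0]:.4f} -> "
            f"{reg.rms_history[-1]:.4f} mm"
        )
    aligned = apply_transform(test, reg.transform)
    field = signed_distance_field(reference, aligned, d_max=d_max)
    measures = [regional_mad(field, r, reference) for r in regions]
    return reg, field, measures


class HydrationStudy:
    """Study model: specimens plus measurement settings; ``fit()`` runs it.

    Parameters
    ----------
    specimens : list of :class:`Specimen`
    icp : ICP settings (study defaults if omitted)
    d_max : correspondence cutoff in mm for the deviation fields
    region_triangles : triangle count per measurement area; if None it is
        chosen per mesh to match the protocol's patch area (10,000 triangles
        at 0.3 mm resolution)
    seed : base seed forwarded to ICP sampling
    """

    def __init__(
        self,
        specimens: List[Specimen],
        icp: Optional[ICPConfig] = None,
        d_max: float = DEFAULT_D_MAX_MM,
        region_triangles: Optional[int] = None,
        seed: int = 0,
    ):
        if not specimens:
            raise StudyError("study needs at least one specimen")
        ids = [s.specimen_id for s in specimens]
        if len(set(ids)) != len(ids):
            raise StudyError("specimen ids must be unique")
        self.specimens = specimens
        self.icp = icp or ICPConfig(seed=seed)
        self.d_max = d_max
        self.region_triangles = region_triangles
        self.seed = seed

    # ------------------------------------------------------------------
    @classmethod
    def from_config(cls, config_path) -> "HydrationStudy":
        """Build a study from a YAML/JSON config of file paths.

        Expected layout::

            seed: 0
            d_max: 5.0
            icp: {metric: point-to-plane, max_iterations: 50, ...}
            specimens:
              - id: SK01
                type: skull
                dry: path/dry.stl
                wet: {wet: path/wet.stl}
                seeds: path/seeds.json        # name -> [x, y, z]
                reference_mask: path/mask.json  # optional face-id list
                landmarks: path/landmarks.json  # optional {test: [...], reference: [...]}
        """
        config_path = Path(config_path)
        raw = yaml.safe_load(config_path.read_text())
        base = config_path.parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        specimens = []
        for entry in raw.get("specimens", []):
            seeds = json.loads(_resolve(entry["seeds"]).read_text())
            landmarks = None
            if entry.get("landmarks"):
                lm = json.loads(_resolve(entry["landmarks"]).read_text())
                landmarks = (np.asarray(lm["test"]), np.asarray(lm["reference"]))
            mask = None
            if entry.get("reference_mask"):
                mask = np.asarray(json.loads(_resolve(entry["reference_mask"]).read_text()))
            specimens.append(
                Specimen(
                    specimen_id=str(entry["id"]),
                    specimen_type=entry["type"],
                    dry=read_stl(_resolve(entry["dry"])),
                    wet={c: read_stl(_resolve(p)) for c, p in entry["wet"].items()},
                    seeds={k: np.asarray(v) for k, v in seeds.items()},
                    landmarks=landmarks,
                    reference_faces=mask,
                )
            )
        icp = ICPConfig.from_dict(raw["icp"]) if raw.get("icp") else None
        return cls(
            specimens,
            icp=icp,
            d_max=float(raw.get("d_max", DEFAULT_D_MAX_MM)),
            region_triangles=raw.get("region_triangles"),
            seed=int(raw.get("seed", 0)),
        )

    # ------------------------------------------------------------------
    def _comparisons(self, specimen: Specimen):
        conditions = list(specimen.wet)
        for cond in conditions:
            yield f"dry-vs-{cond}", specimen.dry, specimen.wet[cond]
        if "wet5" in conditions and "wet15" in conditions:
            yield "wet5-vs-wet15", specimen.wet["wet5"], specimen.wet["wet15"]

    def fit(self) -> "StudyResults":
        """Run registration and measurement for every pair and assemble the
        statistical report."""
        rows = []
        outcomes: List[PairOutcome] = []
        failures = []
        for spec in self.specimens:
            area_names = SKULL_AREAS if spec.specimen_type == "skull" else MANDIBLE_AREAS
            for comparison, reference, test in self._comparisons(spec):
                try:
                    n_tri = self.region_triangles or region_triangle_count(reference)
                    regions = [
                        grow_region(reference, spec.seeds[name], n_tri, name)
                        for name in area_names
                    ]
                    ref_region = None
                    if spec.reference_faces is not None:
                        ref_region, _ = region_from_mask(
                            reference, spec.reference_faces, name="reference-area"
                        )
                    reg, field, measures = run_pair(
                        reference,
                        test,
                        regions,
                        icp=self.icp,
                        d_max=self.d_max,
                        landmarks=spec.landmarks,
                        reference_region=ref_region,
                    )
                except Exception as exc:  # exclude-with-log keeps batch runs alive
                    log.warning(
                        "specimen %s %s excluded: %s", spec.specimen_id, comparison, exc
                    )
                    failures.append(
                        {"specimen_id": spec.specimen_id, "comparison": comparison, "error": str(exc)}
                    )
                    continue
                log.info(
                    "specimen %s %s: rms %.4f mm after %d iterations",
                    spec.specimen_id, comparison, reg.rms_residual, len(reg.rms_history),
                )
                outcomes.append(
                    PairOutcome(
                        spec.specimen_id, comparison, reg, field, measures,
                        reference, whole_mesh_summary(field),
                    )
                )
                for m in measures:
                    rows.append(
                        (spec.specimen_id, spec.specimen_type, comparison, m.region, m.mad)
                    )
        if not outcomes:
            raise StudyError("no specimen pair completed successfully")
        table = hstats.make_study_table(rows)
        return StudyResults(self, table, outcomes, failures)


class StudyResults:
    """Fitted study: measurement table, diagnostics, tests and reports."""

    def __init__(self, model: HydrationStudy, study_table: pd.DataFrame,
                 outcomes: List[PairOutcome], failures: List[dict]):
        self.model = model
        self.study_table = study_table
        self.outcomes = outcomes
        self.failures = failures
        self.tests: Dict[str, hstats.TestResult] = {}
        self.descriptives: Dict[str, hstats.Descriptives] = {}
        self.exemplars: Dict[str, tuple] = {}
        self._analyse()

    # ------------------------------------------------------------------
    def _analyse(self):
        t = self.study_table
        for (stype, comparison), sub in t.groupby(["type", "comparison"], sort=True):
            key = f"{stype}:{comparison}"
            self.descriptives[key] = hstats.describe(sub["mad_mm"].to_numpy())
            area_names = SKULL_AREAS if stype == "skull" else MANDIBLE_AREAS
            groups, labels = [], []
            for name in area_names:
                vals = sub.loc[sub["region"] == name, "mad_mm"].to_numpy()
                if len(vals):
                    groups.append(vals)
                    labels.append(name)
            # across-area comparison: unpaired (Kruskal-Wallis + Dunn) for the
            # hydration contrasts, paired (Friedman) for embedding time
            if comparison == "wet5-vs-wet15":
                pivot = sub.pivot_table(index="specimen_id", columns="region", values="mad_mm")
                pivot = pivot.reindex(columns=[n for n in area_names if n in pivot.columns])
                if pivot.shape[0] >= 2 and pivot.notna().all().all():
                    self.tests[f"{key}:friedman"] = hstats.friedman(pivot.to_numpy())
                    self.tests[f"{key}:dunn"] = hstats.dunn_posthoc(groups, labels=labels)
            elif len(groups) >= 2 and all(len(g) for g in groups) and sum(map(len, groups)) >= 3:
                if len(t["specimen_id"].unique()) >= 2:
                    kw = hstats.kruskal_wallis(groups)
                    self.tests[f"{key}:kruskal-wallis"] = kw
                    if kw.p_value < hstats.ALPHA:
                        self.tests[f"{key}:dunn"] = hstats.dunn_posthoc(groups, labels=labels)

        # exemplar specimens per type/comparison: min, closest-to-mean, max
        # specimen-level MAD over the pre-specified measurement areas
        for (stype, comparison), sub in t.groupby(["type", "comparison"], sort=True):
            per_spec = sub.groupby("specimen_id", sort=True)["mad_mm"].mean()
            if len(per_spec) >= 3:
                self.exemplars[f"{stype}:{comparison}"] = select_exemplars(
                    list(per_spec.items())
                )

    # ------------------------------------------------------------------
    def volume_correlation(self, comparison: str = "dry-vs-wet"):
        """Spearman correlation between dry-model volume and specimen-level
        MAD, computed only over specimens whose dry model is watertight
        (volume requires a closed surface).  Returns None when fewer than
        three qualify."""
        per_spec = (
            self.study_table[self.study_table["comparison"] == comparison]
            .groupby("specimen_id", sort=True)["mad_mm"]
            .mean()
        )
        vols, mads = [], []
        for spec in self.model.specimens:
            if spec.specimen_id in per_spec.index and boundary_edge_count(spec.dry) == 0:
                vols.append(mesh_volume(spec.dry))
                mads.append(per_spec[spec.specimen_id])
        if len(vols) < 3:
            return None
        return hstats.spearman(vols, mads)

    def boxplot_table(self) -> pd.DataFrame:
        """Per (type, comparison, region) box-plot summary rows."""
        rows = []
        for (stype, comparison, region), sub in self.study_table.groupby(
            ["type", "comparison", "region"], sort=True
        ):
            b = hstats.boxplot_stats(sub["mad_mm"].to_numpy())
            rows.append(
                {
                    "type": stype, "comparison": comparison, "region": region,
                    **{k: b[k] for k in ("q1", "median", "q3", "whisker_low", "whisker_high")},
                    "n_outliers": len(b["outliers"]), "n_extremes": len(b["extremes"]),
                }
            )
        return pd.DataFrame(rows)

    def plot_boxes(self, path, comparison: str = None):
        """Box plots of MAD per measurement area, one panel per type."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.study_table
        if comparison is not None:
            t = t[t["comparison"] == comparison]
        types = sorted(t["type"].unique())
        fig, axes = plt.subplots(1, len(types), figsize=(6 * len(types), 4), squeeze=False)
        for ax, stype in zip(axes[0], types):
            sub = t[t["type"] == stype]
            order = SKULL_AREAS if stype == "skull" else MANDIBLE_AREAS
            data = [sub.loc[sub["region"] == r, "mad_mm"].to_numpy() for r in order]
            ax.boxplot(data, tick_labels=list(order))
            ax.set_title(stype)
            ax.set_ylabel("MAD (mm)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text report mirroring the study's results structure."""
        lines = ["Hydration form-change study", "=" * 29, ""]
        for key in sorted(self.descriptives):
            d = self.descriptives[key]
            lines.append(
                f"{key}: median MAD {d.median:.3f} mm (IQR {d.iqr:.3f}; "
                f"range {d.min:.3f}, {d.max:.3f})"
            )
            kw = self.tests.get(f"{key}:kruskal-wallis")
            if kw:
                lines.append(
                    f"  across measurement areas: Kruskal-Wallis H = {kw.statistic:.2f}, "
                    f"df = {kw.df:.0f}, p = {kw.p_value:.4g}"
                )
            fr = self.tests.get(f"{key}:friedman")
            if fr:
                lines.append(
                    f"  across measurement areas (paired): Friedman chi2 = "
                    f"{fr.statistic:.2f}, df = {fr.df:.0f}, p = {fr.p_value:.4g}"
                )
            dunn = self.tests.get(f"{key}:dunn")
            if dunn is not None and dunn.pairwise is not None:
                sig = dunn.pairwise[dunn.pairwise["p_adj"] < hstats.ALPHA]
                if len(sig):
                    pairs = ", ".join(f"{r.group_1}-{r.group_2}" for r in sig.itertuples())
                    lines.append(f"  significant pairs (Dunn, Bonferroni): {pairs}")
                else:
                    lines.append("  no significant pairwise differences (Dunn, Bonferroni)")
            ex = self.exemplars.get(key)
            if ex:
                lines.append(f"  exemplar specimens (min/avg/max): {ex[0]}/{ex[1]}/{ex[2]}")
            lines.append("")
        if self.failures:
            lines.append(f"excluded pairs: {len(self.failures)}")
            for f in self.failures:
                lines.append(f"  {f['specimen_id']} {f['comparison']}: {f['error']}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, outdir, distance_maps: str = "exemplars"):
        """Write the study artefacts: study table CSV, results JSON, box-plot
        CSV, summary text and PLY distance maps (``exemplars``, ``all`` or
        ``none``).  Output is deterministic for a fixed study and seed."""
        outdir = Path(outdir)
        try:
            outdir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise IOError(f"cannot create output directory {outdir}: {exc}") from exc

        self.study_table.sort_values(
            ["specimen_id", "comparison", "region"], kind="stable"
        ).to_csv(outdir / "study_table.csv", index=False)
        self.boxplot_table().to_csv(outdir / "boxplot_data.csv", index=False)

        payload = {
            "descriptives": {
                k: {"median": d.median, "iqr": d.iqr, "min": d.min, "max": d.max}
                for k, d in sorted(self.descriptives.items())
            },
            "tests": {k: v.to_dict() for k, v in sorted(self.tests.items())},
            "exemplars": {k: list(v) for k, v in sorted(self.exemplars.items())},
            "registrations": {
                f"{o.specimen_id}:{o.comparison}": o.registration.to_dict()
                for o in self.outcomes
            },
            "failures": self.failures,
        }
        (outdir / "results.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        (outdir / "summary.txt").write_text(self.summary() + "\n")

        if distance_maps != "none":
            chosen = set()
            if distance_maps == "all":
                chosen = {(o.specimen_id, o.comparison) for o in self.outcomes}
            else:
                for key, (lo, mid, hi) in self.exemplars.items():
                    comparison = key.split(":", 1)[1]
                    chosen |= {(s, comparison) for s in (lo, mid, hi)}
            for o in self.outcomes:
                if (o.specimen_id, o.comparison) in chosen:
                    stype = next(
                        s.specimen_type for s in self.model.specimens
                        if s.specimen_id == o.specimen_id
                    )
                    write_distance_map(
                        o.reference_mesh,
                        o.field.signed_distance,
                        clamp=DEFAULT_CLAMP_MM[stype],
                        path=outdir / f"map_{o.specimen_id}_{o.comparison}.ply",
                    )
        return outdir


def run_study(config_path, outdir=None) -> StudyResults:
    """Convenience wrapper: load a study config, fit it, optionally save."""
    results = HydrationStudy.from_config(config_path).fit()
    if outdir is not None:
        results.save(outdir)
    return results
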