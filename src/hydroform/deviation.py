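"""Signed surface-deviation fields and regional mean absolute distances.

After superimposition, the form change of a specimen is quantified by the
mean absolute distance (MAD) between its two models: zero MAD means perfect
congruence, larger MAD a larger hydration effect.  Distances are sampled at
the vertices of the measured (dry, reference) mesh; the sign is geometric —
positive where the other surface lies outside the measured surface along
its outward normal, matching the red/blue convention of the colour maps.
Vertices whose closest point falls beyond ``d_max`` or on a boundary edge
of the other model have no corresponding surface and are excluded (the grey
areas of the maps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import trimesh

from .errors import MeshGeometryError, RegionError
from .proximity import ClosestPointQuery
from .regions import Region

__all__ = [
    "DeviationField",
    "RegionDeviation",
    "signed_distance_field",
    "regional_mad",
    "whole_mesh_summary",
    "select_exemplars",
]

#: default correspondence cutoff (mm): far above any plausible hydration
#: deviation yet small enough to reject non-homologous surface
DEFAULT_D_MAX_MM = 5.0


@dataclass
class DeviationField:
    """Per-vertex signed distances from a measured mesh to another surface."""

    signed_distance: np.ndarray  # mm; NaN where no correspondence
    has_correspondence: np.ndarray  # bool per sample
    d_max: float

    def __post_init__(self):
        self.signed_distance = np.asarray(self.signed_distance, dtype=np.float64)
        self.has_correspondence = np.asarray(self.has_correspondence, dtype=bool)
        if self.signed_distance.shape != self.has_correspondence.shape:
            raise ValueError("signed_distance and has_correspondence differ in length")

    def __len__(self):
        return len(self.signed_distance)

    @property
    def fraction_corresponding(self) -> float:
        return float(self.has_correspondence.mean())

    def masked(self) -> np.ndarray:
        """Signed distances at corresponding samples only."""
        return self.signed_distance[self.has_correspondence]


@dataclass(frozen=True)
class RegionDeviation:
    """MAD and distributional summaries of |signed distance| in one region."""

    region: str
    mad: float
    median_abs: float
    iqr_abs: float
    n_samples: int
    fraction_corresponding: float

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "mad_mm": self.mad,
            "median_abs_mm": self.median_abs,
            "iqr_abs_mm": self.iqr_abs,
            "n_samples": self.n_samples,
            "fraction_corresponding": self.fraction_corresponding,
        }


def signed_distance_field(
    measured: trimesh.Trimesh,
    other: trimesh.Trimesh,
    d_max: float = DEFAULT_D_MAX_MM,
    other_query: Optional[ClosestPointQuery] = None,
) -> DeviationField:
    """Signed distance from every vertex of ``measured`` to ``other``.

    Both meshes must already be in a common frame (post-registration).
    Magnitude is the exact Euclidean point-to-surface distance; the sign is
    that of (closest point − vertex)·n̂ with n̂ the measured mesh's outward
    vertex normal, so the field is positive where the other surface lies
    outside the measured one.  Correspondence is dropped beyond ``d_max``
    and where the closest point lies on a boundary feature of ``other``.
    """
    if len(measured.vertices) == 0 or len(measured.faces) == 0:
        raise MeshGeometryError("measured mesh is empty")
    if len(other.vertices) == 0 or len(other.faces) == 0:
        raise MeshGeometryError("other mesh is empty")
    query = other_query if other_query is not None else ClosestPointQuery(other)
    pts = np.asarray(measured.vertices, dtype=np.float64)
    cp, d, tid, bary = query.query(pts)

    normals = np.asarray(measured.vertex_normals, dtype=np.float64)
    # positive where the other (test) surface lies outside the measured
    # (reference) surface along its outward normal — red in the colour maps
    side = np.einsum("ij,ij->i", cp - pts, normals)
    sign = np.where(side < 0, -1.0, 1.0)

    corr = (d <= d_max) & ~query.on_boundary(tid, bary)
    signed = np.where(corr, sign * d, np.nan)
    return DeviationField(signed, corr, d_max)


def _summaries(abs_values: np.ndarray):
    mad = float(abs_values.mean())
    median = float(np.median(abs_values))
    q1, q3 = np.percentile(abs_values, [25, 75])  # linear-interpolation quartiles
    return mad, median, float(q3 - q1)


def regional_mad(
    field: DeviationField,
    region: Region,
    mesh: trimesh.Trimesh,
) -> RegionDeviation:
    """MAD of |signed distance| over the corresponding samples whose
    vertices belong to the region's faces on the measured mesh."""
    vids = region.vertex_ids(mesh)
    corr = field.has_correspondence[vids]
    values = np.abs(field.signed_distance[vids][corr])
    if len(values) == 0:
        raise RegionError(f"region {region.name!r} has no corresponding samples")
    mad, median, iqr = _summaries(values)
    return RegionDeviation(
        region=region.name,
        mad=mad,
        median_abs=median,
        iqr_abs=iqr,
        n_samples=int(len(vids)),
        fraction_corresponding=float(corr.mean()),
    )


def whole_mesh_summary(field: DeviationField, name: str = "whole-mesh") -> RegionDeviation:
    """Same statistics over every corresponding sample of the field."""
    values = np.abs(field.masked())
    if len(values) == 0:
        raise RegionError("field has no corresponding samples")
    mad, median, iqr = _summaries(values)
    return RegionDeviation(
        region=name,
        mad=mad,
        median_abs=median,
        iqr_abs=iqr,
        n_samples=len(field),
        fraction_corresponding=field.fraction_corresponding,
    )


def select_exemplars(per_specimen_mads: Sequence):
    """Pick the specimens with minimum, closest-to-mean and maximum summary
    MAD over the pre-specified measurement areas (for the exemplar colour
    maps).  Ties resolve to the earlier entry.
    """
    items = list(per_specimen_mads)
    if len(items) < 3:
        raise ValueError(f"exemplar selection needs >= 3 specimens, got {len(items)}")
    ids = [i for i, _ in items]
    vals = np.asarray([v for _, v in items], dtype=np.float64)
    mean = vals.mean()
    i_min = min(range(len(vals)), key=lambda i: (vals[i], i))
    i_max = min(range(len(vals)), key=lambda i: (-vals[i], i))
    i_avg = min(range(len(vals)), key=lambda i: (abs(vals[i] - mean), i))
    return ids[i_min], ids[i_avg], ids[i_max]
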