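"""Named, contiguous triangle patches: superimposition reference areas and
circular measurement areas.

The study protocol defines each measurement site by picking a circular patch
of a fixed triangle count around an anatomical location; :func:`grow_region`
realises that as deterministic distance-ordered connected growth from a seed
point.  Hand-painted reference areas enter through :func:`region_from_mask`.
Skull catalogs carry ten measurement areas (FM, FR, FL, MR, ML, ZR, ZL, SM,
ACR, ACL), mandible catalogs six (BC, BR, BL, LC, LR, LL).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import RegionError
from .proximity import ClosestPointQuery

__all__ = [
    "Region",
    "RegionCatalog",
    "grow_region",
    "region_from_mask",
    "transfer_region",
    "SKULL_AREAS",
    "MANDIBLE_AREAS",
]

SKULL_AREAS = ("FM", "FR", "FL", "MR", "ML", "ZR", "ZL", "SM", "ACR", "ACL")
MANDIBLE_AREAS = ("BC", "BR", "BL", "LC", "LR", "LL")

#: a measurement seed further than this from the surface is rejected (mm)
MAX_SEED_DISTANCE_MM = 10.0


def _face_adjacency_lists(mesh: trimesh.Trimesh):
    adj = np.asarray(mesh.face_adjacency)
    lists: list[list[int]] = [[] for _ in range(len(mesh.faces))]
    for a, b in adj:
        lists[a].append(int(b))
        lists[b].append(int(a))
    return lists


@dataclass
class Region:
    """A named, edge-connected set of triangle indices on one mesh."""

    name: str
    face_ids: np.ndarray
    seed: Optional[np.ndarray] = None

    def __post_init__(self):
        self.face_ids = np.unique(np.asarray(self.face_ids, dtype=np.int64))
        if len(self.face_ids) == 0:
            raise RegionError(f"region {self.name!r} has no faces")
        if self.seed is not None:
            self.seed = np.asarray(self.seed, dtype=np.float64).reshape(3)

    def __len__(self):
        return len(self.face_ids)

    def vertex_ids(self, mesh: trimesh.Trimesh) -> np.ndarray:
        return np.unique(np.asarray(mesh.faces)[self.face_ids])

    def area(self, mesh: trimesh.Trimesh) -> float:
        return float(np.asarray(mesh.area_faces)[self.face_ids].sum())

    def is_connected(self, mesh: trimesh.Trimesh) -> bool:
        labels = _component_labels(mesh, self.face_ids)
        return labels.max() == 0 if len(labels) else False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "face_ids": [int(i) for i in self.face_ids],
            "seed": None if self.seed is None else [float(x) for x in self.seed],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Region":
        return cls(d["name"], np.asarray(d["face_ids"]), d.get("seed"))


@dataclass
class RegionCatalog:
    """All regions defined on one mesh, with their study role."""

    mesh_id: str
    regions: list = field(default_factory=list)
    roles: dict = field(default_factory=dict)  # name -> "superimposition-reference" | "measurement"
    specimen_type: Optional[str] = None

    def __post_init__(self):
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise RegionError(f"duplicate region names in catalog {self.mesh_id!r}")
        if self.specimen_type is not None:
            expected = {"skull": set(SKULL_AREAS), "mandible": set(MANDIBLE_AREAS)}[self.specimen_type]
            measured = {n for n in names if self.roles.get(n) == "measurement"}
            if measured and measured != expected:
                raise RegionError(
                    f"{self.specimen_type} catalog must carry measurement areas "
                    f"{sorted(expected)}, got {sorted(measured)}"
                )

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def measurement_regions(self) -> list:
        return [r for r in self.regions if self.roles.get(r.name) == "measurement"]

    def reference_region(self) -> Optional[Region]:
        for r in self.regions:
            if self.roles.get(r.name) == "superimposition-reference":
                return r
        return None

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "mesh_id": self.mesh_id,
                "specimen_type": self.specimen_type,
                "regions": [
                    {**r.to_dict(), "role": self.roles.get(r.name, "measurement")}
                    for r in self.regions
                ],
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "RegionCatalog":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) else source
        d = json.loads(text)
        regions = [Region.from_dict(r) for r in d["regions"]]
        roles = {r["name"]: r.get("role", "measurement") for r in d["regions"]}
        return cls(d["mesh_id"], regions, roles, d.get("specimen_type"))


def grow_region(
    mesh: trimesh.Trimesh,
    seed: np.ndarray,
    n_triangles: int,
    name: str = "region",
) -> Region:
    """Grow a circular measurement area of exactly ``n_triangles`` faces.

    Starting from the face nearest the seed point, faces are admitted in
    ascending order of Euclidean centroid-to-seed distance, restricted to
    faces edge-adjacent to the already-selected patch, so the result is a
    contiguous quasi-circular cap.  Ties in distance break on the centroid
    coordinates (lexicographically) and then the face index, making the
    growth deterministic and independent of face ordering.
    """
    seed = np.asarray(seed, dtype=np.float64).reshape(3)
    if n_triangles < 1 or n_triangles > len(mesh.faces):
        raise RegionError(
            f"cannot grow {n_triangles} triangles on a mesh of {len(mesh.faces)} faces"
        )
    query = ClosestPointQuery(mesh)
    _, d, tid, _ = query.query(seed[None])
    if d[0] > MAX_SEED_DISTANCE_MM:
        raise RegionError(
            f"seed {seed.tolist()} is {d[0]:.2f} mm from the surface "
            f"(limit {MAX_SEED_DISTANCE_MM} mm)"
        )
    start = int(tid[0])

    centroids = np.asarray(mesh.triangles_center)
    cent_d = np.linalg.norm(centroids - seed, axis=1)
    adjacency = _face_adjacency_lists(mesh)

    def _key(f):
        return (cent_d[f], centroids[f, 0], centroids[f, 1], centroids[f, 2], f)

    selected = np.zeros(len(mesh.faces), dtype=bool)
    queued = np.zeros(len(mesh.faces), dtype=bool)
    heap = [_key(start)]
    queued[start] = True
    chosen = []
    while heap and len(chosen) < n_triangles:
        f = heapq.heappop(heap)[-1]
        if selected[f]:
            continue
        selected[f] = True
        chosen.append(f)
        for g in adjacency[f]:
            if not queued[g]:
                queued[g] = True
                heapq.heappush(heap, _key(g))
    if len(chosen) < n_triangles:
        raise RegionError(
            f"connected patch around seed exhausted at {len(chosen)} faces "
            f"(requested {n_triangles})"
        )
    return Region(name, np.asarray(chosen), seed)


def _component_labels(mesh: trimesh.Trimesh, face_ids: np.ndarray) -> np.ndarray:
    """Connected-component label per face of the sub-patch ``face_ids``."""
    face_ids = np.asarray(face_ids)
    pos = -np.ones(len(mesh.faces), dtype=np.int64)
    pos[face_ids] = np.arange(len(face_ids))
    adj = np.asarray(mesh.face_adjacency)
    if len(adj):
        mask = (pos[adj[:, 0]] >= 0) & (pos[adj[:, 1]] >= 0)
        rows, cols = pos[adj[mask, 0]], pos[adj[mask, 1]]
    else:
        rows = cols = np.zeros(0, dtype=np.int64)
    n = len(face_ids)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def region_from_mask(mesh: trimesh.Trimesh, face_ids, name: str = "mask"):
    """Wrap an externally supplied (e.g. hand-painted) face set as a Region.

    Only the largest edge-connected component is kept; returns
    ``(region, n_discarded)``.  Ties between equally large components break
    to the one containing the lowest face index.
    """
    face_ids = np.unique(np.asarray(face_ids, dtype=np.int64))
    valid = face_ids[(face_ids >= 0) & (face_ids < len(mesh.faces))]
    if len(valid) == 0:
        raise RegionError(f"mask {name!r} contains no valid face indices")
    labels = _component_labels(mesh, valid)
    sizes = np.bincount(labels)
    best = int(np.flatnonzero(sizes == sizes.max())[0])  # labels ordered by first face
    keep = valid[labels == best]
    return Region(name, keep), int(len(valid) - len(keep))


def transfer_region(
    region: Region,
    from_mesh: trimesh.Trimesh,
    to_mesh: trimesh.Trimesh,
    d_max: float = 1.0,
) -> Region:
    """Carry a region across a superimposed mesh pair.

    Selects the faces of ``to_mesh`` whose centroids project onto the region
    (their closest point on ``from_mesh`` falls on a region face) within
    ``d_max`` mm, and keeps the largest connected component, so homologous
    areas can be measured on both models.
    """
    query = ClosestPointQuery(from_mesh)
    cent = np.asarray(to_mesh.triangles_center)
    _, d, tid, _ = query.query(cent)
    hits = np.flatnonzero(np.isin(tid, region.face_ids) & (d <= d_max))
    if len(hits) == 0:
        raise RegionError(
            f"region {region.name!r} transfers to no faces within {d_max} mm "
            "(are the meshes superimposed?)"
        )
    out, _ = region_from_mask(to_mesh, hits, name=region.name)
    out.seed = None if region.seed is None else region.seed.copy()
    return out
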