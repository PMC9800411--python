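"""Surface-model I/O, validation and volume.

Meshes are carried as :class:`trimesh.Trimesh` objects with coordinates in
millimetres and 0-based face indexing throughout.  STL is the input format
(the scanners of interest export it); because STL stores an unindexed
triangle soup, reading welds coincident vertices so that connectivity
queries (region growing, watertightness) are meaningful.  Signed distance
maps are written as PLY with 8-bit vertex colours — the minimal standard
format that can carry per-vertex colour — plus a plain-text scalar sidecar.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import trimesh
from matplotlib import colormaps

from .errors import MeshFormatError, MeshGeometryError

__all__ = [
    "read_stl",
    "write_stl",
    "write_distance_map",
    "mesh_volume",
    "validate",
    "boundary_edge_count",
    "MeshReport",
    "WELD_TOLERANCE_MM",
]

#: absolute vertex-welding tolerance; scan resolution is 0.3 mm, so this is
#: far below any real feature scale
WELD_TOLERANCE_MM = 1e-9

#: default symmetric colour-scale clamps for distance maps, in mm
DEFAULT_CLAMP_MM = {"skull": 1.0, "mandible": 2.0}

_GREY = np.array([128, 128, 128, 255], dtype=np.uint8)


def weld_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOLERANCE_MM):
    """Merge vertices closer than ``tol`` (absolute, mm) into shared indices.

    Faces degenerated by the merge (repeated vertex index) are dropped.
    """
    decimals = max(0, int(round(-np.log10(tol))))
    key = np.round(vertices, decimals=decimals)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    welded = vertices[np.sort(first)]
    # remap through the sorted-first ordering so original vertex order is kept
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 2] != new_faces[:, 0])
    )
    return welded, new_faces[ok]


def _detect_binary(raw: bytes) -> bool:
    if len(raw) < 84:
        return False
    (n,) = struct.unpack_from("<I", raw, 80)
    return len(raw) == 84 + 50 * n


def read_stl(path) -> trimesh.Trimesh:
    """Read a binary or ASCII STL file into a welded triangle mesh.

    The dialect is auto-detected (binary files are recognised by their exact
    84 + 50·n byte layout, which is unambiguous even when they start with
    the bytes ``solid``).
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) == 0:
        raise MeshFormatError(f"{path}: empty file (0 bytes)")

    if _detect_binary(raw):
        (n,) = struct.unpack_from("<I", raw, 80)
        data = np.frombuffer(raw, dtype=np.uint8, count=50 * n, offset=84)
        facets = data.reshape(-1, 50)
        coords = (
            facets[:, :48]
            .view("<f4")
            .reshape(-1, 12)[:, 3:]  # skip the stored normal
            .astype(np.float64)
            .reshape(-1, 3)
        )
    elif raw.lstrip()[:5].lower() == b"solid":
        coords = _parse_ascii(path, raw)
    else:
        # looked binary but the size did not match the facet count
        if len(raw) >= 84:
            (n,) = struct.unpack_from("<I", raw, 80)
            raise MeshFormatError(
                f"{path}: binary STL truncated — header at byte 80 declares "
                f"{n} facets ({84 + 50 * n} bytes) but the file has {len(raw)} bytes"
            )
        raise MeshFormatError(
            f"{path}: not an STL file — {len(raw)} bytes is shorter than the "
            "84-byte binary header and the content does not start with 'solid'"
        )

    if len(coords) == 0:
        vertices = np.zeros((0, 3))
        faces = np.zeros((0, 3), dtype=np.int64)
    else:
        if not np.isfinite(coords).all():
            raise MeshFormatError(f"{path}: non-finite vertex coordinates")
        vertices, faces = weld_vertices(coords, np.arange(len(coords)).reshape(-1, 3))
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def _parse_ascii(path, raw: bytes) -> np.ndarray:
    coords = []
    for lineno, line in enumerate(raw.decode("ascii", errors="replace").splitlines(), 1):
        tokens = line.split()
        if tokens[:1] == ["vertex"]:
            if len(tokens) != 4:
                raise MeshFormatError(
                    f"{path}: line {lineno}: vertex needs 3 coordinates"
                )
            try:
                coords.append([float(t) for t in tokens[1:]])
            except ValueError:
                raise MeshFormatError(
                    f"{path}: line {lineno}: unparsable vertex coordinate"
                ) from None
    if len(coords) % 3 != 0:
        raise MeshFormatError(
            f"{path}: truncated ASCII STL — {len(coords)} vertex lines is not "
            "a multiple of 3"
        )
    return np.asarray(coords, dtype=np.float64).reshape(-1, 3) if coords else np.zeros((0, 3))


def write_stl(mesh: trimesh.Trimesh, path) -> None:
    """Write a mesh as binary STL (80-byte header, 50 bytes per facet)."""
    path = Path(path)
    try:
        data = trimesh.exchange.stl.export_stl(mesh)
        path.write_bytes(data)
    except OSError as exc:
        raise IOError(f"cannot write STL to {path}: {exc}") from exc


def write_distance_map(
    mesh: trimesh.Trimesh,
    values: np.ndarray,
    clamp: float = 1.0,
    path=None,
    sidecar: bool = True,
) -> None:
    """Write a colour-coded signed distance map as an ASCII PLY file.

    ``values`` holds one signed distance (mm) per vertex; NaN marks vertices
    with no corresponding surface on the other model, which are coloured
    neutral grey.  Finite values are clamped to ``±clamp`` and mapped on a
    diverging blue–white–red scale (negative = other surface inside, white =
    congruent, positive = other surface outside).  A plain-text sidecar
    ``<path>.txt`` stores the raw scalars.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (len(mesh.vertices),):
        raise ValueError(
            f"distance map needs one value per vertex: got {values.shape}, "
            f"mesh has {len(mesh.vertices)} vertices"
        )
    if clamp <= 0:
        raise ValueError("clamp must be positive")
    path = Path(path)

    missing = ~np.isfinite(values)
    unit = np.clip(values / clamp, -1.0, 1.0)
    cmap = colormaps["bwr"]
    rgba = (cmap((np.nan_to_num(unit) + 1.0) / 2.0) * 255).round().astype(np.uint8)
    rgba[missing] = _GREY

    out = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, vertex_colors=rgba, process=False
    )
    data = trimesh.exchange.ply.export_ply(out, encoding="ascii")
    try:
        path.write_bytes(data)
        if sidecar:
            with open(str(path) + ".txt", "w") as fh:
                for v in values:
                    fh.write(f"{v:.6f}\n" if np.isfinite(v) else "nan\n")
    except OSError as exc:
        raise IOError(f"cannot write distance map to {path}: {exc}") from exc


def boundary_edge_count(mesh: trimesh.Trimesh) -> int:
    """Number of edges not shared by exactly two faces."""
    if len(mesh.faces) == 0:
        return 0
    edges = np.sort(mesh.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts != 2).sum())


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume (mm³) of a watertight, consistently wound mesh.

    Computed as the signed-tetrahedron sum (divergence theorem); positive
    for outward winding.
    """
    n_bad = boundary_edge_count(mesh)
    if len(mesh.faces) == 0 or n_bad:
        raise MeshGeometryError(
            f"volume requires a watertight mesh: {n_bad} boundary edges"
        )
    tri = mesh.triangles
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


@dataclass(frozen=True)
class MeshReport:
    """Summary of a mesh's basic geometry and topology."""

    n_vertices: int
    n_faces: int
    watertight: bool
    bbox_min: tuple
    bbox_max: tuple
    mean_edge_length: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def validate(mesh: trimesh.Trimesh) -> MeshReport:
    """Report counts, bounding box, edge length and watertightness.

    Watertight means every edge is shared by exactly two faces (boundary
    edge count zero).  Never raises.
    """
    if len(mesh.vertices) == 0:
        return MeshReport(0, 0, False, (0.0,) * 3, (0.0,) * 3, 0.0)
    if len(mesh.faces) == 0:
        bb = mesh.vertices.min(0), mesh.vertices.max(0)
        return MeshReport(len(mesh.vertices), 0, False, tuple(bb[0]), tuple(bb[1]), 0.0)
    edges = mesh.vertices[np.sort(mesh.edges_unique, axis=1)]
    mean_edge = float(np.linalg.norm(edges[:, 1] - edges[:, 0], axis=1).mean())
    return MeshReport(
        n_vertices=len(mesh.vertices),
        n_faces=len(mesh.faces),
        watertight=boundary_edge_count(mesh) == 0,
        bbox_min=tuple(float(x) for x in mesh.vertices.min(0)),
        bbox_max=tuple(float(x) for x in mesh.vertices.max(0)),
        mean_edge_length=mean_edge,
    )
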