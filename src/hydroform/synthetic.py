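"""Synthetic paired dry/wet specimens with known ground truth.

Real skulls and mandibles from the motivating study are not publicly
deposited, so every pipeline stage is exercised on generated stand-ins that
emulate the study's geometric and statistical structure: a closed
ellipsoidal skull-like shell (~170×140×120 mm) with zygoma-analogue lateral
protrusions and a forehead plateau, and an open C-shaped mandible-like arch
(~110 mm wide) with two tall rami plates.  Hydration is modelled as a
smooth analytic displacement field — a global outward enlargement along the
normals, doubled at the zygoma analogues (skull mode), or an enlargement
plus bilateral ramus expansion plus an arch-opening "flattening" about the
chin (mandible mode) — with scanner-like Gaussian noise along the normals
and an arbitrary rigid misalignment that registration must undo.

Because the pipeline removes any rigid component by best-fit
superimposition, every deformation field is projected orthogonal to the six
linearised rigid-body modes (in the surface-normal metric that
point-to-plane alignment minimises) before being applied.  The ground-truth
expected MAD of a region is then simply the mean |d·n̂| of the projected
field over the region's vertices, well defined independently of the
registration.  Deformations are analytic rather than physical: the goal is
a testbed with closed-form expectations, not anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .errors import HydroformError
from .registration import RigidTransform
from .regions import MANDIBLE_AREAS, SKULL_AREAS, Region, grow_region

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticSpecimen",
    "make_skull_shell",
    "make_mandible_arch",
    "apply_hydration_deformation",
    "add_scan_noise",
    "perturb_rigid",
    "generate_specimen",
    "generate_study",
    "region_triangle_count",
]

# ---------------------------------------------------------------------------
# geometry constants (mm / rad); fixed so that the deformation field is a
# deterministic function of position alone
SKULL_AXES = np.array([85.0, 70.0, 60.0])  # semi-axes: width, depth, height
# anterior is -y, right is +x, up is +z
_ZYG_R = np.array([0.92, -0.36, -0.12])
_ZYG_L = _ZYG_R * np.array([-1.0, 1.0, 1.0])
_FOREHEAD = np.array([0.0, -0.55, 0.84])
_ZYG_SHAPE_SIGMA = 0.28  # rad, geometric bump width
_ZYG_SHAPE_AMP = 0.10  # fractional radial protrusion
_FOREHEAD_FLAT_AMP = 0.03
_FOREHEAD_FLAT_SIGMA = 0.35
_ZYG_EFFECT_SIGMA = 0.35  # rad, width of the doubled hydration effect

_SKULL_SEED_DIRS = {
    "FM": (0.00, -0.55, 0.84),
    "FR": (0.32, -0.50, 0.80),
    "FL": (-0.32, -0.50, 0.80),
    "MR": (0.30, -0.88, -0.34),
    "ML": (-0.30, -0.88, -0.34),
    "ZR": tuple(_ZYG_R),
    "ZL": tuple(_ZYG_L),
    "SM": (0.00, -0.15, -0.99),
    "ACR": (0.28, -0.55, -0.79),
    "ACL": (-0.28, -0.55, -0.79),
}

ARCH_WIDTH_MM = 110.0
_ARCH_PHI_MAX = 1.35  # rad; half-opening of the arch
_TUBE_H = 6.0  # horizontal cross-section semi-axis
_TUBE_V0 = 13.0  # vertical semi-axis along the corpus
_TUBE_V1 = 30.0  # vertical semi-axis at the ramus plates
_RAMUS_RAMP = (0.68, 0.97)  # |phi|/phi_max range over which the ramus rises
_RAMUS_EXPAND_RAMP = (0.52, 0.78)  # weight ramp of the bilateral expansion;
# saturates below the ramus measurement seeds so those patches sit on the
# plateau of the field, where point-to-surface distance equals |d·n̂|


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _smoothstep(x, lo, hi):
    t = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic generator.

    Defaults emulate the study: 0.3 mm fusion resolution, hydration effects
    whose regional medians land near 0.2 mm (skull) / 0.56 mm (mandible),
    scanner noise of ~0.035 mm SD along the normals, and a rigid
    misalignment for registration to undo.  ``flattening`` is the
    dimensionless arch-opening factor of the mandible mode (rotation of the
    arms about the chin hinge, in radians per unit of normalised arch
    coordinate).  ``embedding_extra_mm`` is the additional enlargement of a
    long-embedding wet model over a short one (the ~0.05 mm effect).
    """

    specimen_type: str = "skull"
    target_edge_length: float = 0.3
    enlargement: float = 0.2
    flattening: float = 0.016
    bilateral_expansion: float = 1.0
    noise_sd: float = 0.035
    max_rot_deg: float = 5.0
    max_trans_mm: float = 5.0
    embedding_extra_mm: float = 0.03
    effect_scale_sd: float = 0.35
    shape_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.specimen_type not in ("skull", "mandible"):
            raise ValueError(f"unknown specimen_type {self.specimen_type!r}")
        if self.target_edge_length <= 0:
            raise ValueError("target_edge_length must be positive")
        if self.target_edge_length > 2.0:
            raise HydroformError(
                f"target_edge_length {self.target_edge_length} mm cannot resolve "
                "the arch features (limit 2 mm)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("enlargement", "flattening", "bilateral_expansion"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Exact per-vertex displacement, misalignment and expected MADs."""

    misalignment: RigidTransform
    displacement: np.ndarray  # (n, 3) mm, on the dry base vertices
    normals: np.ndarray  # (n, 3) dry outward vertex normals
    expected_mads: Dict[str, float] = field(default_factory=dict)
    expected_whole_mad: float = float("nan")

    def expected_regional_mad(self, region: Region, mesh: trimesh.Trimesh) -> float:
        """Mean |d·n̂| of the true displacement over the region's vertices."""
        vids = region.vertex_ids(mesh)
        return float(np.abs(np.einsum("ij,ij->i", self.displacement[vids], self.normals[vids])).mean())

    def normal_magnitudes(self) -> np.ndarray:
        return np.abs(np.einsum("ij,ij->i", self.displacement, self.normals))


# ---------------------------------------------------------------------------
# base shapes


def _icosphere_subdivisions(target_edge: float, mean_radius: float) -> int:
    # icosahedron edge on the unit sphere is ~1.0515 and halves per level
    return int(np.clip(round(np.log2(1.0515 * mean_radius / target_edge)), 3, 8))


def make_skull_shell(config: SyntheticConfig):
    """Closed, watertight skull-like shell with zygoma-analogue lateral
    protrusions and a forehead plateau; returns ``(mesh, seeds)`` where
    seeds name surface points for the ten skull measurement areas."""
    axes = SKULL_AXES * _shape_jitter_factors(config)
    mean_r = float(np.prod(axes) ** (1.0 / 3.0))
    sub = _icosphere_subdivisions(config.target_edge_length, mean_r)
    base = trimesh.creation.icosphere(subdivisions=sub)
    u = np.asarray(base.vertices)  # unit directions
    verts = u * axes * (1.0 + _skull_radial_feature(u))[:, None]
    mesh = trimesh.Trimesh(vertices=verts, faces=base.faces.copy(), process=False)

    seeds = {}
    for name, d in _SKULL_SEED_DIRS.items():
        du = _unit(np.asarray(d))
        seeds[name] = du * axes * (1.0 + float(_skull_radial_feature(du[None])[0]))
    return mesh, seeds


def _shape_jitter_factors(config: SyntheticConfig) -> np.ndarray:
    if config.shape_jitter == 0:
        return np.ones(3)
    rng = np.random.default_rng(config.seed)
    return 1.0 + config.shape_jitter * rng.standard_normal(3)


def _skull_radial_feature(u: np.ndarray) -> np.ndarray:
    """Fractional radial offset building the zygoma bumps and the forehead
    plateau on a unit-direction field."""
    ang_r = _angle_to(u, _ZYG_R)
    ang_l = _angle_to(u, _ZYG_L)
    ang_f = _angle_to(u, _FOREHEAD)
    bump = _ZYG_SHAPE_AMP * (
        np.exp(-((ang_r / _ZYG_SHAPE_SIGMA) ** 2))
        + np.exp(-((ang_l / _ZYG_SHAPE_SIGMA) ** 2))
    )
    plateau = _FOREHEAD_FLAT_AMP * np.exp(-((ang_f / _FOREHEAD_FLAT_SIGMA) ** 2))
    return bump - plateau


def _angle_to(u: np.ndarray, d: np.ndarray) -> np.ndarray:
    return np.arccos(np.clip(u @ _unit(d), -1.0, 1.0))


def make_mandible_arch(config: SyntheticConfig, watertight: bool = False):
    """Open C-shaped swept surface with two tall ramus plates.

    The centreline is a horizontal circular arc (chin at the front, −y);
    the elliptical cross-section grows vertically near the two ends to form
    the ramus analogues.  The condylar ends are open unless ``watertight``
    caps them.  Returns ``(mesh, seeds)``; the labelled ramus tip points are
    stored in ``mesh.metadata['ramus_tips']``.
    """
    jitter = _shape_jitter_factors(config)
    width = ARCH_WIDTH_MM * float(jitter[0])
    R = width / 2.0 / np.sin(_ARCH_PHI_MAX)
    a_h = _TUBE_H * float(jitter[1])
    v0, v1 = _TUBE_V0 * float(jitter[2]), _TUBE_V1 * float(jitter[2])

    e = config.target_edge_length
    circumference = 2 * np.pi * np.sqrt((a_h**2 + v0**2) / 2.0)
    path_len = 2 * _ARCH_PHI_MAX * R
    nv = max(12, int(round(circumference / e)))
    nt = max(24, int(round(path_len / e)))

    phi = np.linspace(-_ARCH_PHI_MAX, _ARCH_PHI_MAX, nt)
    theta = np.linspace(0.0, 2 * np.pi, nv, endpoint=False)

    a_v = v0 + (v1 - v0) * _smoothstep(np.abs(phi) / _ARCH_PHI_MAX, *_RAMUS_RAMP)
    cz = a_v - v0  # keeps the lower border level
    cx, cy = R * np.sin(phi), -R * np.cos(phi)
    n_out = np.stack([np.sin(phi), -np.cos(phi)], axis=1)  # horizontal outward

    ct, st = np.cos(theta), np.sin(theta)
    X = cx[:, None] + a_h * ct[None, :] * n_out[:, 0][:, None]
    Y = cy[:, None] + a_h * ct[None, :] * n_out[:, 1][:, None]
    Z = cz[:, None] + a_v[:, None] * st[None, :]
    verts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    faces = []
    for i in range(nt - 1):
        for j in range(nv):
            j2 = (j + 1) % nv
            a = i * nv + j
            b = i * nv + j2
            c = (i + 1) * nv + j
            d = (i + 1) * nv + j2
            faces.append([a, b, d])
            faces.append([a, d, c])
    if watertight:
        # fan caps over the two open ends
        c0 = len(verts)
        c1 = c0 + 1
        centers = np.array(
            [[cx[0], cy[0], cz[0]], [cx[-1], cy[-1], cz[-1]]]
        )
        verts = np.vstack([verts, centers])
        for j in range(nv):
            j2 = (j + 1) % nv
            faces.append([c0, j, j2])
            faces.append([c1, (nt - 1) * nv + j2, (nt - 1) * nv + j])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:  # enforce outward winding
        mesh.invert()

    s = _ARCH_PHI_MAX * np.array([0.45, 0.84])  # body / ramus seed arc positions
    def _pt(p, th):
        av = v0 + (v1 - v0) * _smoothstep(abs(p) / _ARCH_PHI_MAX, *_RAMUS_RAMP)
        n = np.array([np.sin(p), -np.cos(p), 0.0])
        c = np.array([R * np.sin(p), -R * np.cos(p), av - v0])
        return c + a_h * np.cos(th) * n + av * np.sin(th) * np.array([0, 0, 1.0])

    seeds = {
        "BC": _pt(0.0, 0.0),
        "BR": _pt(s[1], 0.15 * np.pi),   # outer ramus plate, mid height
        "BL": _pt(-s[1], 0.15 * np.pi),
        "LC": _pt(0.0, np.pi),
        "LR": _pt(s[0], np.pi),
        "LL": _pt(-s[0], np.pi),
    }
    mesh.metadata["ramus_tips"] = {
        "R": np.array([R * np.sin(_ARCH_PHI_MAX), -R * np.cos(_ARCH_PHI_MAX), cz[-1] + a_v[-1]]),
        "L": np.array([-R * np.sin(_ARCH_PHI_MAX), -R * np.cos(_ARCH_PHI_MAX), cz[0] + a_v[0]]),
    }
    mesh.metadata["arch_width"] = width
    mesh.metadata["arch_R"] = R
    return mesh, seeds


# ---------------------------------------------------------------------------
# deformation


def _project_out_rigid(points, normals, disp):
    """Remove the best-fit rigid component of a displacement field in the
    surface-normal metric (the quantity point-to-plane alignment removes)."""
    c = points.mean(0)
    q = points - c
    modes = np.empty((len(points), 6, 3))
    modes[:, 0] = [1.0, 0.0, 0.0]
    modes[:, 1] = [0.0, 1.0, 0.0]
    modes[:, 2] = [0.0, 0.0, 1.0]
    modes[:, 3] = np.cross(np.broadcast_to([1.0, 0, 0], q.shape), q)
    modes[:, 4] = np.cross(np.broadcast_to([0, 1.0, 0], q.shape), q)
    modes[:, 5] = np.cross(np.broadcast_to([0, 0, 1.0], q.shape), q)
    A = np.einsum("imk,ik->im", modes, normals)
    b = np.einsum("ik,ik->i", disp, normals)
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    return disp - np.einsum("imk,m->ik", modes, beta)


def apply_hydration_deformation(mesh: trimesh.Trimesh, config: SyntheticConfig):
    """Deform a generated dry mesh into its hydrated counterpart.

    Skull mode: outward normal offset by ``enlargement``, doubled (smooth
    blend) on the zygoma analogues.  Mandible mode: outward offset, rami
    displaced laterally by ``bilateral_expansion`` and the arch opened about
    the chin hinge by ``flattening``.  The field is projected orthogonal to
    the rigid-body modes; returns ``(wet_mesh, GroundTruth)``.
    """
    pts = np.asarray(mesh.vertices, dtype=np.float64)
    normals = np.asarray(mesh.vertex_normals, dtype=np.float64)

    if config.specimen_type == "skull":
        u = _unit(pts / SKULL_AXES)
        w = 1.0 + (
            np.exp(-((_angle_to(u, _ZYG_R) / _ZYG_EFFECT_SIGMA) ** 2))
            + np.exp(-((_angle_to(u, _ZYG_L) / _ZYG_EFFECT_SIGMA) ** 2))
        )
        disp = config.enlargement * np.clip(w, 1.0, 2.0)[:, None] * normals
    else:
        R = float(mesh.metadata.get("arch_R", ARCH_WIDTH_MM / 2 / np.sin(_ARCH_PHI_MAX)))
        phi = np.arctan2(pts[:, 0], -pts[:, 1])
        w_r = _smoothstep(np.abs(phi) / _ARCH_PHI_MAX, *_RAMUS_EXPAND_RAMP)
        lateral = np.zeros_like(pts)
        lateral[:, 0] = config.bilateral_expansion * w_r * np.sign(phi)

        chin = np.array([0.0, -R, 0.0])
        rel = pts - chin
        zxr = np.stack([-rel[:, 1], rel[:, 0], np.zeros(len(pts))], axis=1)  # ẑ×(p−chin)
        opening = -config.flattening * (phi / _ARCH_PHI_MAX)[:, None] * zxr

        disp = config.enlargement * normals + lateral + opening

    disp = _project_out_rigid(pts, normals, disp)
    wet = trimesh.Trimesh(vertices=pts + disp, faces=mesh.faces.copy(), process=False)
    gt = GroundTruth(
        misalignment=RigidTransform.identity(),
        displacement=disp,
        normals=normals,
        expected_whole_mad=float(np.abs(np.einsum("ij,ij->i", disp, normals)).mean()),
    )
    return wet, gt


def add_scan_noise(mesh: trimesh.Trimesh, noise_sd: float, seed: int) -> trimesh.Trimesh:
    """Zero-mean Gaussian offsets along the vertex normals (surface-scan
    noise is predominantly radial); reproducible for a fixed seed."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, noise_sd, len(mesh.vertices))
    verts = np.asarray(mesh.vertices) + offsets[:, None] * np.asarray(mesh.vertex_normals)
    return trimesh.Trimesh(vertices=verts, faces=mesh.faces.copy(), process=False)


def perturb_rigid(mesh: trimesh.Trimesh, max_rot_deg: float, max_trans_mm: float, seed: int):
    """Apply a random rigid misalignment (rotation about the centroid, axis
    uniform on the sphere, angle uniform within the bound; translation
    uniform within its bound).  Returns ``(mesh, transform)``."""
    if max_rot_deg < 0 or max_trans_mm < 0:
        raise ValueError("bounds must be nonnegative")
    rng = np.random.default_rng(seed)
    axis = _unit(rng.standard_normal(3))
    angle = np.radians(rng.uniform(0.0, max_rot_deg))
    R = Rotation.from_rotvec(axis * angle).as_matrix()
    direction = _unit(rng.standard_normal(3))
    t_vec = direction * rng.uniform(0.0, max_trans_mm)
    c = np.asarray(mesh.vertices).mean(0)
    transform = RigidTransform(R, c - R @ c + t_vec)
    out = trimesh.Trimesh(
        vertices=transform.apply(mesh.vertices), faces=mesh.faces.copy(), process=False
    )
    return out, transform


# ---------------------------------------------------------------------------
# whole-specimen and whole-study generation

#: patch area equivalent to the protocol's 10,000 triangles at 0.3 mm fusion
#: resolution (10,000 × √3/4 × 0.3² mm²)
PROTOCOL_PATCH_AREA_MM2 = 10_000 * (np.sqrt(3) / 4) * 0.3**2


def region_triangle_count(mesh: trimesh.Trimesh, area_mm2: float = PROTOCOL_PATCH_AREA_MM2) -> int:
    """Triangle count whose patch area on this mesh matches the protocol's
    10,000-triangle area at 0.3 mm resolution."""
    mean_face_area = float(mesh.area) / len(mesh.faces)
    return int(np.clip(round(area_mm2 / mean_face_area), 30, len(mesh.faces) // 4))


@dataclass
class SyntheticSpecimen:
    """One generated specimen: dry model, wet model(s), seeds and truths."""

    specimen_id: str
    specimen_type: str
    dry: trimesh.Trimesh
    wet: Dict[str, trimesh.Trimesh]
    seeds: Dict[str, np.ndarray]
    ground_truth: Dict[str, GroundTruth]  # keyed by comparison name
    regions: Dict[str, Region] = field(default_factory=dict)  # on the clean base
    effect_scale: float = 1.0


def generate_specimen(
    config: SyntheticConfig,
    specimen_id: str = "S00",
    conditions=("wet",),
    n_region_triangles: Optional[int] = None,
) -> SyntheticSpecimen:
    """Generate one dry/wet specimen pair (or triplet with two embedding
    conditions) with full ground truth.

    Per-specimen biological variability enters as a log-normal scale factor
    on the deformation magnitudes (``effect_scale_sd``) and a small Gaussian
    jitter of the base shape (``shape_jitter``); conditions named ``wet15``
    get ``embedding_extra_mm`` of extra enlargement over ``wet5``/``wet``.
    All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    effect_scale = float(np.exp(config.effect_scale_sd * rng.standard_normal()))

    if config.specimen_type == "skull":
        base, seeds = make_skull_shell(config)
    else:
        base, seeds = make_mandible_arch(config)

    base_normals = np.asarray(base.vertex_normals, dtype=np.float64)

    fields: Dict[str, np.ndarray] = {}
    wets: Dict[str, trimesh.Trimesh] = {}
    truths: Dict[str, GroundTruth] = {}
    for k, cond in enumerate(conditions):
        extra = config.embedding_extra_mm if cond == "wet15" else 0.0
        cfg = replace(
            config,
            enlargement=(config.enlargement + extra) * effect_scale,
            bilateral_expansion=config.bilateral_expansion * effect_scale,
            flattening=config.flattening * effect_scale,
        )
        wet_clean, gt = apply_hydration_deformation(base, cfg)
        fields[cond] = gt.displacement
        noisy = add_scan_noise(wet_clean, config.noise_sd, seed=int(rng.integers(2**31)))
        moved, misalignment = perturb_rigid(
            noisy, config.max_rot_deg, config.max_trans_mm, seed=int(rng.integers(2**31))
        )
        gt.misalignment = misalignment
        wets[cond] = moved
        truths[f"dry-vs-{cond}"] = gt

    if "wet5" in fields and "wet15" in fields:
        dd = fields["wet15"] - fields["wet5"]
        truths["wet5-vs-wet15"] = GroundTruth(
            misalignment=RigidTransform.identity(),
            displacement=dd,
            normals=base_normals,
            expected_whole_mad=float(np.abs(np.einsum("ij,ij->i", dd, base_normals)).mean()),
        )

    dry = add_scan_noise(base, config.noise_sd, seed=int(rng.integers(2**31)))

    # expected regional MADs on the clean base geometry
    n_tri = n_region_triangles or region_triangle_count(base)
    names = SKULL_AREAS if config.specimen_type == "skull" else MANDIBLE_AREAS
    regions = {}
    for name in names:
        region = grow_region(base, seeds[name], n_tri, name=name)
        regions[name] = region
        for gt in truths.values():
            gt.expected_mads[name] = gt.expected_regional_mad(region, base)

    return SyntheticSpecimen(
        specimen_id=specimen_id,
        specimen_type=config.specimen_type,
        dry=dry,
        wet=wets,
        seeds={k: np.asarray(v) for k, v in seeds.items()},
        ground_truth=truths,
        regions=regions,
        effect_scale=effect_scale,
    )


def generate_study(
    config: SyntheticConfig,
    n_specimens: int,
    conditions=("wet",),
    n_region_triangles: Optional[int] = None,
):
    """Generate a list of specimens with independent shapes and effect
    scales, seeded reproducibly from ``config.seed``."""
    if n_specimens < 1:
        raise ValueError("need at least one specimen")
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(n_specimens):
        cfg = replace(config, seed=int(rng.integers(2**31)))
        out.append(
            generate_specimen(
                cfg,
                specimen_id=f"{config.specimen_type[0].upper()}{i:02d}",
                conditions=conditions,
                n_region_triangles=n_region_triangles,
            )
        )
    return out
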