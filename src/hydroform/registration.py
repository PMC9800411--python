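"""Rigid superimposition of paired surface models.

The pair convention follows the study design: the dry specimen is the fixed
*reference* (target) model and the hydrated specimen is the moving *test*
(source) model that is approximated to it.  Alignment is a closed-form
landmark fit (optional rough initialisation) followed by iterative closest
point with exact closest-point-on-surface correspondences.  The default ICP
settings are 100% estimated overlap, 100% point sampling, point-to-plane
matching and 50 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .errors import DegenerateConfigurationError, MeshGeometryError
from .proximity import ClosestPointQuery

__all__ = [
    "RigidTransform",
    "ICPConfig",
    "RegistrationResult",
    "landmark_align",
    "icp_register",
    "apply_transform",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation then translation), in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other, i.e. the transform applying ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))

    def to_dict(self) -> dict:
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],
            "translation": [float(x) for x in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]).reshape(3, 3), np.asarray(d["translation"]))


@dataclass(frozen=True)
class ICPConfig:
    """ICP settings; the defaults are the study's superimposition settings."""

    estimated_overlap: float = 1.0
    sampling: float = 1.0
    metric: str = "point-to-plane"
    max_iterations: int = 50
    convergence_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.estimated_overlap <= 1.0:
            raise ValueError("estimated_overlap must be in (0, 1]")
        if not 0.0 < self.sampling <= 1.0:
            raise ValueError("sampling must be in (0, 1]")
        if self.metric not in ("point-to-plane", "point-to-point"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "estimated_overlap": self.estimated_overlap,
            "sampling": self.sampling,
            "metric": self.metric,
            "max_iterations": self.max_iterations,
            "convergence_tol": self.convergence_tol,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ICPConfig":
        return cls(**d)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_history: list = field(default_factory=list)
    n_correspondences: int = 0
    converged: bool = False

    @property
    def rms_residual(self) -> float:
        return self.rms_history[-1] if self.rms_history else float("nan")

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "rms_history": [float(r) for r in self.rms_history],
            "n_correspondences": int(self.n_correspondences),
            "converged": bool(self.converged),
        }


def landmark_align(
    source_points: np.ndarray,
    target_points: np.ndarray,
    allow_scaling: bool = False,
):
    """Closed-form least-squares rigid fit of homologous landmark pairs.

    Minimises Σ‖R·s_i + t − t_i‖² via SVD of the cross-covariance matrix
    (reflections excluded).  With ``allow_scaling`` a uniform scale is also
    estimated and returned as ``(transform, scale)``.
    """
    s = np.asarray(source_points, dtype=np.float64)
    t = np.asarray(target_points, dtype=np.float64)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("landmark sets must be matching (n, 3) arrays")
    if len(s) < 3:
        raise DegenerateConfigurationError(
            f"landmark alignment needs >= 3 point pairs, got {len(s)}"
        )
    cs, ct = s.mean(0), t.mean(0)
    s0, t0 = s - cs, t - ct
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("landmarks are collinear")

    H = s0.T @ t0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scaling:
        scale = float(np.trace(D @ np.diag(S)) / (s0**2).sum())
        return RigidTransform(R, ct - scale * R @ cs), scale
    return RigidTransform(R, ct - R @ cs)


def apply_transform(mesh: trimesh.Trimesh, t: RigidTransform) -> trimesh.Trimesh:
    """Return a copy of the mesh with vertices rigidly transformed;
    connectivity unchanged, normals re-derived lazily."""
    return trimesh.Trimesh(vertices=t.apply(mesh.vertices), faces=mesh.faces.copy(), process=False)


def _solve_point_to_plane(p, q, n) -> RigidTransform:
    # linearised residual ((p + ω×p + t) − q)·n; 6×6 normal equations
    A = np.hstack([np.cross(p, n), n])
    b = np.einsum("ij,ij->i", q - p, n)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    R = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform(R, x[3:])


def _solve_point_to_point(p, q) -> RigidTransform:
    cp, cq = p.mean(0), q.mean(0)
    H = (p - cp).T @ (q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cq - R @ cp)


def icp_register(
    source: trimesh.Trimesh,
    target: trimesh.Trimesh,
    config: Optional[ICPConfig] = None,
    init: Optional[RigidTransform] = None,
    source_region=None,
    target_region=None,
    target_query: Optional[ClosestPointQuery] = None,
) -> RegistrationResult:
    """Iterative closest point registration of ``source`` onto ``target``.

    Each iteration (a) takes the sampled source vertices, (b) finds their
    exact closest points on the target surface, (c) retains the best
    ``estimated_overlap`` fraction of correspondences by distance (all of
    them at the default 1.0), (d) solves for the rigid increment under the
    configured metric, and (e) stops at ``max_iterations`` or when the rms
    improves by less than ``convergence_tol``.  Running out of iterations is
    not an error (``converged=False``) — the study protocol runs a fixed 50.

    ``source_region``/``target_region`` optionally restrict the
    superimposition to a reference area: sampling is limited to source
    vertices inside ``source_region``, and correspondences are sought only
    on the ``target_region`` sub-surface.  ``target_query`` lets callers
    reuse a prebuilt :class:`ClosestPointQuery` for the same target.
    """
    if len(source.vertices) == 0 or len(source.faces) == 0:
        raise MeshGeometryError("source mesh is empty")
    if len(target.vertices) == 0 or len(target.faces) == 0:
        raise MeshGeometryError("target mesh is empty")
    config = config or ICPConfig()
    T = init or RigidTransform.identity()

    pts = np.asarray(source.vertices, dtype=np.float64)
    if source_region is not None:
        vids = np.unique(np.asarray(source.faces)[np.asarray(source_region.face_ids)])
        pts = pts[vids]
    if config.sampling < 1.0:
        rng = np.random.default_rng(config.seed)
        k = max(3, int(round(config.sampling * len(pts))))
        pts = pts[np.sort(rng.choice(len(pts), size=k, replace=False))]

    if target_query is None:
        face_ids = None if target_region is None else target_region.face_ids
        target_query = ClosestPointQuery(target, face_ids=face_ids)

    history: list[float] = []
    converged = False
    n_corr = len(pts)
    for _ in range(config.max_iterations):
        p = T.apply(pts)
        cp, d, tid, bary = target_query.query(p)

        if config.estimated_overlap < 1.0:
            k = max(3, int(np.ceil(config.estimated_overlap * len(d))))
            keep = np.argsort(d, kind="stable")[:k]
        else:
            keep = slice(None)
        dk = d[keep]
        n_corr = len(dk)
        rms = float(np.sqrt(np.mean(dk**2)))
        history.append(rms)
        if len(history) >= 2 and history[-2] - rms < config.convergence_tol:
            converged = True
            break

        if config.metric == "point-to-plane":
            normals = target_query.interpolated_normals(tid, bary)
            inc = _solve_point_to_plane(p[keep], cp[keep], normals[keep])
        else:
            inc = _solve_point_to_point(p[keep], cp[keep])
        T = inc.compose(T)

    return RegistrationResult(
        transform=T,
        rms_history=history,
        n_correspondences=n_corr,
        converged=converged,
    )
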