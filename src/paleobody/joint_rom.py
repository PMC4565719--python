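"""Osteological joint mobility by collision sweeps.

The mobile bone (humerus/femur) rotates about an anatomical joint coordinate
system (ACS) placed at its approximated centre of rotation — the centre of a
sphere least-squares fitted into the proximal joint surface — until its mesh
collides with the fixed girdle element. Six directions are swept
independently about single ACS axes:

* x (long axis, pointing lateral in the reference pose): long-axis rotation,
  counter-clockwise (+x, right-hand rule) and clockwise (-x); the cw/ccw
  labels follow a right-lateral view of a right limb with the animal's head
  to the right.
* y (up): positive rotation swings the limb tip caudally = retraction,
  negative = protraction.
* z (cranial): positive rotation swings the tip dorsally = abduction,
  negative = adduction.

All angles are relative to a non-physiological sprawling reference pose
(stylopodium perpendicular to the sagittal plane, epicondylar axis
horizontal). An assumed joint space (cartilage proxy) is imposed by
translating the bone outward along the socket-centre -> head-centre line,
carrying the rotation centre with it; mobility is tabulated over a list of
joint-space offsets (0–2.5 mm in 0.5 mm steps by default). Sweeps are
purely deterministic; the reported limit is the last collision-free pose,
conservative by at most one increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial.transform import Rotation

from .mesh_core import (
    CONTACT_TOL,
    DegenerateGeometryError,
    _segments_pierce_triangles,
    fit_sphere,
    open_edge_count,
    winding_number,
)

__all__ = [
    "JointACS",
    "SweepConfig",
    "SweepOutcome",
    "ROMResult",
    "DIRECTIONS",
    "MM_PER_CM",
    "build_acs",
    "apply_joint_space",
    "sweep_to_collision",
    "rom_table",
]

MM_PER_CM = 10.0

#: direction name -> (ACS axis, rotation sign); see module docstring.
DIRECTIONS = {
    "adduction": ("z", -1),
    "abduction": ("z", +1),
    "protraction": ("y", -1),
    "retraction": ("y", +1),
    "lar_cw": ("x", -1),
    "lar_ccw": ("x", +1),
}


@dataclass(frozen=True)
class JointACS:
    """Right-handed orthonormal anatomical coordinate system at a joint centre."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        m = np.column_stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-8):
            raise DegenerateGeometryError("ACS axes must be orthonormal")
        if np.linalg.det(m) < 0:
            raise DegenerateGeometryError("ACS must be right-handed")

    def axis(self, name: str) -> np.ndarray:
        return {"x": self.x_axis, "y": self.y_axis, "z": self.z_axis}[name]

    def translated(self, offset) -> "JointACS":
        return JointACS(self.origin + np.asarray(offset, dtype=float),
                        self.x_axis, self.y_axis, self.z_axis)


@dataclass(frozen=True)
class SweepConfig:
    """Angular increment, per-axis sweep caps (degrees) and joint spaces (mm)."""

    increment_deg: float = 0.1
    limit_deg: float = 180.0
    lar_limit_deg: float = 360.0
    joint_spaces_mm: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)

    def __post_init__(self):
        if not self.increment_deg > 0:
            raise ValueError("angular increment must be positive")
        if any(s < 0 for s in self.joint_spaces_mm):
            raise ValueError("joint spaces must be non-negative")
        object.__setattr__(self, "joint_spaces_mm", tuple(self.joint_spaces_mm))

    def limit_for(self, axis: str) -> float:
        return self.lar_limit_deg if axis == "x" else self.limit_deg


@dataclass(frozen=True)
class SweepOutcome:
    """Result of one single-axis sweep."""

    angle_deg: float
    collided_at_reference: bool = False
    limit_reached: bool = False


@dataclass
class ROMResult:
    """Maximal rotations (degrees) per direction, tabulated over joint spaces."""

    table: pd.DataFrame
    config: SweepConfig
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)

    def is_monotone(self) -> bool:
        """True iff every direction is non-decreasing in joint space."""
        cols = [c for c in DIRECTIONS if c in self.table.columns]
        diffs = self.table.sort_values("joint_space_mm")[cols].diff().iloc[1:]
        return bool((diffs >= -1e-12).all().all())


# ---------------------------------------------------------------------------
# ACS construction
# ---------------------------------------------------------------------------


def build_acs(
    mobile_surface_points,
    girdle_surface_points=None,
    long_axis=(1, 0, 0),
    up=(0, 1, 0),
    cranial=(0, 0, 1),
) -> JointACS:
    """Fit the joint centre and erect the anatomical coordinate system.

    The origin is the centre of a least-squares sphere through the selected
    proximal joint-surface vertices of the mobile bone. The axes are built by
    Gram–Schmidt with the long-axis hint taken exactly as x, the up hint
    projected to y, and z = x cross y (flipping y if needed so z points to
    the cranial hint's side). ``girdle_surface_points``, when given, are
    included in the fit's sanity radius but do not move the origin (the
    centre of rotation belongs to the mobile bone's head).
    """
    sphere = fit_sphere(mobile_surface_points)
    x = np.asarray(long_axis, dtype=float)
    norm = np.linalg.norm(x)
    if norm < 1e-12:
        raise DegenerateGeometryError("long-axis hint is degenerate")
    x = x / norm
    y = np.asarray(up, dtype=float)
    y = y - (y @ x) * x
    norm = np.linalg.norm(y)
    if norm < 1e-12:
        raise DegenerateGeometryError("up hint is parallel to the long axis")
    y = y / norm
    z = np.cross(x, y)
    if np.asarray(cranial, dtype=float) @ z < 0:
        y, z = -y, -z
    return JointACS(origin=sphere.center, x_axis=x, y_axis=y, z_axis=z)


# ---------------------------------------------------------------------------
# joint space
# ---------------------------------------------------------------------------


def apply_joint_space(
    bone: trimesh.Trimesh, acs: JointACS, socket_center, s_mm: float
) -> tuple[trimesh.Trimesh, JointACS]:
    """Translate the bone out of the socket by ``s_mm`` millimetres.

    The offset direction runs from ``socket_center`` (a point of the socket,
    e.g. its deepest point) through the fitted head centre; the ACS origin
    (rotation centre) is carried along with the bone.
    """
    if s_mm < 0:
        raise ValueError("joint space must be non-negative")
    direction = acs.origin - np.asarray(socket_center, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            "socket centre coincides with the head centre; offset direction undefined"
        )
    offset = direction / norm * (s_mm / MM_PER_CM)
    moved = trimesh.Trimesh(vertices=bone.vertices + offset, faces=bone.faces, process=False)
    return moved, acs.translated(offset)


# ---------------------------------------------------------------------------
# collision oracle (precomputed girdle, bone re-posed per sweep step)
# ---------------------------------------------------------------------------


def _rho_min_segments(w0, d):
    """Min norm of the affine map w0 + t*d over t in [0,1]; rows vectorised."""
    dd = np.einsum("ij,ij->i", d, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(dd > 1e-30, -np.einsum("ij,ij->i", w0, d) / dd, 0.0)
    t = np.clip(t, 0.0, 1.0)
    return np.linalg.norm(w0 + t[:, None] * d, axis=1)


def _cyl_intervals_segments(center, u, segs):
    """Per-segment [h, rho] intervals in cylindrical coordinates about the axis."""
    rel = segs - center
    h = np.einsum("ijk,k->ij", rel, u)
    perp = rel - h[..., None] * u
    rho_max = np.linalg.norm(perp, axis=2).max(axis=1)
    rho_min = _rho_min_segments(perp[:, 0], perp[:, 1] - perp[:, 0])
    return h.min(axis=1), h.max(axis=1), rho_min, rho_max


def _cyl_intervals_triangles(center, u, tris):
    rel = tris - center
    h = np.einsum("ijk,k->ij", rel, u)
    perp = rel - h[..., None] * u
    rho_max = np.linalg.norm(perp, axis=2).max(axis=1)
    # min over the 3 edges, then 0 where the axis line pierces the triangle
    rho_min = np.minimum.reduce(
        [
            _rho_min_segments(perp[:, i], perp[:, (i + 1) % 3] - perp[:, i])
            for i in range(3)
        ]
    )
    e1 = rel[:, 1] - rel[:, 0]
    e2 = rel[:, 2] - rel[:, 0]
    hvec = np.cross(np.broadcast_to(u, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, hvec)
    ok = np.abs(det) > 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(ok, 1.0 / det, 0.0)
    s = -rel[:, 0]
    a = np.einsum("ij,ij->i", s, hvec) * inv
    q = np.cross(s, e1)
    b = np.einsum("j,ij->i", u, q) * inv
    pierced = ok & (a >= 0) & (b >= 0) & (a + b <= 1)
    rho_min = np.where(pierced, 0.0, rho_min)
    return h.min(axis=1), h.max(axis=1), rho_min, rho_max


def _cyl_overlap_pairs(int_a, int_b, pad):
    h_lo_a, h_hi_a, r_lo_a, r_hi_a = int_a
    h_lo_b, h_hi_b, r_lo_b, r_hi_b = int_b
    overlap = (
        (h_lo_a[:, None] <= h_hi_b[None, :] + pad)
        & (h_lo_b[None, :] <= h_hi_a[:, None] + pad)
        & (r_lo_a[:, None] <= r_hi_b[None, :] + pad)
        & (r_lo_b[None, :] <= r_hi_a[:, None] + pad)
    )
    return np.nonzero(overlap)


class _CollisionOracle:
    """Bone-vs-girdle contact test for sweeps about a fixed rotation axis.

    Rotation about the axis preserves every point's cylindrical coordinates
    (height along the axis, radius from it), so feature pairs whose (h, rho)
    intervals are disjoint can never touch in any pose of the sweep. Those
    feasible pairs are computed once; each pose then only runs an AABB filter
    plus Möller–Trumbore piercing on them.
    """

    def __init__(self, girdle: trimesh.Trimesh, bone: trimesh.Trimesh, center, axis):
        center = np.asarray(center, dtype=float)
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        self.g_tri = girdle.triangles
        self.g_edges = girdle.vertices[girdle.edges_unique]
        self.g_tri_lo = self.g_tri.min(axis=1)
        self.g_tri_hi = self.g_tri.max(axis=1)
        self.g_edge_lo = self.g_edges.min(axis=1)
        self.g_edge_hi = self.g_edges.max(axis=1)
        self.g_bounds = (girdle.bounds[0].copy(), girdle.bounds[1].copy())
        self.g_closed = open_edge_count(girdle) == 0
        self.girdle = girdle
        self.bone_faces = bone.faces
        self.bone_edge_idx = bone.edges_unique

        pad = 1e-6
        b_edges = bone.vertices[self.bone_edge_idx]
        b_tris = bone.vertices[self.bone_faces]
        be_int = _cyl_intervals_segments(center, axis, b_edges)
        bt_int = _cyl_intervals_triangles(center, axis, b_tris)
        gt_int = _cyl_intervals_triangles(center, axis, self.g_tri)
        ge_int = _cyl_intervals_segments(center, axis, self.g_edges)
        self.pairs_be_gt = _cyl_overlap_pairs(be_int, gt_int, pad)
        self.pairs_ge_bt = _cyl_overlap_pairs(ge_int, bt_int, pad)
        # pair-gathered girdle-side arrays, contiguous for the per-pose loop
        ii, jj = self.pairs_be_gt
        self._be_idx = self.bone_edge_idx[ii]
        self._gt_tri = np.ascontiguousarray(self.g_tri[jj])
        self._gt_lo = np.ascontiguousarray(self.g_tri_lo[jj])
        self._gt_hi = np.ascontiguousarray(self.g_tri_hi[jj])
        ii, jj = self.pairs_ge_bt
        self._bt_idx = self.bone_faces[jj]
        self._ge_seg = np.ascontiguousarray(self.g_edges[ii])
        self._ge_lo = np.ascontiguousarray(self.g_edge_lo[ii])
        self._ge_hi = np.ascontiguousarray(self.g_edge_hi[ii])

    def collides(self, bone_vertices: np.ndarray) -> bool:
        lo = bone_vertices.min(axis=0)
        hi = bone_vertices.max(axis=0)
        if np.any(lo > self.g_bounds[1] + CONTACT_TOL) or np.any(
            self.g_bounds[0] > hi + CONTACT_TOL
        ):
            return False
        # bone edges piercing girdle faces (cylindrically feasible pairs only)
        if len(self._be_idx):
            e = bone_vertices[self._be_idx]
            lo_e = e.min(axis=1)
            hi_e = e.max(axis=1)
            near = np.all(
                (lo_e <= self._gt_hi + CONTACT_TOL) & (self._gt_lo <= hi_e + CONTACT_TOL),
                axis=1,
            )
            if near.any():
                en = e[near]
                tn = self._gt_tri[near]
                if _segments_pierce_triangles(
                    en[:, 0], en[:, 1], tn[:, 0], tn[:, 1], tn[:, 2]
                ).any():
                    return True
        # girdle edges piercing bone faces
        if len(self._bt_idx):
            t = bone_vertices[self._bt_idx]
            lo_t = t.min(axis=1)
            hi_t = t.max(axis=1)
            near = np.all(
                (self._ge_lo <= hi_t + CONTACT_TOL) & (lo_t <= self._ge_hi + CONTACT_TOL),
                axis=1,
            )
            if near.any():
                tn = t[near]
                sn = self._ge_seg[near]
                if _segments_pierce_triangles(
                    sn[:, 0], sn[:, 1], tn[:, 0], tn[:, 1], tn[:, 2]
                ).any():
                    return True
        # containment (bone swallowed by a closed girdle) counts as collision
        if self.g_closed and winding_number(self.girdle, bone_vertices[:1])[0] > 0.25:
            return True
        return False


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def sweep_to_collision(
    girdle: trimesh.Trimesh,
    bone: trimesh.Trimesh,
    acs: JointACS,
    axis: str,
    direction: int,
    cfg: SweepConfig | None = None,
) -> SweepOutcome:
    """Largest collision-free rotation about one ACS axis, in degrees.

    The bone is rotated from the reference pose in multiples of the
    configured increment about ``direction * acs.axis(axis)`` through the
    ACS origin; the reported angle is the largest multiple such that no
    visited pose up to and including it collides (capped at the axis' sweep
    limit). A collision already at the reference pose returns 0 with
    ``collided_at_reference`` set.
    """
    if axis not in ("x", "y", "z"):
        raise ValueError(f"axis must be x, y or z, got {axis!r}")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    cfg = cfg or SweepConfig()
    if girdle is None or len(girdle.faces) == 0:
        return SweepOutcome(angle_deg=cfg.limit_for(axis), limit_reached=True)

    oracle = _CollisionOracle(girdle, bone, acs.origin, acs.axis(axis))
    base = bone.vertices - acs.origin
    if oracle.collides(bone.vertices):
        return SweepOutcome(angle_deg=0.0, collided_at_reference=True)

    rotvec = direction * acs.axis(axis)
    limit = cfg.limit_for(axis)
    n_steps = int(np.floor(limit / cfg.increment_deg + 1e-9))
    step_rot = Rotation.from_rotvec(rotvec * np.deg2rad(cfg.increment_deg))
    rot = Rotation.identity()
    for step in range(1, n_steps + 1):
        rot = step_rot * rot
        posed = base @ rot.as_matrix().T + acs.origin
        if oracle.collides(posed):
            return SweepOutcome(angle_deg=(step - 1) * cfg.increment_deg)
    return SweepOutcome(angle_deg=n_steps * cfg.increment_deg, limit_reached=True)


def rom_table(
    girdle: trimesh.Trimesh,
    bone: trimesh.Trimesh,
    acs: JointACS,
    socket_center,
    cfg: SweepConfig | None = None,
) -> ROMResult:
    """Sweep all six directions at every configured joint space.

    Each row starts from the reference pose translated outward by that
    joint space; the six sweeps are independent single-axis rotations.
    """
    cfg = cfg or SweepConfig()
    rows = []
    flag_rows = []
    for s in cfg.joint_spaces_mm:
        placed, acs_s = apply_joint_space(bone, acs, socket_center, s)
        row = {"joint_space_mm": s}
        flags = {"joint_space_mm": s}
        for name, (axis, sign) in DIRECTIONS.items():
            outcome = sweep_to_collision(girdle, placed, acs_s, axis, sign, cfg)
            row[name] = outcome.angle_deg
            flags[name + "_ref_collision"] = outcome.collided_at_reference
            flags[name + "_limit_reached"] = outcome.limit_reached
        rows.append(row)
        flag_rows.append(flags)
    return ROMResult(table=pd.DataFrame(rows), config=cfg, flags=pd.DataFrame(flag_rows))
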