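"""Retrodeformation of plastically distorted meshes.

Burial under kilometres of overburden compacts fossil-bearing strata and
shears whatever lies in them; assuming the deformation was homogeneous over
the stratum, it is a single affine map and can be undone exactly by two
rules operating on anatomical evidence:

* **rule 1** — anatomical axes that must have been mutually perpendicular
  (rostro-caudal, latero-lateral, dorso-ventral) are restored to a
  perpendicular target triad, which fixes shear and recovers bilateral
  symmetry;
* **rule 2** — a cross-section known to have been circular (e.g. a vertebral
  centrum) is decompressed along the dorso-ventral axis until it is round
  again, which fixes the uniaxial compaction factor.

A reciprocal cross-check applies the recovered stretch factor to an
independently preserved reference element (compacted along a different
anatomical axis) and compares dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from trimesh.intersections import mesh_plane

from .mesh_core import AffineTransform, DegenerateGeometryError, apply_transform

__all__ = [
    "AxisTriad",
    "SectionRoundness",
    "CrossCheckReport",
    "restore_orthogonality",
    "measure_roundness",
    "decompress_round",
    "cross_check_reciprocal",
    "uniaxial_stretch",
]


@dataclass(frozen=True)
class AxisTriad:
    """Anatomical axis triad: origin plus rostro-caudal / latero-lateral /
    dorso-ventral direction vectors (not necessarily orthogonal when fitted
    to a distorted specimen)."""

    origin: np.ndarray
    e_rc: np.ndarray
    e_ll: np.ndarray
    e_dv: np.ndarray

    def __post_init__(self):
        for name in ("origin", "e_rc", "e_ll", "e_dv"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise DegenerateGeometryError("axis triad vectors are linearly dependent")

    @property
    def matrix(self) -> np.ndarray:
        """Columns are the three axis vectors."""
        return np.column_stack([self.e_rc, self.e_ll, self.e_dv])

    def is_orthonormal(self, tol: float = 1e-9) -> bool:
        m = self.matrix
        return bool(np.allclose(m.T @ m, np.eye(3), atol=tol))

    @classmethod
    def orthonormal(cls, origin=(0, 0, 0), e_rc=(1, 0, 0), e_ll=(0, 1, 0), e_dv=(0, 0, 1)):
        return cls(origin, e_rc, e_ll, e_dv)


@dataclass(frozen=True)
class SectionRoundness:
    """A planar cross-section's lateral and dorso-ventral diameters (cm).

    ``ratio`` = dorso-ventral / lateral; 1 for a circle, < 1 for a
    dorso-ventrally flattened section.
    """

    plane_origin: np.ndarray
    plane_normal: np.ndarray
    lateral_diameter: float
    dorsoventral_diameter: float

    def __post_init__(self):
        object.__setattr__(self, "plane_origin", np.asarray(self.plane_origin, dtype=float))
        n = np.asarray(self.plane_normal, dtype=float)
        object.__setattr__(self, "plane_normal", n / np.linalg.norm(n))
        if not (self.lateral_diameter > 0 and self.dorsoventral_diameter > 0):
            raise DegenerateGeometryError("section diameters must be positive")

    @property
    def ratio(self) -> float:
        return self.dorsoventral_diameter / self.lateral_diameter


@dataclass(frozen=True)
class CrossCheckReport:
    """Per-axis extents of the reciprocally stretched reference vs expected."""

    measured: np.ndarray
    expected: np.ndarray
    relative_error: np.ndarray
    tolerance: float
    passed: bool


# ---------------------------------------------------------------------------
# rule 1: restore perpendicular anatomical axes
# ---------------------------------------------------------------------------


def restore_orthogonality(
    mesh: trimesh.Trimesh, distorted: AxisTriad, target: AxisTriad
) -> tuple[trimesh.Trimesh, AffineTransform]:
    """Undo shear by mapping the distorted axis triad onto a perpendicular one.

    Returns the corrected mesh and the unique affine map sending each
    distorted triad vector onto the corresponding target vector (and the
    distorted origin onto the target origin). If the specimen was deformed
    by an affine map D, fitting the triad as D applied to the true axes
    makes the returned transform exactly D^-1.
    """
    if not target.is_orthonormal():
        raise DegenerateGeometryError("target triad must be orthonormal")
    linear = target.matrix @ np.linalg.inv(distorted.matrix)
    translation = target.origin - linear @ distorted.origin
    t = AffineTransform(linear, translation)
    return apply_transform(mesh, t), t


# ---------------------------------------------------------------------------
# rule 2: decompress until a reference section is round
# ---------------------------------------------------------------------------


def measure_roundness(
    mesh: trimesh.Trimesh,
    plane_origin,
    plane_normal,
    lateral_dir,
) -> SectionRoundness:
    """Section the mesh with a plane and measure its two in-plane diameters.

    Diameters are extents of the section polyline along ``lateral_dir`` and
    the in-plane perpendicular (the dorso-ventral direction); the extent
    measure is deterministic and needs no ellipse fit.
    """
    plane_origin = np.asarray(plane_origin, dtype=float)
    normal = np.asarray(plane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    lateral = np.asarray(lateral_dir, dtype=float)
    lateral = lateral - (lateral @ normal) * normal
    norm = np.linalg.norm(lateral)
    if norm < 1e-12:
        raise DegenerateGeometryError("lateral direction is parallel to the plane normal")
    lateral /= norm
    dorsoventral = np.cross(normal, lateral)

    segments = mesh_plane(mesh, plane_normal=normal, plane_origin=plane_origin)
    if len(segments) == 0:
        raise ValueError("section plane does not intersect the mesh")
    points = segments.reshape(-1, 3) - plane_origin
    lat = points @ lateral
    dv = points @ dorsoventral
    return SectionRoundness(
        plane_origin=plane_origin,
        plane_normal=normal,
        lateral_diameter=float(lat.max() - lat.min()),
        dorsoventral_diameter=float(dv.max() - dv.min()),
    )


def uniaxial_stretch(direction, scale: float, fixed_point=(0.0, 0.0, 0.0)) -> AffineTransform:
    """Affine stretch by ``scale`` along ``direction`` keeping ``fixed_point``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if not scale > 0:
        raise DegenerateGeometryError("stretch scale must be positive")
    linear = np.eye(3) + (scale - 1.0) * np.outer(d, d)
    fixed = np.asarray(fixed_point, dtype=float)
    return AffineTransform(linear, fixed - linear @ fixed)


def decompress_round(
    mesh: trimesh.Trimesh, section: SectionRoundness, dv_dir
) -> tuple[trimesh.Trimesh, AffineTransform, float]:
    """Stretch dorso-ventrally until the reference section is round.

    The stretch factor is forced by the section itself: scale = lateral
    diameter / dorso-ventral diameter. Extents perpendicular to ``dv_dir``
    are preserved exactly. Returns (corrected mesh, transform, scale).
    """
    scale = section.lateral_diameter / section.dorsoventral_diameter
    t = uniaxial_stretch(dv_dir, scale, fixed_point=section.plane_origin)
    return apply_transform(mesh, t), t, float(scale)


# ---------------------------------------------------------------------------
# reciprocal cross-check
# ---------------------------------------------------------------------------


def _extents(mesh: trimesh.Trimesh, frame: np.ndarray) -> np.ndarray:
    proj = mesh.vertices @ frame
    return proj.max(axis=0) - proj.min(axis=0)


def cross_check_reciprocal(
    reference_mesh: trimesh.Trimesh,
    axis,
    scale: float,
    expected_extents,
    frame=None,
    tolerance: float = 0.05,
) -> CrossCheckReport:
    """Apply the rule-2 stretch factor to a reference element and compare sizes.

    The reference (preserved compacted along a *different* anatomical axis,
    here ``axis``) is stretched by the same ``scale``; its extents along the
    ``frame`` directions (columns; default the global axes) are compared to
    ``expected_extents`` at a relative ``tolerance``.
    """
    if not scale > 0:
        raise DegenerateGeometryError("cross-check scale must be positive")
    frame = np.eye(3) if frame is None else np.asarray(frame, dtype=float).reshape(3, 3)
    expected = np.asarray(expected_extents, dtype=float).reshape(3)
    stretched = apply_transform(reference_mesh, uniaxial_stretch(axis, scale))
    measured = _extents(stretched, frame)
    rel_err = np.abs(measured - expected) / np.where(expected != 0, expected, 1.0)
    return CrossCheckReport(
        measured=measured,
        expected=expected,
        relative_error=rel_err,
        tolerance=tolerance,
        passed=bool(np.all(rel_err <= tolerance)),
    )
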