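"""Procedural fixtures with closed-form ground truth.

Real digitized fossils are rarely redistributable, so every stage of the
toolkit is exercised on synthetic stand-ins generated here at run time:

* a six-region toy body of prismatic hoop segments whose volumes and CoMs
  have exact closed forms;
* a parametric ball-and-socket joint (spherical head + faceted shaft seated
  in a spherical cup) with an optional protruding rim lip over one azimuthal
  sector, and the analytic first-contact angle of the shaft against the cup
  rim for the no-lip geometry;
* a circular-centrum vertebra stand-in and a bilaterally symmetric skull
  stand-in for retrodeformation tests;
* known-distortion application (uniaxial compaction followed by shear) with
  the exact inverse recorded.

All generators are deterministic: the same spec (including seed) produces
byte-identical meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .body_model import HoopProfile, SegmentSpec, octagon_area
from .mesh_core import AffineTransform, MassProperties
from .retrodeform import uniaxial_stretch

__all__ = [
    "FixtureSpec",
    "ToyBodyFixture",
    "SocketJointFixture",
    "VertebraFixture",
    "DistortionResult",
    "make_toy_body",
    "make_socket_joint",
    "make_vertebra",
    "make_skull_pair",
    "distort",
    "random_distortion",
    "sphere_patch_points",
    "predicted_contact_angle",
]


# ---------------------------------------------------------------------------
# specs and fixture containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind, shape parameters, resolution, seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        makers = {
            "toy_body": make_toy_body,
            "socket_joint": make_socket_joint,
            "vertebra": make_vertebra,
            "skull_pair": make_skull_pair,
        }
        try:
            maker = makers[self.kind]
        except KeyError:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {sorted(makers)}") from None
        return maker(seed=self.seed, **self.params)


@dataclass
class ToyBodyFixture:
    segments: list
    analytic: dict  # segment name -> MassProperties (one copy)
    ground_truth: dict


@dataclass
class SocketJointFixture:
    girdle: trimesh.Trimesh
    bone: trimesh.Trimesh
    acs: "object"  # JointACS; imported lazily to avoid a cycle
    socket_center: np.ndarray
    params: dict
    ground_truth: dict

    def predicted_contact(self, direction: str, s_mm: float) -> float | None:
        """Analytic shaft-vs-rim contact angle (degrees) for one direction.

        Exact for the smooth geometry; mesh faceting shifts it by a fraction
        of a degree. ``None`` for the long-axis rotations (never blocked by
        an axisymmetric cup).
        """
        azimuths = {"abduction": 0.0, "adduction": 180.0, "protraction": 90.0, "retraction": 270.0}
        if direction not in azimuths:
            return None
        phi = self.params["cup_half_angle_deg"]
        lip = self.params.get("lip")
        if lip is not None:
            delta = (azimuths[direction] - lip["azimuth_center_deg"] + 180.0) % 360.0 - 180.0
            if abs(delta) <= lip["azimuth_halfwidth_deg"]:
                phi = phi + lip["extra_deg"]
        return predicted_contact_angle(
            self.params["cup_inner_radius"],
            phi,
            self.params["neck_radius"],
            s_mm / 10.0,
        )


@dataclass
class VertebraFixture:
    mesh: trimesh.Trimesh
    radius: float
    length: float
    axis: np.ndarray
    ground_truth: dict


@dataclass
class DistortionResult:
    mesh: trimesh.Trimesh
    transform: AffineTransform
    inverse: AffineTransform


# ---------------------------------------------------------------------------
# toy body
# ---------------------------------------------------------------------------


def _prism_segment(name, region, a, b, start, end, up, count=1, n_hoops=9, k=1.0):
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    axis = end - start
    length = np.linalg.norm(axis)
    axis = axis / length
    centers = start + np.linspace(0.0, length, n_hoops)[:, None] * axis
    hoops = tuple(HoopProfile(center=c, axis=axis, up=up, a=a, b=b, k=k) for c in centers)
    return SegmentSpec(name=name, hoops=hoops, count=count, region=region), length


def make_toy_body(seed: int = 0, scale: float = 1.0, n_hoops: int = 9) -> ToyBodyFixture:
    """A six-region prismatic body with exact analytic mass properties.

    Plan (cm, before ``scale``): hips at the origin, x cranial, y
    medio-lateral, z dorso-ventral. Every segment is a prism of identical
    octagonal hoops, so volume = hoop area x length and the CoM is the axis
    midpoint — both closed forms. Dimensions emulate a small sprawling
    tetrapod (~half-metre trunk+tail). ``seed`` is accepted for interface
    uniformity; the toy body is fully deterministic.
    """
    s = float(scale)
    up = (0.0, 0.0, 1.0)
    plan = [
        # name, region, a, b, start, end, up, count
        ("trunk", "trunk", 5.0, 4.0, (0, 0, 1.0), (25, 0, 1.0), up, 1),
        ("neck", "neck", 2.0, 2.0, (25, 0, 1.5), (31, 0, 1.5), up, 1),
        ("head", "head", 2.5, 2.0, (31, 0, 1.5), (39, 0, 1.5), up, 1),
        ("tail", "tail", 1.5, 1.5, (0, 0, 1.0), (-20, 0, 1.0), up, 1),
        ("pectoral_limb", "pectoral_limb", 1.5, 1.5, (22, -6, 0.0), (22, -6, -10.0), (1, 0, 0), 2),
        ("pelvic_limb", "pelvic_limb", 1.8, 1.8, (0, -6, 0.0), (0, -6, -10.0), (1, 0, 0), 2),
    ]
    segments = []
    analytic = {}
    gt_segments = {}
    for name, region, a, b, start, end, up_dir, count in plan:
        a, b = a * s, b * s
        start = np.asarray(start, dtype=float) * s
        end = np.asarray(end, dtype=float) * s
        seg, length = _prism_segment(name, region, a, b, start, end, up_dir, count, n_hoops)
        volume = octagon_area(a, b, 1.0) * length
        com = (start + end) / 2.0
        props = MassProperties(volume=volume, mass=volume * 1e-6 * seg.density, com=com)
        segments.append(seg)
        analytic[name] = props
        gt_segments[name] = {
            "volume_cm3": volume,
            "mass_kg": props.mass,
            "com_cm": com.tolist(),
            "count": count,
        }
    total = sum(p.mass * seg.count for p, seg in zip(analytic.values(), segments))
    weighted = np.zeros(3)
    for seg, props in zip(segments, analytic.values()):
        if seg.count == 2:
            weighted += props.mass * (props.com + props.com * np.array([1, -1, 1]))
        else:
            weighted += props.mass * props.com
    whole_com = weighted / total
    return ToyBodyFixture(
        segments=segments,
        analytic=analytic,
        ground_truth={
            "segments": gt_segments,
            "whole_mass_kg": total,
            "whole_com_cm": whole_com.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# ball-and-socket joint
# ---------------------------------------------------------------------------


def predicted_contact_angle(
    cup_inner_radius: float, cup_half_angle_deg: float, neck_radius: float, s_cm: float = 0.0
) -> float:
    """First-contact rotation (degrees) of a thin shaft against the cup rim.

    Smooth-geometry closed form: rotating the shaft (a cylinder of radius
    ``neck_radius`` whose axis passes through the head centre, offset by the
    joint space ``s_cm`` along +x) in a plane containing the cup axis, the
    nearest rim point lies in that plane at polar angle 180 - phi from +x.
    Contact occurs when the rim point's distance to the shaft axis equals
    the neck radius.
    """
    phi = np.deg2rad(cup_half_angle_deg)
    R = cup_inner_radius
    px = -R * np.cos(phi)
    pw = R * np.sin(phi)
    qx, qw = px - s_cm, pw
    qnorm = np.hypot(qx, qw)
    if neck_radius >= qnorm:
        raise ValueError("neck radius reaches the rim already at the reference pose")
    theta = np.arctan2(qw, qx) - np.arcsin(neck_radius / qnorm)
    return float(np.rad2deg(theta))


def _oriented(vertices, faces) -> trimesh.Trimesh:
    """Deterministic consistently-wound, outward-oriented closed mesh."""
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces[:, ::-1], process=False)
    return trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)


def _tube(radius, length, n_sections, n_rings):
    """Closed faceted cylinder along +x from 0 to length, axially subdivided."""
    psi = np.linspace(0.0, 2 * np.pi, n_sections, endpoint=False)
    ring = np.column_stack([np.zeros_like(psi), np.cos(psi), np.sin(psi)]) * radius
    xs = np.linspace(0.0, length, n_rings + 1)
    verts = np.concatenate([ring + np.array([x, 0, 0]) for x in xs])
    c0 = len(verts)
    c1 = c0 + 1
    verts = np.vstack([verts, [0.0, 0.0, 0.0], [length, 0.0, 0.0]])
    faces = []
    for i in range(n_rings):
        b0, b1 = i * n_sections, (i + 1) * n_sections
        for j in range(n_sections):
            jn = (j + 1) % n_sections
            faces.append((b0 + j, b0 + jn, b1 + jn))
            faces.append((b0 + j, b1 + jn, b1 + j))
    last = n_rings * n_sections
    for j in range(n_sections):
        jn = (j + 1) % n_sections
        faces.append((c0, jn, j))  # start cap (outward -x)
        faces.append((c1, last + j, last + jn))  # end cap (outward +x)
    return _oriented(verts, faces)


def _spherical_cup(R_in, R_out, phi_per_azimuth_deg, n_polar, n_azimuth):
    """Closed spherical-shell cap with pole at -x and per-azimuth rim angle."""
    psi = np.linspace(0.0, 2 * np.pi, n_azimuth, endpoint=False)
    phi_eff = np.deg2rad(np.asarray(phi_per_azimuth_deg, dtype=float))
    # polar angle alpha from +x: pole alpha=pi, rim alpha=pi - phi_eff
    t = np.linspace(0.0, 1.0, n_polar + 1)[1:]  # rows below the pole
    alpha = np.pi - t[:, None] * phi_eff[None, :]  # (n_polar, n_az)
    d = np.stack(
        [
            np.cos(alpha),
            np.sin(alpha) * np.cos(psi)[None, :],
            np.sin(alpha) * np.sin(psi)[None, :],
        ],
        axis=-1,
    )  # (n_polar, n_az, 3)
    inner = (R_in * d).reshape(-1, 3)
    outer = (R_out * d).reshape(-1, 3)
    pole_in = np.array([[-R_in, 0.0, 0.0]])
    pole_out = np.array([[-R_out, 0.0, 0.0]])
    verts = np.concatenate([inner, outer, pole_in, pole_out])
    n_grid = n_polar * n_azimuth
    i_pole_in, i_pole_out = 2 * n_grid, 2 * n_grid + 1

    def idx(layer, i, j):
        return layer * n_grid + i * n_azimuth + (j % n_azimuth)

    faces = []
    for j in range(n_azimuth):
        faces.append((i_pole_in, idx(0, 0, j), idx(0, 0, j + 1)))
        faces.append((i_pole_out, idx(1, 0, j + 1), idx(1, 0, j)))
    for i in range(n_polar - 1):
        for j in range(n_azimuth):
            a, b = idx(0, i, j), idx(0, i, j + 1)
            c, d2 = idx(0, i + 1, j + 1), idx(0, i + 1, j)
            faces.append((a, b, c))
            faces.append((a, c, d2))
            a, b = idx(1, i, j), idx(1, i, j + 1)
            c, d2 = idx(1, i + 1, j + 1), idx(1, i + 1, j)
            faces.append((a, c, b))
            faces.append((a, d2, c))
    rim = n_polar - 1
    for j in range(n_azimuth):
        a, b = idx(0, rim, j), idx(0, rim, j + 1)
        c, d2 = idx(1, rim, j + 1), idx(1, rim, j)
        faces.append((a, b, c))
        faces.append((a, c, d2))
    return _oriented(verts, faces)


def make_socket_joint(
    seed: int = 0,
    head_radius: float = 1.0,
    neck_radius: float = 0.35,
    shaft_length: float = 4.0,
    clearance: float = 0.05,
    cup_half_angle_deg: float = 90.0,
    cup_thickness: float = 0.2,
    lip: dict | None = None,
    n_azimuth: int = 64,
    n_polar: int = 10,
    shaft_sections: int = 32,
    shaft_rings: int = 12,
    head_subdivisions: int = 2,
) -> SocketJointFixture:
    """Ball-and-socket fixture: spherical head + shaft seated in a cup.

    The bone is a head sphere centred at the origin with a faceted shaft
    along +x; the girdle is a spherical-shell cup of inner radius
    ``head_radius + clearance`` whose pole sits at -x and whose rim lies at
    ``cup_half_angle_deg`` from the pole. ``lip`` (optional) extends the
    coverage by ``extra_deg`` over an azimuthal sector
    (``azimuth_center_deg`` +- ``azimuth_halfwidth_deg``; azimuth 0 = +y,
    90 = +z/cranial), emulating a bony acetabular lip. The reference pose
    has the shaft lateral (+x), y up, z cranial — x is the long axis.

    Ground truth: the analytic no-lip contact angle per joint space (exact
    for smooth geometry; faceting shifts it by well under a degree at the
    default resolution).
    """
    if not neck_radius < head_radius:
        raise ValueError("neck radius must be smaller than head radius")
    if not 0.0 < cup_half_angle_deg <= 90.0:
        raise ValueError("cup half-angle must lie in (0, 90] degrees")
    if lip is not None:
        missing = {"azimuth_center_deg", "azimuth_halfwidth_deg", "extra_deg"} - set(lip)
        if missing:
            raise ValueError(f"lip definition missing keys: {sorted(missing)}")

    R_in = head_radius + clearance
    psi_deg = np.arange(n_azimuth) * 360.0 / n_azimuth
    phi_eff = np.full(n_azimuth, cup_half_angle_deg)
    if lip is not None:
        delta = (psi_deg - lip["azimuth_center_deg"] + 180.0) % 360.0 - 180.0
        phi_eff[np.abs(delta) <= lip["azimuth_halfwidth_deg"]] += lip["extra_deg"]
    girdle = _spherical_cup(R_in, R_in + cup_thickness, phi_eff, n_polar, n_azimuth)

    head = trimesh.creation.icosphere(subdivisions=head_subdivisions, radius=head_radius)
    head = trimesh.Trimesh(vertices=head.vertices, faces=head.faces, process=False)
    shaft = _tube(neck_radius, shaft_length, shaft_sections, shaft_rings)
    bone = trimesh.util.concatenate([head, shaft])
    bone = trimesh.Trimesh(vertices=bone.vertices, faces=bone.faces, process=False)

    from .joint_rom import JointACS  # late import: joint_rom imports nothing from here

    acs = JointACS(origin=(0.0, 0.0, 0.0), x_axis=(1, 0, 0), y_axis=(0, 1, 0), z_axis=(0, 0, 1))
    socket_center = np.array([-R_in, 0.0, 0.0])
    params = {
        "head_radius": head_radius,
        "neck_radius": neck_radius,
        "shaft_length": shaft_length,
        "clearance": clearance,
        "cup_inner_radius": R_in,
        "cup_half_angle_deg": cup_half_angle_deg,
        "cup_thickness": cup_thickness,
        "lip": lip,
    }
    gt = {
        "no_lip_contact_deg": {
            f"{s:.1f}": predicted_contact_angle(R_in, cup_half_angle_deg, neck_radius, s / 10.0)
            for s in (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)
        }
    }
    return SocketJointFixture(
        girdle=girdle, bone=bone, acs=acs, socket_center=socket_center,
        params=params, ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# vertebra / skull stand-ins
# ---------------------------------------------------------------------------


def make_vertebra(
    seed: int = 0, radius: float = 1.0, length: float = 2.5, n_sections: int = 48
) -> VertebraFixture:
    """Circular-centrum vertebra stand-in: a capped cylinder along x.

    Synthetic stand-in for an isolated vertebral centrum whose cross-section
    perpendicular to the cranio-caudal (x) axis is an exact circle, so any
    measured roundness departure is pure distortion.
    """
    mesh = _tube(radius, length, n_sections, 2)
    mesh = trimesh.Trimesh(
        vertices=mesh.vertices - np.array([length / 2.0, 0.0, 0.0]),
        faces=mesh.faces,
        process=False,
    )
    return VertebraFixture(
        mesh=mesh,
        radius=radius,
        length=length,
        axis=np.array([1.0, 0.0, 0.0]),
        ground_truth={"radius_cm": radius, "length_cm": length, "roundness": 1.0},
    )


def make_skull_pair(seed: int = 0, size: float = 3.0, subdivisions: int = 3) -> trimesh.Trimesh:
    """Bilaterally symmetric skull stand-in (synthetic; mirror plane y = 0).

    An ellipsoidal braincase with two mirrored lateral bosses; used to test
    that shear correction restores bilateral symmetry.
    """
    case = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    case_v = case.vertices * np.array([1.0 * size, 0.55 * size, 0.4 * size])
    boss = trimesh.creation.icosphere(subdivisions=max(subdivisions - 1, 1), radius=0.18 * size)
    parts = [trimesh.Trimesh(vertices=case_v, faces=case.faces, process=False)]
    for sign in (+1.0, -1.0):
        center = np.array([0.25 * size, sign * 0.55 * size, 0.05 * size])
        parts.append(
            trimesh.Trimesh(vertices=boss.vertices + center, faces=boss.faces, process=False)
        )
    merged = trimesh.util.concatenate(parts)
    return trimesh.Trimesh(vertices=merged.vertices, faces=merged.faces, process=False)


# ---------------------------------------------------------------------------
# known distortions
# ---------------------------------------------------------------------------


def distort(
    mesh: trimesh.Trimesh,
    shear: AffineTransform | np.ndarray | None = None,
    dv_compression: float = 1.0,
    dv_dir=(0.0, 0.0, 1.0),
) -> DistortionResult:
    """Apply compaction then shear, recording the exact inverse.

    ``dv_compression`` in (0, 1] scales the mesh along ``dv_dir`` (vertical
    compaction); ``shear`` is an additional affine map applied afterwards
    (tectonic shear). The returned inverse undoes the composite exactly.
    """
    if not 0.0 < dv_compression <= 1.0:
        raise ValueError("dv_compression must lie in (0, 1]")
    from .mesh_core import apply_transform

    comp = uniaxial_stretch(dv_dir, dv_compression)
    if shear is None:
        shear_t = AffineTransform.identity()
    elif isinstance(shear, AffineTransform):
        shear_t = shear
    else:
        shear_t = AffineTransform(np.asarray(shear, dtype=float))
    transform = shear_t.compose(comp)  # compression first, then shear
    return DistortionResult(
        mesh=apply_transform(mesh, transform),
        transform=transform,
        inverse=transform.inverse(),
    )


def random_distortion(
    seed: int, max_shear: float = 0.3, compression_range=(0.55, 0.9)
) -> tuple[AffineTransform, float]:
    """Seeded random shear matrix and compaction factor for round-trip tests."""
    rng = np.random.default_rng(seed)
    shear = np.eye(3)
    off = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    for i, j in off:
        shear[i, j] = rng.uniform(-max_shear, max_shear)
    if np.linalg.det(shear) <= 0.05:  # keep well-conditioned and orientation-preserving
        return random_distortion(seed + 1, max_shear, compression_range)
    compression = float(rng.uniform(*compression_range))
    return AffineTransform(shear), compression


# ---------------------------------------------------------------------------
# sphere-fit test data
# ---------------------------------------------------------------------------


def sphere_patch_points(
    center=(0.0, 0.0, 0.0),
    radius: float = 1.0,
    n: int = 200,
    cap_half_angle_deg: float = 90.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Deterministic points on (or near) a spherical cap around +z.

    Points are spread with a Fibonacci lattice over the cap; optional
    Gaussian radial noise (along the surface normal) with a fixed seed.
    """
    k = np.arange(n) + 0.5
    cos_max = np.cos(np.deg2rad(cap_half_angle_deg))
    z = 1.0 - (1.0 - cos_max) * k / n
    azimuth = np.pi * (1.0 + np.sqrt(5.0)) * k
    sin_t = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    normals = np.column_stack([sin_t * np.cos(azimuth), sin_t * np.sin(azimuth), z])
    r = np.full(n, float(radius))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sigma, size=n)
    return np.asarray(center, dtype=float) + normals * r[:, None]
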