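"""Volumetric body-shape model: octagonal hoops lofted along skeletal axes.

A body segment is described by ordered octagonal cross-section hoops that hug
the skeleton; the hoops are skinned into a closed surface whose volume (at a
tissue density of 1000 kg m^-3 by default) gives the segment mass, and the
segment masses and centres of mass compose into whole-body mass

    M_body = sum_i m_i

and whole-body centre of mass

    CoM = (1 / M_body) * sum_i m_i r_i

in a system frame with x cranio-caudal (cranial positive), y medio-lateral
and z dorso-ventral, origin midway between the hips in the reference pose.

Uncertainty in the soft-tissue outline is handled by a min/max envelope:
"maximal" outlines inflate the hoop semi-axes to 120% and bulge the diagonal
vertices to a profile intermediate between ellipse and square; "minimal"
outlines keep the skeleton-hugging semi-axes and pull the diagonals in to a
profile intermediate between ellipse and diamond. Combining per-segment
minima and maxima yields the canonical four whole-body models (max/min
overall, max cranial, max caudal) plus the mean-estimate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .mesh_core import (
    DegenerateGeometryError,
    MassProperties,
    contains_mesh,
    mass_properties,
)

__all__ = [
    "HoopProfile",
    "SegmentSpec",
    "OutlineVariant",
    "BodyMassReport",
    "SegmentMassEntry",
    "K_MIN",
    "K_MAX",
    "REGIONS",
    "diagonal_scale",
    "octagon_area",
    "make_octagon",
    "loft",
    "apply_variant",
    "subtract_cavities",
    "segment_mass_properties",
    "total_mass",
    "whole_body_com",
    "whole_body_models",
    "sensitivity_report",
]

_SQRT2 = float(np.sqrt(2.0))

#: recognised body regions for the sensitivity combination scheme
REGIONS = ("head", "neck", "trunk", "pectoral_limb", "pelvic_limb", "tail")

#: regions whose mass pulls the CoM cranially / caudally
_CRANIAL = frozenset({"neck", "trunk", "pectoral_limb"})
_CAUDAL = frozenset({"pelvic_limb", "tail"})


def diagonal_scale(profile: str) -> float:
    """Diagonal vertex scale factor of an octagonal hoop for a named profile.

    The 45-degree vertex of an elliptical profile sits at a fraction 1/sqrt(2)
    of the semi-axes, a square corner at a fraction 1 — i.e. at 1 and sqrt(2)
    times the elliptical diagonal — and a diamond edge midpoint at 1/sqrt(2)
    times it. "Intermediate" profiles take the midpoint of the elliptical
    factor and the extreme:

    =====================  =======================
    profile                factor
    =====================  =======================
    ellipse                1
    square                 sqrt(2)        ~ 1.414
    diamond                1/sqrt(2)      ~ 0.707
    ellipse-square         (1+sqrt(2))/2  ~ 1.207
    ellipse-diamond        (1+1/sqrt(2))/2 ~ 0.853
    =====================  =======================
    """
    table = {
        "ellipse": 1.0,
        "square": _SQRT2,
        "diamond": 1.0 / _SQRT2,
        "ellipse-square": (1.0 + _SQRT2) / 2.0,
        "ellipse-diamond": (1.0 + 1.0 / _SQRT2) / 2.0,
    }
    try:
        return table[profile]
    except KeyError:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(table)}") from None


#: diagonal scale of the "minimal" outline (intermediate ellipse/diamond), ~0.853
K_MIN = diagonal_scale("ellipse-diamond")
#: diagonal scale of the "maximal" outline (intermediate ellipse/square), ~1.207
K_MAX = diagonal_scale("ellipse-square")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HoopProfile:
    """One octagonal cross-section hoop.

    ``center`` lies on the segment's skeletal axis; the hoop spans the plane
    perpendicular to ``axis`` (the loft direction), with ``up`` the
    dorso-ventral direction in that plane. ``a`` and ``b`` are the lateral
    and dorso-ventral semi-axes (cm); ``k`` scales the four diagonal
    vertices between the diamond (1/sqrt 2) and square (sqrt 2) limits.
    """

    center: np.ndarray
    axis: np.ndarray
    up: np.ndarray
    a: float
    b: float
    k: float = 1.0

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float).reshape(3)
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        up = np.asarray(self.up, dtype=float).reshape(3)
        axis = axis / np.linalg.norm(axis)
        up = up / np.linalg.norm(up)
        if abs(axis @ up) > 1e-8:
            raise ValueError("hoop axis and up direction must be perpendicular")
        if not (self.a > 0 and self.b > 0):
            raise ValueError("hoop semi-axes must be positive")
        if not (1.0 / _SQRT2 - 1e-9 <= self.k <= _SQRT2 + 1e-9):
            raise ValueError(f"diagonal scale k={self.k} outside [1/sqrt2, sqrt2]")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "up", up)


@dataclass(frozen=True)
class SegmentSpec:
    """A body segment: ordered hoops, optional cavities, density, multiplicity.

    ``count=2`` marks a bilaterally paired segment (limbs) whose mirror image
    about the sagittal plane is counted in whole-body sums. ``region`` tags
    the segment for the min/max combination scheme.
    """

    name: str
    hoops: tuple
    cavities: tuple = ()
    density: float = 1000.0
    count: int = 1
    region: str | None = None

    def __post_init__(self):
        hoops = tuple(self.hoops)
        if len(hoops) < 2:
            raise ValueError(f"segment {self.name!r} needs at least 2 hoops")
        if self.count < 1:
            raise ValueError("segment multiplicity must be >= 1")
        # consecutive centers strictly ordered along the mean loft direction
        centers = np.array([h.center for h in hoops])
        direction = np.mean([h.axis for h in hoops], axis=0)
        s = centers @ direction
        if not np.all(np.diff(s) > 1e-12):
            raise ValueError(
                f"segment {self.name!r}: hoop centers must advance strictly along the axis"
            )
        object.__setattr__(self, "hoops", hoops)
        object.__setattr__(self, "cavities", tuple(self.cavities))


@dataclass(frozen=True)
class OutlineVariant:
    """Parameters of the min/max outline envelope.

    ``radial_scale`` inflates the semi-axes of "maximal" outlines (1.0 =
    skeleton-hugging, 1.2 = +20%); ``k_max``/``k_min`` are the diagonal
    scales of the maximal and minimal profiles.
    """

    radial_scale: float = 1.2
    k_min: float = K_MIN
    k_max: float = K_MAX

    def __post_init__(self):
        if not (1.0 <= self.radial_scale <= 1.2 + 1e-12):
            raise ValueError("radial_scale must lie in [1.0, 1.2]")


@dataclass(frozen=True)
class SegmentMassEntry:
    """Mass (kg) and CoM (cm) of one segment, with multiplicity.

    For ``count=2`` the entry describes one side of a bilateral pair; the
    pair contributes mirrored CoMs at (x, +y, z) and (x, -y, z).
    """

    mass: float
    com: np.ndarray
    count: int = 1

    def __post_init__(self):
        object.__setattr__(self, "com", np.asarray(self.com, dtype=float).reshape(3))
        if self.mass < 0:
            raise ValueError("segment mass must be >= 0")
        if self.count not in (1, 2):
            raise ValueError("segment multiplicity must be 1 or 2 (bilateral pair)")


@dataclass
class BodyMassReport:
    """Per-segment variants plus whole-body models, Table-style."""

    segments: pd.DataFrame
    whole: pd.DataFrame
    segment_properties: dict = field(default_factory=dict)

    def model(self, name: str) -> pd.Series:
        return self.whole.set_index("model").loc[name]


# ---------------------------------------------------------------------------
# hoop geometry
# ---------------------------------------------------------------------------


def octagon_area(a: float, b: float, k: float = 1.0) -> float:
    """Closed-form area of the octagonal profile: 2*sqrt(2)*k*a*b."""
    return 2.0 * _SQRT2 * k * a * b


def make_octagon(h: HoopProfile) -> np.ndarray:
    """The hoop's 8 vertices (cm), counter-clockwise viewed along the axis.

    Cardinal vertices sit at +-a laterally and +-b dorso-ventrally; the four
    diagonal vertices at k * (+-a/sqrt2, +-b/sqrt2).
    """
    lateral = np.cross(h.up, h.axis)
    lateral /= np.linalg.norm(lateral)
    s = 1.0 / _SQRT2
    local = np.array(
        [
            (h.a, 0.0),
            (h.k * h.a * s, h.k * h.b * s),
            (0.0, h.b),
            (-h.k * h.a * s, h.k * h.b * s),
            (-h.a, 0.0),
            (-h.k * h.a * s, -h.k * h.b * s),
            (0.0, -h.b),
            (h.k * h.a * s, -h.k * h.b * s),
        ]
    )
    return h.center + local[:, :1] * lateral + local[:, 1:] * h.up


def loft(segment: SegmentSpec) -> trimesh.Trimesh:
    """Skin the segment's hoops into a watertight triangle mesh.

    Corresponding vertices of consecutive octagons are joined by quad strips
    (split into triangles) and the first and last hoops are closed with
    triangle fans around their centers. Cavities are *not* subtracted here —
    see :func:`segment_mass_properties`.
    """
    rings = np.array([make_octagon(h) for h in segment.hoops])  # (n, 8, 3)
    n = len(rings)
    _warn_if_self_intersecting(segment)
    vertices = rings.reshape(-1, 3)
    start_c = len(vertices)
    end_c = start_c + 1
    vertices = np.vstack([vertices, segment.hoops[0].center, segment.hoops[-1].center])
    faces = []
    for i in range(n - 1):
        base0 = 8 * i
        base1 = 8 * (i + 1)
        for j in range(8):
            jn = (j + 1) % 8
            a, b = base0 + j, base0 + jn
            c, d = base1 + jn, base1 + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    for j in range(8):
        jn = (j + 1) % 8
        faces.append((start_c, jn, j))  # start cap, outward = -axis
        faces.append((end_c, 8 * (n - 1) + j, 8 * (n - 1) + jn))  # end cap
    return trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)


def _warn_if_self_intersecting(segment: SegmentSpec) -> None:
    """Heuristic diagnostic: hoop spacing too small for the radius/axis change."""
    hoops = segment.hoops
    for h0, h1 in zip(hoops, hoops[1:]):
        spacing = float(np.linalg.norm(h1.center - h0.center))
        tilt = float(np.arccos(np.clip(h0.axis @ h1.axis, -1.0, 1.0)))
        reach = max(h0.a, h0.b, h1.a, h1.b) * np.sin(tilt / 2.0) * 2.0
        if reach > spacing:
            warnings.warn(
                f"segment {segment.name!r}: hoop planes may self-intersect "
                f"(spacing {spacing:.3g} cm < tilted reach {reach:.3g} cm)",
                RuntimeWarning,
                stacklevel=3,
            )
            return


def apply_variant(segment: SegmentSpec, variant: OutlineVariant, which: str) -> SegmentSpec:
    """Return the 'min' or 'max' outline of a segment.

    max: semi-axes scaled by ``variant.radial_scale`` and diagonals set to
    ``k_max``; min: semi-axes kept at their skeleton-hugging values and
    diagonals set to ``k_min``. Hoop centers and axes are unchanged
    (inflation is about each hoop's own center).
    """
    if which == "max":
        scale, k = variant.radial_scale, variant.k_max
    elif which == "min":
        scale, k = 1.0, variant.k_min
    else:
        raise ValueError(f"variant selector must be 'min' or 'max', got {which!r}")
    hoops = tuple(
        replace(h, a=h.a * scale, b=h.b * scale, k=k) for h in segment.hoops
    )
    return replace(segment, hoops=hoops)


# ---------------------------------------------------------------------------
# mass properties
# ---------------------------------------------------------------------------


def subtract_cavities(
    mesh: trimesh.Trimesh,
    cavities: list[trimesh.Trimesh],
    density: float = 1000.0,
) -> MassProperties:
    """Segment mass properties with contained cavity volumes removed.

    Pure mass-property arithmetic (V <- V - Vc, CoM <- (V r - Vc rc)/(V - Vc));
    no boolean surface operation is performed, which is exact as long as each
    cavity is fully contained in the segment mesh (checked).
    """
    props = mass_properties(mesh, density)
    volume, com = props.volume, props.com
    for cav in cavities:
        if not contains_mesh(mesh, cav):
            raise ValueError("cavity mesh is not fully contained in the segment mesh")
        cav_props = mass_properties(cav, density)
        new_volume = volume - cav_props.volume
        if not new_volume > 0:
            raise DegenerateGeometryError("cavity subtraction left non-positive volume")
        com = (volume * com - cav_props.volume * cav_props.com) / new_volume
        volume = new_volume
    return MassProperties(volume=volume, mass=volume * 1e-6 * density, com=com)


def segment_mass_properties(segment: SegmentSpec) -> MassProperties:
    """Mass properties of one copy of the segment (cavities subtracted)."""
    mesh = loft(segment)
    cavity_meshes = [
        loft(c) if isinstance(c, SegmentSpec) else c for c in segment.cavities
    ]
    return subtract_cavities(mesh, cavity_meshes, segment.density)


def total_mass(entries: list[SegmentMassEntry]) -> float:
    """Whole-body mass: sum of segment masses, paired segments counted twice."""
    return float(sum(e.mass * e.count for e in entries))


def whole_body_com(entries: list[SegmentMassEntry]) -> np.ndarray:
    """Mass-weighted whole-body CoM; bilateral pairs contribute (x, +-y, z)."""
    m_body = total_mass(entries)
    if not m_body > 0:
        raise DegenerateGeometryError("whole-body mass must be positive")
    weighted = np.zeros(3)
    for e in entries:
        if e.count == 2:
            mirrored = e.com * np.array([1.0, -1.0, 1.0])
            weighted += e.mass * (e.com + mirrored)
        else:
            weighted += e.mass * e.com
    return weighted / m_body


# ---------------------------------------------------------------------------
# sensitivity combinatorics
# ---------------------------------------------------------------------------


def _check_regions(regions):
    unknown = set(regions) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown body region(s): {sorted(unknown)}; expected {REGIONS}")
    if None in regions:
        raise ValueError("every segment needs a region tag for the combination scheme")


def whole_body_models(per_segment: list[dict]) -> pd.DataFrame:
    """The five canonical whole-body models from per-segment min/max entries.

    ``per_segment`` holds one dict per segment with keys ``region``,
    ``count`` and entries ``min``/``max`` (each ``(mass, com)``); the head
    may carry a ``single`` entry instead, held fixed across combinations.

    Models: max_overall (all max), min_overall (all min), max_cranial (max
    neck/trunk/pectoral with min pelvic/tail), max_caudal (the converse) and
    mean (arithmetic mean of the min_overall and max_overall mass and CoM).
    """
    _check_regions([seg["region"] for seg in per_segment])

    def pick(seg, which):
        if "single" in seg:
            mass, com = seg["single"]
        else:
            mass, com = seg[which]
        return SegmentMassEntry(mass=mass, com=com, count=seg.get("count", 1))

    def combo(selector):
        entries = [pick(seg, selector(seg["region"])) for seg in per_segment]
        return total_mass(entries), whole_body_com(entries)

    models = {
        "max_cranial": combo(lambda r: "max" if r in _CRANIAL else "min"),
        "max_caudal": combo(lambda r: "max" if r in _CAUDAL else "min"),
        "max_overall": combo(lambda r: "max"),
        "min_overall": combo(lambda r: "min"),
    }
    mean_mass = (models["max_overall"][0] + models["min_overall"][0]) / 2.0
    mean_com = (models["max_overall"][1] + models["min_overall"][1]) / 2.0
    models["mean"] = (mean_mass, mean_com)
    rows = [
        {"model": name, "mass_kg": m, "x_cm": c[0], "y_cm": c[1], "z_cm": c[2]}
        for name, (m, c) in models.items()
    ]
    return pd.DataFrame(rows)


def sensitivity_report(
    segments: list[SegmentSpec], variant: OutlineVariant | None = None
) -> BodyMassReport:
    """Run the full min/max outline sensitivity analysis on a segmented body.

    Each non-head segment is lofted in its minimal and maximal outline; the
    head keeps its single configured outline (it is not varied in the
    canonical combination scheme, though callers may vary it by passing
    pre-varied specs). Emits per-segment rows plus the five whole-body
    models.
    """
    variant = variant or OutlineVariant()
    _check_regions([s.region for s in segments])

    seg_rows = []
    per_segment = []
    seg_props: dict[str, dict[str, MassProperties]] = {}
    for seg in segments:
        entry: dict = {"region": seg.region, "count": seg.count}
        if seg.region == "head":
            props = segment_mass_properties(seg)
            entry["single"] = (props.mass, props.com)
            seg_props[seg.name] = {"single": props}
            seg_rows.append(_segment_row(seg, "single", props))
        else:
            variants = {}
            for which in ("max", "min"):
                props = segment_mass_properties(apply_variant(seg, variant, which))
                variants[which] = props
                entry[which] = (props.mass, props.com)
                seg_rows.append(_segment_row(seg, which, props))
            seg_props[seg.name] = variants
        per_segment.append(entry)

    whole = whole_body_models(per_segment)
    return BodyMassReport(
        segments=pd.DataFrame(seg_rows), whole=whole, segment_properties=seg_props
    )


def _segment_row(seg: SegmentSpec, which: str, props: MassProperties) -> dict:
    return {
        "segment": seg.name,
        "region": seg.region,
        "variant": which,
        "count": seg.count,
        "volume_cm3": props.volume,
        "mass_kg": props.mass,
        "x_cm": props.com[0],
        "y_cm": props.com[1],
        "z_cm": props.com[2],
    }
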