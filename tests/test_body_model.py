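"""Octagonal hoops, lofting, outline variants and whole-body composition."""

import numpy as np
import pytest
import trimesh

from paleobody import (
    HoopProfile,
    K_MAX,
    K_MIN,
    OutlineVariant,
    SegmentMassEntry,
    SegmentSpec,
    apply_variant,
    diagonal_scale,
    loft,
    make_octagon,
    mass_properties,
    octagon_area,
    segment_mass_properties,
    sensitivity_report,
    subtract_cavities,
    total_mass,
    whole_body_com,
    whole_body_models,
)
from paleobody.synthetic_specimen import make_toy_body


def _hoop(center, a=1.0, b=1.0, k=1.0, axis=(1, 0, 0), up=(0, 0, 1)):
    return HoopProfile(center=center, axis=axis, up=up, a=a, b=b, k=k)


def _prism(a=1.0, b=1.0, k=1.0, length=5.0, n=2, region="trunk", count=1):
    centers = np.linspace(0, length, n)
    hoops = tuple(_hoop((c, 0, 0), a, b, k) for c in centers)
    return SegmentSpec(name="seg", hoops=hoops, region=region, count=count)


def _shoelace(h: HoopProfile) -> float:
    """Independent polygon-area oracle in the hoop plane."""
    verts = make_octagon(h)
    lateral = np.cross(h.up, h.axis)
    x = (verts - h.center) @ (lateral / np.linalg.norm(lateral))
    y = (verts - h.center) @ h.up
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestOctagon:
    def test_unit_circle_octagon_area(self):
        h = _hoop((0, 0, 0))
        assert _shoelace(h) == pytest.approx(2 * np.sqrt(2))
        assert octagon_area(1, 1, 1) == pytest.approx(2 * np.sqrt(2))

    def test_square_limit(self):
        h = _hoop((0, 0, 0), k=np.sqrt(2))
        verts = make_octagon(h)
        assert _shoelace(h) == pytest.approx(4.0)
        # diagonals coincide with the square corners
        assert np.max(np.abs(verts[:, 1:])) == pytest.approx(1.0)

    def test_intermediate_profile_between_ellipse_and_square(self):
        h_mid = _hoop((0, 0, 0), a=2.0, b=1.0, k=K_MAX)
        area_mid = _shoelace(h_mid)
        assert _shoelace(_hoop((0, 0, 0), a=2.0, b=1.0, k=1.0)) < area_mid
        assert area_mid < _shoelace(_hoop((0, 0, 0), a=2.0, b=1.0, k=np.sqrt(2)))
        # closed form agrees with the shoelace oracle for anisotropic hoops
        assert octagon_area(2.0, 1.0, K_MAX) == pytest.approx(area_mid)

    def test_counter_clockwise_order_about_axis(self):
        verts = make_octagon(_hoop((0, 0, 0)))
        ang = np.unwrap(np.arctan2(verts[:, 2], verts[:, 1]))
        assert np.all(np.diff(ang) > 0)

    def test_diagonal_scale_calibration(self):
        """The geometric derivation reproduces the 120.7% / 85.3% factors."""
        assert diagonal_scale("ellipse-square") == pytest.approx((1 + np.sqrt(2)) / 2)
        assert diagonal_scale("ellipse-diamond") == pytest.approx((1 + 1 / np.sqrt(2)) / 2)
        # reported to 3 significant figures as 120.7% and 85.3%
        assert abs(diagonal_scale("ellipse-square") - 1.207) < 1e-3
        assert abs(diagonal_scale("ellipse-diamond") - 0.853) < 1e-3

    def test_invalid_hoops_rejected(self):
        with pytest.raises(ValueError, match="perpendicular"):
            HoopProfile(center=(0, 0, 0), axis=(1, 0, 0), up=(1, 1, 0), a=1, b=1)
        with pytest.raises(ValueError, match="k="):
            _hoop((0, 0, 0), k=1.5)


class TestLoft:
    def test_square_prism_volume(self):
        seg = _prism(a=1.0, b=1.0, k=np.sqrt(2), length=3.0)
        mesh = loft(seg)
        assert mesh.is_watertight
        assert mass_properties(mesh).volume == pytest.approx(4.0 * 3.0)

    def test_octagonal_prism_volume_and_com(self):
        seg = _prism(a=1.5, b=0.8, k=1.0, length=5.0, n=12)
        mp = mass_properties(loft(seg))
        assert mp.volume == pytest.approx(octagon_area(1.5, 0.8, 1.0) * 5.0)
        assert np.allclose(mp.com, (2.5, 0, 0), atol=1e-9)

    @pytest.mark.parametrize("n", [3, 12, 60])
    def test_taper_matches_slice_integral(self, n):
        """Cone-like taper: volume equals area-coefficient * integral(a(t)b(t))dt.

        For linear tapers the quad-split slivers cancel, so the lofted
        polyhedron integrates the cross-section area exactly at any hoop
        count; the closed-form integral is the independent oracle.
        """
        L, a0, b0, taper = 6.0, 2.0, 1.5, 0.95
        coef = octagon_area(1.0, 1.0, 1.0)
        ts = np.linspace(0.0, 1.0, n)
        # taper to a point is degenerate; stop just short of the apex
        hoops = tuple(
            _hoop((t * L, 0, 0), a=a0 * (1 - taper * t), b=b0 * (1 - taper * t)) for t in ts
        )
        seg = SegmentSpec(name="cone", hoops=hoops, region="tail")
        analytic = coef * a0 * b0 * L * (1.0 - (1.0 - taper) ** 3) / (3.0 * taper)
        assert mass_properties(loft(seg)).volume == pytest.approx(analytic, rel=1e-9)

    def test_self_intersection_warning(self):
        hoops = (
            _hoop((0, 0, 0), a=3.0, b=3.0),
            HoopProfile(center=(0.2, 0, 0), axis=(0.4, 0.9165151389911680, 0),
                        up=(0, 0, 1), a=3.0, b=3.0),
        )
        seg = SegmentSpec(name="kink", hoops=hoops, region="tail")
        with pytest.warns(RuntimeWarning, match="self-intersect"):
            loft(seg)


class TestOutlineVariants:
    def test_min_max_rules(self):
        seg = _prism(a=1.0, b=1.0)
        v = OutlineVariant()
        mx = apply_variant(seg, v, "max")
        mn = apply_variant(seg, v, "min")
        assert mx.hoops[0].a == pytest.approx(1.2)
        assert mx.hoops[0].k == pytest.approx(1.207, abs=1e-3)
        assert mn.hoops[0].a == pytest.approx(1.0)
        assert mn.hoops[0].k == pytest.approx(0.853, abs=1e-3)
        assert np.allclose(mx.hoops[0].center, seg.hoops[0].center)

    def test_volume_ratio_matches_area_ratio_oracle(self):
        seg = _prism(a=1.3, b=0.7, length=4.0)
        v = OutlineVariant()
        vol_max = mass_properties(loft(apply_variant(seg, v, "max"))).volume
        vol_min = mass_properties(loft(apply_variant(seg, v, "min"))).volume
        area_max = _shoelace(apply_variant(seg, v, "max").hoops[0])
        area_min = _shoelace(apply_variant(seg, v, "min").hoops[0])
        assert vol_max / vol_min == pytest.approx(area_max / area_min, rel=1e-9)
        assert vol_max / vol_min == pytest.approx(1.2**2 * K_MAX / K_MIN, rel=1e-9)


class TestCavities:
    def test_centred_cavity_volume_only(self):
        outer = trimesh.creation.box((10, 10, 10))
        inner = trimesh.creation.box((2, 2, 2))
        got = subtract_cavities(outer, [inner])
        assert got.volume == pytest.approx(992.0)
        assert np.allclose(got.com, 0.0, atol=1e-9)

    def test_offcentre_cavity_matches_hollowed_mesh_oracle(self):
        outer = trimesh.creation.box((10, 10, 10))
        inner = trimesh.creation.box((2, 3, 2))
        inner = trimesh.Trimesh(inner.vertices + [2.0, 1.0, -1.5], inner.faces, process=False)
        got = subtract_cavities(outer, [inner])
        # oracle: one explicit closed surface with an inward-oriented void
        hollow = trimesh.util.concatenate(
            [outer, trimesh.Trimesh(inner.vertices, inner.faces[:, ::-1], process=False)]
        )
        oracle = mass_properties(trimesh.Trimesh(hollow.vertices, hollow.faces, process=False))
        assert got.volume == pytest.approx(oracle.volume, rel=1e-12)
        assert np.allclose(got.com, oracle.com, atol=1e-9)
        # CoM moves away from the removed (cranio-dorsal) volume
        assert got.com[0] < 0 and got.com[2] > 0

    def test_empty_cavity_list_is_identity(self):
        outer = trimesh.creation.box((4, 4, 4))
        got = subtract_cavities(outer, [])
        ref = mass_properties(outer)
        assert got.volume == ref.volume and np.allclose(got.com, ref.com)

    def test_uncontained_cavity_rejected(self):
        outer = trimesh.creation.box((4, 4, 4))
        stray = trimesh.creation.box((2, 2, 2))
        stray = trimesh.Trimesh(stray.vertices + [3.0, 0, 0], stray.faces, process=False)
        with pytest.raises(ValueError, match="contained"):
            subtract_cavities(outer, [stray])


class TestWholeBody:
    def test_total_mass_counts_pairs_twice(self):
        entries = [
            SegmentMassEntry(1.0, (0, 0, 0)),
            SegmentMassEntry(0.25, (1, -2, 0), count=2),
        ]
        assert total_mass(entries) == pytest.approx(1.5)

    def test_two_equal_point_masses_balance(self):
        entries = [SegmentMassEntry(1.0, (1, 0, 0)), SegmentMassEntry(1.0, (-1, 0, 0))]
        assert np.allclose(whole_body_com(entries), 0.0)

    def test_mirrored_pairs_cancel_y_exactly(self):
        entries = [
            SegmentMassEntry(2.0, (3.0, 0.0, 1.0)),
            SegmentMassEntry(0.5, (1.0, -4.0, -2.0), count=2),
        ]
        com = whole_body_com(entries)
        assert com[1] == 0.0  # exact, not approximate
        assert com[0] == pytest.approx((2 * 3 + 2 * 0.5 * 1) / 3)

    def test_single_segment_degenerates_to_its_com(self):
        entries = [SegmentMassEntry(0.7, (2.0, 0.5, -1.0))]
        assert np.allclose(whole_body_com(entries), (2.0, 0.5, -1.0))

    def test_hand_computed_two_segment_body(self):
        """Mass and CoM composition against explicit hand arithmetic."""
        rows = [
            {"region": "trunk", "count": 1, "max": (2.0, (10.0, 0, 1.0)), "min": (1.0, (8.0, 0, 1.0))},
            {"region": "tail", "count": 1, "max": (0.5, (-5.0, 0, 0.5)), "min": (0.2, (-4.0, 0, 0.5))},
        ]
        models = whole_body_models(rows).set_index("model")
        assert models.loc["max_overall", "mass_kg"] == pytest.approx(2.5)
        assert models.loc["max_overall", "x_cm"] == pytest.approx((2 * 10 - 0.5 * 5) / 2.5)
        assert models.loc["max_cranial", "mass_kg"] == pytest.approx(2.2)
        assert models.loc["max_cranial", "x_cm"] == pytest.approx((2 * 10 - 0.2 * 4) / 2.2)
        assert models.loc["mean", "mass_kg"] == pytest.approx((2.5 + 1.2) / 2)

    def test_missing_region_rejected(self):
        with pytest.raises(ValueError, match="region"):
            whole_body_models([{"region": None, "count": 1, "max": (1, (0, 0, 0)), "min": (1, (0, 0, 0))}])


class TestSensitivityReport:
    def test_toy_body_envelope_invariants(self, toy_body):
        report = sensitivity_report(toy_body.segments)
        seg = report.segments
        for name, grp in seg[seg.variant != "single"].groupby("segment"):
            vmax = grp.loc[grp.variant == "max", "volume_cm3"].item()
            vmin = grp.loc[grp.variant == "min", "volume_cm3"].item()
            assert vmax > vmin
        whole = report.whole.set_index("model")
        assert whole.loc["max_overall", "mass_kg"] >= whole.loc["max_cranial", "mass_kg"]
        assert whole.loc["max_cranial", "mass_kg"] >= whole.loc["min_overall", "mass_kg"]
        assert whole.loc["max_caudal", "mass_kg"] >= whole.loc["min_overall", "mass_kg"]
        # CoM envelope: cranial model bounds the mean which bounds the caudal
        assert (
            whole.loc["max_cranial", "x_cm"]
            >= whole.loc["mean", "x_cm"]
            >= whole.loc["max_caudal", "x_cm"]
        )
        # bilaterally mirrored body: whole-body y is exactly zero
        assert (whole["y_cm"] == 0.0).all()

    def test_head_held_single(self, toy_body):
        report = sensitivity_report(toy_body.segments)
        head_rows = report.segments.query("region == 'head'")
        assert list(head_rows.variant) == ["single"]

    def test_symmetric_prism_matches_segment_mass_properties(self):
        seg = _prism(a=1.0, b=1.0, length=2.0, region="trunk")
        report = sensitivity_report([seg])
        mx = apply_variant(seg, OutlineVariant(), "max")
        expect = segment_mass_properties(mx)
        row = report.segments.query("variant == 'max'").iloc[0]
        assert row.mass_kg == pytest.approx(expect.mass, rel=1e-12)
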