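"""Motor fields, discrepancies, and symmetry dipoles against independent oracles."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ductiometry import (
    DuctionSet,
    DuctionVector,
    build_cohort_reports,
    build_index_report,
    discrepancy,
    gaze_difference,
    motor_field,
    muscle_bias,
    muscle_difference,
    normalize_motor_fields,
)
from ductiometry.directions import GAZE_LABELS, MIRROR_LABEL, NOMINAL_DIRECTION_DEG
from ductiometry.indices import discrepancy_from_polygons, motor_field_polygon


def make_set(magnitudes, directions=None, pid="P1", eye="OD"):
    """Build a DuctionSet from per-label magnitudes (and optional directions)."""
    vectors = {}
    for i, label in enumerate(GAZE_LABELS):
        mag = magnitudes[i] if not isinstance(magnitudes, dict) else magnitudes[label]
        if directions is None:
            d = NOMINAL_DIRECTION_DEG[label]
        elif isinstance(directions, dict):
            d = directions[label]
        else:
            d = directions[i]
        vectors[label] = DuctionVector(mag, d, label=label, eye=eye)
    return DuctionSet(pid, eye, vectors)


def mirror_set(od, pid="P1"):
    """The left-eye set that mirrors an OD set about the vertical axis."""
    vectors = {}
    for label in GAZE_LABELS:
        src = od.vectors[MIRROR_LABEL[label]]
        direction = (180.0 - src.direction_deg) % 360.0
        vectors[label] = DuctionVector(src.magnitude_deg, direction, label=label, eye="OS")
    return DuctionSet(pid, "OS", vectors)


def shoelace(tips):
    x, y = np.asarray(tips).T
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def clip_convex(subject, clip):
    """Sutherland-Hodgman intersection of a polygon with a convex clip polygon."""
    output = [tuple(p) for p in subject]
    n = len(clip)
    for i in range(n):
        a, b = np.asarray(clip[i]), np.asarray(clip[(i + 1) % n])
        edge = b - a

        def inside(p):
            return edge[0] * (p[1] - a[1]) - edge[1] * (p[0] - a[0]) >= 0

        def intersect(p, q):
            p, q = np.asarray(p), np.asarray(q)
            d = q - p
            denom = edge[0] * d[1] - edge[1] * d[0]
            t = (edge[0] * (a[1] - p[1]) - edge[1] * (a[0] - p[0])) / denom
            return tuple(p + t * d)

        polygon, output = output, []
        for j, q in enumerate(polygon):
            p = polygon[j - 1]
            if inside(q):
                if not inside(p):
                    output.append(intersect(p, q))
                output.append(q)
            elif inside(p):
                output.append(intersect(p, q))
        if not output:
            return []
    return output


class TestMotorField:
    def test_regular_octagon_closed_form(self):
        # a regular octagon of circumradius r has area 2*sqrt(2)*r^2
        s = make_set([40.0] * 8)
        assert motor_field(s) == pytest.approx(2 * math.sqrt(2) * 40.0**2, rel=1e-12)

    def test_area_scales_quadratically(self):
        base = motor_field(make_set([40.0] * 8))
        doubled = motor_field(make_set([80.0] * 8))
        assert doubled == pytest.approx(4 * base, rel=1e-12)

    def test_matches_shoelace_oracle_on_random_octagons(self, rng):
        nominal = np.array([NOMINAL_DIRECTION_DEG[l] for l in GAZE_LABELS])
        for _ in range(1000):
            mags = rng.uniform(5.0, 60.0, 8)
            dirs = nominal + rng.uniform(-20.0, 20.0, 8)
            s = make_set(list(mags), list(dirs))
            assert motor_field(s) == pytest.approx(
                shoelace(motor_field_polygon(s)), abs=1e-9
            )

    def test_collinear_tips_rejected(self):
        s = make_set([10.0] * 8, [0.0, 0.0, 0.0, 0.0, 180.0, 180.0, 180.0, 180.0])
        with pytest.raises(ValueError, match="degenerate"):
            motor_field(s)


class TestNormalization:
    def test_homogeneous_cohort_normalizes_to_one(self):
        assert np.allclose(normalize_motor_fields([4500.0] * 6), 1.0)

    def test_two_participant_example(self):
        assert np.allclose(normalize_motor_fields([3000.0, 5000.0]), [0.75, 1.25])

    @given(st.lists(st.floats(min_value=100.0, max_value=9000.0), min_size=1, max_size=30))
    def test_cohort_mean_is_exactly_one(self, areas):
        assert normalize_motor_fields(areas).mean() == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_areas_rejected(self):
        with pytest.raises(ValueError):
            normalize_motor_fields([1000.0, 0.0])


class TestDiscrepancy:
    def test_identical_sets_have_zero_discrepancy(self):
        od = make_set([40, 35, 31, 38, 46, 42, 42, 40])
        os_ = mirror_set(od)
        assert discrepancy(od, os_, "motor").value == pytest.approx(0.0, abs=1e-12)
        # gaze comparison of a mirror-symmetric-but-anisotropic pattern
        # is NOT zero; use a fully symmetric pattern for the gaze case
        sym = make_set([40.0] * 8)
        sym_os = mirror_set(sym)
        assert discrepancy(sym, sym_os, "gaze").value == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_polygons_have_discrepancy_one(self):
        a = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        b = a + [10.0, 0.0]
        assert discrepancy_from_polygons(a, b, "gaze").value == pytest.approx(1.0)

    def test_dented_octagon_matches_clipping_oracle(self):
        od = make_set([40.0] * 8)
        os_mags = [40.0] * 8
        os_mags[GAZE_LABELS.index("up")] = 20.0  # one vertex pulled inward
        os_ = make_set(os_mags, pid="P1", eye="OS")
        result = discrepancy(od, os_, "gaze")

        od_tips = motor_field_polygon(od)
        os_tips = motor_field_polygon(os_)
        inter = clip_convex(os_tips, od_tips)  # od is convex (regular octagon)
        a_od, a_os = shoelace(od_tips), shoelace(os_tips)
        expected = (a_od + a_os - 2 * shoelace(inter)) / (a_od + a_os)
        assert result.value == pytest.approx(expected, abs=1e-9)

    def test_motor_kind_reflects_left_eye_first(self):
        # an OD-only adduction deficit: after reflection the fields match
        mags = {l: 40.0 for l in GAZE_LABELS}
        mags["left"] = 15.0
        od = make_set(mags)
        os_mags = {l: 40.0 for l in GAZE_LABELS}
        os_mags["right"] = 15.0  # the OS mirror-matched duction
        os_ = make_set(os_mags, eye="OS")
        assert discrepancy(od, os_, "motor").value == pytest.approx(0.0, abs=1e-12)
        assert discrepancy(od, os_, "gaze").value > 0.05

    def test_monotone_as_vertex_shrinks(self):
        od = make_set([40.0] * 8)
        previous = 0.0
        for scale in (1.0, 0.8, 0.6, 0.4, 0.2):
            mags = [40.0] * 8
            mags[2] = 40.0 * scale
            os_ = make_set(mags, eye="OS")
            value = discrepancy(od, os_, "gaze").value
            assert value >= previous - 1e-12
            previous = value

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            od = make_set(list(rng.uniform(5, 60, 8)))
            os_ = make_set(list(rng.uniform(5, 60, 8)), eye="OS")
            for kind in ("motor", "gaze"):
                assert 0.0 <= discrepancy(od, os_, kind).value <= 1.0


class TestMuscleBias:
    def test_uniform_octagon_has_zero_bias(self):
        dip = muscle_bias(make_set([40.0] * 8))
        assert dip.magnitude == pytest.approx(0.0, abs=1e-12)
        assert dip.direction_deg is None

    def test_common_direction_has_unit_bias(self):
        s = make_set([40.0] * 8, [30.0] * 8)
        assert muscle_bias(s).magnitude == pytest.approx(1.0, abs=1e-12)

    def test_downward_strengthening_points_down(self):
        # the two downward-quadrant ductions at 50, the rest at 40
        mags = {l: 40.0 for l in GAZE_LABELS}
        mags["down_left"] = 50.0
        mags["down_right"] = 50.0
        dip = muscle_bias(make_set(mags))
        # hand vector-average of the normalized octagon
        vecs = []
        for label in GAZE_LABELS:
            a = math.radians(NOMINAL_DIRECTION_DEG[label])
            vecs.append(mags[label] / 50.0 * np.array([math.cos(a), math.sin(a)]))
        expected = np.mean(vecs, axis=0)
        assert dip.direction_deg == pytest.approx(270.0, abs=1e-9)
        assert dip.magnitude == pytest.approx(np.linalg.norm(expected), abs=1e-12)

    def test_scale_invariance(self):
        mags = [40, 35, 31, 38, 46, 42, 42, 40]
        a = muscle_bias(make_set(mags))
        b = muscle_bias(make_set([m * 1.7 for m in mags]))
        assert a.magnitude == pytest.approx(b.magnitude, abs=1e-12)
        assert a.direction_deg == pytest.approx(b.direction_deg, abs=1e-9)

    def test_all_zero_set_rejected(self):
        vectors = {
            l: DuctionVector(0.0, None, label=l, eye="OD") for l in GAZE_LABELS
        }
        s = DuctionSet("P1", "OD", vectors)
        with pytest.raises(ValueError):
            muscle_bias(s)


class TestDifferenceDipoles:
    def test_perfect_mirror_gives_zero_muscle_difference(self):
        od = make_set([40, 35, 31, 38, 46, 42, 42, 40])
        dip = muscle_difference(od, mirror_set(od))
        assert dip.magnitude == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(dip.anti, -dip.pro)

    def test_identical_eyes_give_zero_gaze_difference(self):
        od = make_set([40, 35, 31, 38, 46, 42, 42, 40])
        os_ = make_set([40, 35, 31, 38, 46, 42, 42, 40], eye="OS")
        assert gaze_difference(od, os_).magnitude == pytest.approx(0.0, abs=1e-12)

    def test_adduction_only_difference_is_horizontal(self):
        od = make_set([40.0] * 8)
        os_mags = {l: 40.0 for l in GAZE_LABELS}
        os_mags["right"] = 30.0  # OS adduction deficit (mirror pair of OD "left")
        os_ = make_set(os_mags, eye="OS")
        dip = muscle_difference(od, os_)
        assert dip.magnitude > 0
        assert dip.direction_deg in (pytest.approx(0.0, abs=1e-9), pytest.approx(180.0, abs=1e-9))

    def test_single_gaze_discrepancy_is_horizontal(self):
        od = make_set([40.0] * 8)
        os_mags = {l: 40.0 for l in GAZE_LABELS}
        os_mags["left"] = 25.0
        os_ = make_set(os_mags, eye="OS")
        dip = gaze_difference(od, os_)
        assert dip.direction_deg in (pytest.approx(0.0, abs=1e-9), pytest.approx(180.0, abs=1e-9))

    def test_magnitude_invariant_to_common_scaling(self):
        od = make_set([40, 35, 31, 38, 46, 42, 42, 40])
        os_ = make_set([38, 36, 30, 39, 44, 43, 41, 40], eye="OS")
        a = muscle_difference(od, os_)
        od2 = make_set([m * 1.5 for m in [40, 35, 31, 38, 46, 42, 42, 40]])
        os2 = make_set([m * 1.5 for m in [38, 36, 30, 39, 44, 43, 41, 40]], eye="OS")
        b = muscle_difference(od2, os2)
        assert a.magnitude == pytest.approx(b.magnitude, abs=1e-12)
        # the raw difference scale is NOT invariant: it carries the units
        assert b.mean_raw_norm == pytest.approx(1.5 * a.mean_raw_norm, abs=1e-9)

    @given(
        st.lists(st.floats(min_value=5.0, max_value=60.0), min_size=16, max_size=16),
    )
    def test_anti_is_always_negated_pro(self, mags):
        od = make_set(mags[:8])
        os_ = make_set(mags[8:], eye="OS")
        for dip in (
            muscle_bias(od),
            muscle_bias(os_),
            muscle_difference(od, os_),
            gaze_difference(od, os_),
        ):
            assert np.allclose(dip.anti, -dip.pro, atol=0)
            assert 0.0 <= dip.magnitude <= 1.0 + 1e-12


class TestIndexReport:
    def test_homogeneous_symmetric_cohort(self):
        pairs = []
        for pid in ("P1", "P2", "P3"):
            od = make_set([40.0] * 8, pid=pid)
            os_ = make_set([40.0] * 8, pid=pid, eye="OS")
            pairs.append((od, os_))
        reports = build_cohort_reports(pairs)
        for r in reports:
            assert r.mf_od.normalized == pytest.approx(1.0, abs=1e-12)
            assert r.mf_os.normalized == pytest.approx(1.0, abs=1e-12)
            assert r.mdisc.value == pytest.approx(0.0, abs=1e-12)
            assert r.gdisc.value == pytest.approx(0.0, abs=1e-12)
            for dip in (r.mb_od, r.mb_os, r.mdiff, r.gdiff):
                assert dip.magnitude == pytest.approx(0.0, abs=1e-12)

    def test_report_round_trips_through_json(self):
        od = make_set([40, 35, 31, 38, 46, 42, 42, 40])
        os_ = make_set([38, 36, 30, 39, 44, 43, 41, 40], eye="OS")
        report = build_index_report(od, os_, {"OD": 4500.0, "OS": 4500.0})
        restored = json.loads(report.to_json())
        assert restored == report.to_dict()
        assert restored["MF_OD"]["raw_deg2"] == pytest.approx(motor_field(od))

    def test_cohort_normalized_means_are_one_per_eye(self, rng):
        pairs = []
        for i in range(8):
            od = make_set(list(rng.uniform(30, 50, 8)), pid=f"P{i}")
            os_ = make_set(list(rng.uniform(30, 50, 8)), pid=f"P{i}", eye="OS")
            pairs.append((od, os_))
        reports = build_cohort_reports(pairs)
        assert np.mean([r.mf_od.normalized for r in reports]) == pytest.approx(1.0, abs=1e-9)
        assert np.mean([r.mf_os.normalized for r in reports]) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_participants_rejected(self):
        od = make_set([40.0] * 8, pid="P1")
        os_ = make_set([40.0] * 8, pid="P2", eye="OS")
        with pytest.raises(ValueError):
            build_index_report(od, os_)
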