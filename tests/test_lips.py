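"""Lip boundary pipeline: strips, midline detection, corners, constrained fits."""

import numpy as np
import pytest

from anacurve import (LipConfig, PhantomSpec, curve_rms_distance,
                      detect_lip_points, make_lip_phantom, mouth_frame,
                      vertical_strips)
from anacurve.lips import Candidate, LipStripResult, resolve_multiple_candidates


def test_default_strip_count_and_geometry(lip_phantom):
    _, cloud, _, _ = lip_phantom
    frame = mouth_frame(cloud)
    strips = vertical_strips(cloud, LipConfig(), frame)
    assert len(strips) == 50
    # strips are parallel planes: all share the slab normal n1
    normals = np.array([s.frame.n2 for s in strips])
    assert np.abs(normals - normals[0]).max() < 1e-12
    # offsets more than 2*delta apart give disjoint strips
    offs = np.array([(s.frame.origin - frame.origin) @ frame.n1 for s in strips])
    assert np.all(np.diff(offs) > 0)


def test_mouth_frame_finds_the_long_axis(lip_phantom):
    _, cloud, _, _ = lip_phantom
    frame = mouth_frame(cloud)
    # the phantom's mouth axis is world x, vertical is y, normal is z
    assert abs(frame.n1 @ np.array([1.0, 0, 0])) > np.cos(np.deg2rad(5))
    assert frame.n2 @ np.array([0.0, 1, 0]) > 0.99
    assert frame.n3 @ np.array([0.0, 0, 1]) > 0.99


def test_lateral_strip_has_no_midline(lip_result):
    result, _ = lip_result
    lateral = [r for r in result.strip_results if abs(r.offset) > 40]
    assert lateral and all(not r.has_midline for r in lateral)
    # and candidates are only present where a midline was detected
    for r in result.strip_results:
        if not r.has_midline:
            assert not r.upper and not r.lower


def test_central_strip_detects_all_three_features(lip_result, lip_phantom):
    result, truth = lip_result
    _, _, _, _ = lip_phantom
    central = min((r for r in result.strip_results if r.has_midline),
                  key=lambda r: abs(r.offset))
    assert abs(central.offset) < 2.0
    mid_true = truth.curves["midline"]
    d = np.linalg.norm(mid_true - central.midline_point, axis=1).min()
    assert d < 1.0
    assert len(central.upper) >= 1 and len(central.lower) >= 1
    up_d = np.linalg.norm(truth.curves["upper"] - central.upper[0].point,
                          axis=1).min()
    lo_d = np.linalg.norm(truth.curves["lower"] - central.lower[-1].point,
                          axis=1).min()
    assert up_d < 1.5 and lo_d < 1.5


def _strip_result(index, offset, cands):
    r = LipStripResult(index, offset, None, None)
    r.midline_point = np.array([offset, 0.0, 0.0])
    r.midline_s = 0.0
    r.upper = cands
    return r


def test_resolver_passes_single_candidates_through():
    results = [
        _strip_result(i, float(i), [Candidate(1.0, np.array([float(i), 1.0, 0.0]), 0.1)])
        for i in range(8)
    ]
    out = resolve_multiple_candidates(results, "upper")
    assert all(o is results[i].upper[0] for i, o in enumerate(out))


def test_resolver_prefers_candidate_near_preliminary(lip_result):
    result, _ = lip_result
    rs = [r for r in result.strip_results if r.has_midline and len(r.upper) == 1]
    assert len(rs) >= 6
    victim = rs[len(rs) // 2]
    true_cand = victim.upper[0]
    spurious = Candidate(true_cand.s + 8.0,
                         true_cand.point + np.array([0.0, 8.0, 0.0]), 0.5)
    victim.upper = [true_cand, spurious]
    try:
        out = resolve_multiple_candidates(result.strip_results, "upper")
        assert out[victim.index] is true_cand
    finally:
        victim.upper = [true_cand]


def test_resolver_tie_breaks_to_smaller_arc_length():
    from anacurve.lips import select_nearest_candidate

    tie = [Candidate(0.0, np.array([4.0, 1.0, 0.0]), 0.1),
           Candidate(2.0, np.array([4.0, 1.0, 0.0]), 0.1)]
    assert select_nearest_candidate(tie, 1.0) is tie[0]
    assert select_nearest_candidate(tie, 1.6) is tie[1]


def test_corners_near_truth_and_symmetric(lip_result):
    result, truth = lip_result
    corners = result.curves.corners
    errs = [min(np.linalg.norm(corners[i] - truth.corners[j])
                for j in range(2)) for i in range(2)]
    assert max(errs) < 1.5
    # mirror symmetry of the phantom: corner x locations match in magnitude
    # (each corner is detected independently, so allow detection jitter)
    assert abs(abs(corners[0][0]) - abs(corners[1][0])) < 1.5


def test_boundaries_pass_exactly_through_corners(lip_result):
    result, _ = lip_result
    c = result.curves
    for name in ("upper", "lower", "midline"):
        ends = np.vstack([c.as_dict()[name][0], c.as_dict()[name][-1]])
        assert np.abs(ends - c.corners).max() < 1e-6


def test_curves_recover_truth_to_about_a_millimetre(lip_result):
    result, truth = lip_result
    rms = {name: curve_rms_distance(result.curves.as_dict()[name],
                                    truth.curves[name])[0]
           for name in ("upper", "midline", "lower")}
    assert rms["midline"] < 1.0
    assert rms["upper"] < 1.2
    assert rms["lower"] < 1.2


def test_notch_is_preserved_by_the_constrained_fit():
    # the shape penalties cover only the first and last 40% of arc length, so
    # a central notch in upper-lip-shaped data must survive the heavily
    # parameterised (25 df) corner-constrained fit
    from anacurve.pspline import (EqualityConstraint, ShapeConstraintSpec,
                                  fit_shape_constrained)

    s = np.linspace(0.0, 60.0, 48)
    bow = 10.0 * np.sin(np.pi * s / 60.0)
    notch = 1.5 * np.exp(-((s - 30.0) ** 2) / (2 * 3.0 ** 2))
    x = bow - notch
    con = EqualityConstraint(np.array([0.0, 60.0]), np.array([0.0, 0.0]))
    model = fit_shape_constrained(s, x, nbasis=30, df=25.0, constraint=con,
                                  shapes=ShapeConstraintSpec.upper_lip())
    y_mid = model(np.array([30.0]))[0]
    y_shoulders = model(np.array([22.0, 38.0]))
    fitted_dip = 0.5 * (y_shoulders[0] + y_shoulders[1]) - y_mid
    data_dip = 0.5 * (x[np.argmin(np.abs(s - 22.0))] +
                      x[np.argmin(np.abs(s - 38.0))]) - x[np.argmin(np.abs(s - 30.0))]
    assert fitted_dip > 0.7 * data_dip


def test_pipeline_is_deterministic(lip_phantom):
    from anacurve import estimate_lip_boundaries
    _, cloud, _, _ = lip_phantom
    a = estimate_lip_boundaries(cloud, LipConfig())
    b = estimate_lip_boundaries(cloud, LipConfig())
    assert np.array_equal(a.curves.upper, b.curves.upper)
    assert np.array_equal(a.curves.corners, b.curves.corners)


def test_detect_lip_points_handles_empty_strip(lip_phantom):
    _, cloud, _, _ = lip_phantom
    frame = mouth_frame(cloud)
    strips = vertical_strips(cloud, LipConfig(), frame)
    # an artificial strip with too few points yields an empty result
    from anacurve.frames import TransectStrip

    tiny = TransectStrip(strips[0].points[:5], strips[0].frame,
                         strips[0].abscissa[:5], strips[0].ordinate[:5],
                         strips[0].delta)
    r = detect_lip_points(tiny, LipConfig())
    assert not r.has_midline and not r.upper and not r.lower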