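"""Breast boundary pipeline: transects, screening rules, gaps, boundary fit."""

import numpy as np
import pytest

from anacurve import (BreastConfig, LandmarkSet, fit_boundary,
                      interpolate_gaps, radial_transects)
from anacurve.breast import RadialCandidate, filter_candidates


def test_default_transect_count(breast_result):
    result, _, _ = breast_result
    assert len(result.strips) == 51


def test_no_strip_crosses_the_midline_plane(breast_result, torso_phantom):
    result, lms, _ = breast_result
    # the ssn--xipho plane here is x = 0; the right breast's strips must stay
    # on the positive side
    for strip in result.strips:
        if len(strip):
            assert strip.points[:, 0].min() > -1e-9


def test_length_rule_caps_strip_extent(torso_phantom):
    from anacurve import candidate_boundary_points, side_landmarks
    _, cloud, landmarks, _ = torso_phantom
    lms = side_landmarks(landmarks, "r")
    config = BreastConfig(n_transects=12)
    strips = radial_transects(cloud, lms, config)
    cands = candidate_boundary_points(strips, config)
    arcs = [max(c.arc_length for c in cl) if cl else None for cl in cands]
    for i in range(2, len(arcs)):
        prev = [a for a in arcs[i - 2:i] if a is not None]
        if len(prev) == 2 and arcs[i] is not None:
            assert arcs[i] <= 1.5 * max(prev) + 15.0  # slack: cap precedes refit


def make_filter_fixture():
    """Hand-built landmark geometry for the exclusion rules."""
    prom = np.array([0.0, 0.0, 50.0])
    med = np.array([-50.0, 0.0, 10.0])
    lat = np.array([52.0, 0.0, 10.0])
    inf_ = np.array([0.0, -50.0, 10.0])
    ssn = np.array([0.0, 120.0, 10.0])
    xipho = np.array([0.0, -45.0, 10.0])
    lms = LandmarkSet(["prom", "med", "lat", "inf", "ssn", "xipho"],
                      np.vstack([prom, med, lat, inf_, ssn, xipho]))
    # a flat cloud so the surface normals at ssn/xipho are +z
    rng = np.random.default_rng(0)
    xy = rng.uniform(-80, 130, (4000, 2))
    from anacurve import SurfacePointCloud

    cloud = SurfacePointCloud(np.column_stack(
        [xy[:, 0], xy[:, 1], 10.0 + 0.001 * rng.standard_normal(4000)]))
    return cloud, lms


def run_filter(point):
    cloud, lms = make_filter_fixture()
    cand = RadialCandidate(0, 0.0, np.asarray(point, dtype=float), 10.0, 0.2)
    filter_candidates([[cand]], cloud, lms, BreastConfig())
    return cand


def test_rule_a_excludes_points_too_close_to_prom():
    cand = run_filter([0.0, 0.0 + 0.5 * 50.0 * 0.0, 50.0 - 25.0])
    # ||c - prom|| = 25 = 0.5 * min distance -> excluded by (a)
    assert not cand.retained and cand.excluded_by == "a"


def test_rule_b_excludes_excess_protrusion():
    # 20 mm above the med/lat protrusion band (z = 10 +- 10 allowance)
    cand = run_filter([-50.0, 0.0, 10.0 + 20.0 + 1e-6])
    assert not cand.retained and cand.excluded_by == "b"


def test_rule_c_excludes_points_above_ssn():
    cand = run_filter([-30.0, 125.0, 10.0])
    assert not cand.retained and cand.excluded_by == "c"


def test_candidate_at_med_is_retained():
    cand = run_filter([-50.0, 0.0, 10.0])
    assert cand.retained


def test_missing_landmark_is_a_named_error():
    cloud, lms = make_filter_fixture()
    broken = LandmarkSet([n for n in lms.names if n != "inf"],
                         np.array([lms[n] for n in lms.names if n != "inf"]))
    with pytest.raises(KeyError, match="inf"):
        filter_candidates([[]], cloud, broken, BreastConfig())


def test_gap_interpolation_midpoint_and_weights():
    k = 51
    angles = np.array([2 * np.pi * i / k for i in range(k)])
    truth = np.column_stack([60 * np.cos(angles), 60 * np.sin(angles),
                             np.zeros(k)])
    per = [None if i in (5, 6, 7) else truth[i] for i in range(k)]
    pts, interp = interpolate_gaps(per, angles)
    assert interp.sum() == 3
    # side-curve extension is linear, so a three-transect gap on a 60 mm
    # circle is recovered to a couple of millimetres
    assert np.abs(pts[[5, 6, 7]] - truth[[5, 6, 7]]).max() < 2.0
    # weights sum to one for every gap position
    for l in range(1, 6):
        for i in range(1, l + 1):
            assert np.isclose((l + 1 - i) / (l + 1) + i / (l + 1), 1.0)


def test_single_gap_is_average_of_side_predictions():
    k = 51
    angles = np.array([2 * np.pi * i / k for i in range(k)])
    truth = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(k)]) * 40
    per = [None if i == 25 else truth[i] for i in range(k)]
    pts, interp = interpolate_gaps(per, angles)
    assert interp[25]
    assert np.linalg.norm(pts[25] - truth[25]) < 1.0


def test_gap_spanning_half_the_transects_is_rejected():
    k = 16
    angles = np.array([2 * np.pi * i / k for i in range(k)])
    per = [None] * 9 + [np.array([1.0, 0, 0])] * 7
    with pytest.raises(ValueError, match="half"):
        interpolate_gaps(per, angles)


def test_boundary_fit_on_a_perfect_circle():
    k = 40
    angles = np.array([2 * np.pi * i / k for i in range(k)])
    pts = np.column_stack([55 * np.cos(angles), 55 * np.sin(angles),
                           np.full(k, 3.0)])
    boundary = fit_boundary(pts, angles)
    r = np.linalg.norm(boundary.curve_points[:, :2], axis=1)
    # 12 df over the full circle leaves a small smoothing bias (~1% of the
    # radius) but no structure
    assert np.abs(r - 55).max() < 0.7
    assert boundary.closure_gap < 1.0


def test_boundary_fit_rejects_sparse_input():
    angles = np.array([0.0, 0.1, 0.2, 3.0])
    with pytest.raises(ValueError):
        fit_boundary(np.zeros((4, 3)), angles)


def test_pipeline_is_deterministic(torso_phantom):
    from anacurve import estimate_breast_boundary, side_landmarks
    _, cloud, landmarks, _ = torso_phantom
    lms = side_landmarks(landmarks, "l")
    cfg = BreastConfig(n_transects=17)
    a = estimate_breast_boundary(cloud, lms, cfg)
    b = estimate_breast_boundary(cloud, lms, cfg)
    assert np.array_equal(a.boundary.curve_points, b.boundary.curve_points)


def test_recovered_boundary_tracks_the_truth(breast_result):
    result, _, truth = breast_result
    d = np.array([np.linalg.norm(truth.curves["r"] - p, axis=1).min()
                  for p in result.boundary.curve_points])
    assert d.max() < 2.0
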