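"""Synthetic surface generators: determinism, counts, truth consistency, noise."""

import numpy as np
import pytest

from anacurve import (PhantomSpec, add_surface_noise, make_lip_phantom,
                      make_torso_phantom, side_landmarks)


def test_same_seed_is_bit_identical():
    a, _, _ = make_torso_phantom(PhantomSpec.torso(seed=5))
    b, _, _ = make_torso_phantom(PhantomSpec.torso(seed=5))
    assert np.array_equal(a.points, b.points)
    c, _, _ = make_lip_phantom(PhantomSpec.lip(seed=5))
    d, _, _ = make_lip_phantom(PhantomSpec.lip(seed=5))
    assert np.array_equal(c.points, d.points)


def test_torso_point_count_near_thirty_thousand(torso_phantom):
    _, cloud, _, _ = torso_phantom
    assert abs(len(cloud) - 30_000) / 30_000 < 0.20


def test_lip_high_density_count_near_150k():
    cloud, _, _ = make_lip_phantom(PhantomSpec.lip(high_density=True))
    assert abs(len(cloud) - 150_000) / 150_000 < 0.20


def test_invalid_spec_names_the_offending_field():
    with pytest.raises(ValueError, match="breast_radius"):
        PhantomSpec.torso(breast_radius=-1.0)
    with pytest.raises(ValueError, match="noise_sd"):
        PhantomSpec.lip(noise_sd=-0.1)
    with pytest.raises(ValueError, match="kind"):
        PhantomSpec(kind="arm")


def test_landmarks_lie_on_the_sampled_surface(torso_phantom):
    _, cloud, landmarks, _ = torso_phantom
    spacing = cloud.mean_spacing()
    # distance to the local tangent plane of the sampled surface
    for p in landmarks.points:
        _, idx = cloud.tree.query(p, k=12)
        nb = cloud.points[idx]
        centred = nb - nb.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        assert abs((p - nb.mean(axis=0)) @ vt[2]) < 0.5 * spacing


def test_truth_boundary_interleaves_the_cloud(torso_phantom):
    _, cloud, _, truth = torso_phantom
    spacing = cloud.mean_spacing()
    for side in ("l", "r"):
        d, _ = cloud.tree.query(truth.curves[side])
        assert d.max() < 2 * spacing


def test_transect_curvature_peaks_near_true_boundary(torso_phantom, breast_result):
    # the usability property behind the whole pipeline: a radial transect's
    # curvature maximum falls close to the true junction circle
    _, _, truth = breast_result
    result, _, _ = breast_result
    errors = []
    for cands in result.candidates:
        for c in cands:
            if c.retained:
                errors.append(np.linalg.norm(truth.curves["r"] - c.point,
                                             axis=1).min())
    errors = np.asarray(errors)
    assert np.median(errors) < 2.0


def test_lip_truth_has_three_curves_meeting_at_corners(lip_phantom):
    _, _, _, truth = lip_phantom
    assert set(truth.curves) == {"upper", "midline", "lower"}
    for name, curve in truth.curves.items():
        assert np.allclose(curve[0], truth.corners[0], atol=1e-9)
        assert np.allclose(curve[-1], truth.corners[1], atol=1e-9)


def test_symmetric_spec_gives_mirror_symmetric_corners(lip_phantom):
    _, _, _, truth = lip_phantom
    left, right = truth.corners
    assert abs(left[0] + right[0]) < 1e-6
    assert abs(left[1] - right[1]) < 1e-6
    assert abs(left[2] - right[2]) < 1e-6


def test_zero_ridge_height_flags_curves_absent():
    _, _, truth = make_lip_phantom(PhantomSpec.lip(ridge_height=0.0,
                                                   lower_ridge_height=0.0))
    assert truth.curves["upper"] is None
    assert truth.curves["lower"] is None
    assert truth.curves["midline"] is not None


def test_side_landmarks_picks_one_breast(torso_phantom):
    _, _, landmarks, _ = torso_phantom
    lms = side_landmarks(landmarks, "r")
    assert lms.names == ["prom", "med", "lat", "inf", "ssn", "xipho"]
    assert lms["prom"][0] > 0  # right side has positive x


def test_noise_free_call_is_identity(torso_phantom):
    _, cloud, _, _ = torso_phantom
    out = add_surface_noise(cloud, sd=0.0, orange_peel_amplitude=0.0)
    assert out is cloud


def test_iid_noise_magnitude(torso_phantom):
    _, cloud, _, _ = torso_phantom
    noisy = add_surface_noise(cloud, sd=0.3, seed=11)
    disp = np.linalg.norm(noisy.points - cloud.points, axis=1)
    assert abs(disp.std() - 0.3) / 0.3 < 0.05 or abs(
        np.sqrt(np.mean(disp ** 2)) - 0.3) / 0.3 < 0.05


def test_negative_noise_rejected(torso_phantom):
    _, cloud, _, _ = torso_phantom
    with pytest.raises(ValueError):
        add_surface_noise(cloud, sd=-0.1)


def test_orange_peel_correlation_length(lip_phantom):
    _, cloud, _, _ = lip_phantom
    target = 8.0
    noisy = add_surface_noise(cloud, sd=0.0, orange_peel_amplitude=0.5,
                              correlation_length=target, seed=3)
    disp = np.einsum("ij,ij->i", noisy.points - cloud.points,
                     noisy.points - cloud.points) ** 0.5
    signed = (noisy.points - cloud.points)[:, 2]  # mostly normal ~ +z here
    # empirical correlogram over point pairs binned by distance
    rng = np.random.default_rng(0)
    idx = rng.choice(len(cloud), 4000, replace=False)
    p = cloud.points[idx, :2]
    v = signed[idx] - signed[idx].mean()
    d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2).ravel()
    prod = np.outer(v, v).ravel()
    bins = np.linspace(0.5, 20, 30)
    which = np.digitize(d, bins)
    corr = np.array([prod[which == i].mean() for i in range(1, len(bins))])
    corr /= v.var()
    centres = 0.5 * (bins[:-1] + bins[1:])
    below = np.nonzero(corr < np.exp(-1.0))[0]
    assert len(below) > 0
    est = centres[below[0]]
    assert abs(est - target) / target < 0.25
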