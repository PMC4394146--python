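"""Procrustes superimposition, shape PCA and paired score comparison."""

import numpy as np
import pytest

from anacurve import (ShapeSample, paired_score_test, procrustes_distance,
                      shape_at_score, shape_pca, superimpose)


def base_config(rng, n_points=40):
    return rng.standard_normal((n_points, 3)) * np.array([10.0, 6.0, 2.0])


def rigid(config, rng):
    th = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    return config @ R.T + rng.uniform(-20, 20, 3)


def test_identical_configurations_have_zero_distance(rng):
    A = base_config(rng)
    assert procrustes_distance(A, A.copy()) < 1e-10


def test_rigid_motion_has_zero_distance(rng):
    A = base_config(rng)
    assert procrustes_distance(A, rigid(A, rng)) < 1e-9


def test_alignment_mean_is_a_fixed_point(rng):
    sample = ShapeSample(np.stack([rigid(base_config(rng), rng) for _ in range(6)]))
    aligned = superimpose(sample)
    X = aligned.configurations
    mean = X.mean(axis=0)
    # rotating any aligned configuration onto the mean changes nothing
    from anacurve.shape import _optimal_rotation

    for i in range(len(X)):
        Xi = X[i] - X[i].mean(axis=0)
        R = _optimal_rotation(Xi, mean - mean.mean(axis=0))
        assert np.abs(Xi @ R - Xi).max() < 1e-6


def test_centroid_sizes_preserved_without_scaling(rng):
    sample = ShapeSample(np.stack([base_config(rng) * s for s in (1.0, 1.5, 0.7)]))
    sizes_before = sample.centroid_sizes()
    aligned = superimpose(sample, remove_scale=False)
    assert np.allclose(aligned.centroid_sizes(), sizes_before)
    unit = superimpose(sample, remove_scale=True)
    assert np.allclose(unit.centroid_sizes(), 1.0)


def test_degenerate_configuration_rejected():
    flat = np.zeros((2, 10, 3))
    with pytest.raises(ValueError):
        superimpose(ShapeSample(flat))


def orthogonalise_mode(mode, base):
    """Remove the translation/rotation components of a deformation mode so it
    survives Procrustes alignment intact."""
    directions = []
    for k in range(3):
        e = np.zeros_like(mode)
        e[:, k] = 1.0
        directions.append(e.ravel())
    gens = [np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]]),
            np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]]),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]])]
    centred = base - base.mean(axis=0)
    for J in gens:
        directions.append((centred @ J.T).ravel())
    v = mode.ravel().copy()
    basis, _ = np.linalg.qr(np.column_stack(directions))
    v = v - basis @ (basis.T @ v)
    v /= np.linalg.norm(v)
    return v.reshape(mode.shape)


def planted_sample(rng, n=12, n_points=50):
    base = base_config(rng, n_points)
    mode = orthogonalise_mode(rng.standard_normal((n_points, 3)), base)
    scores = rng.standard_normal(n) * 3.0
    configs = np.stack([base + s * mode + 0.01 * rng.standard_normal((n_points, 3))
                        for s in scores])
    return configs, mode


def test_variance_is_conserved(rng):
    configs, _ = planted_sample(rng)
    aligned = superimpose(ShapeSample(configs))
    model = shape_pca(aligned)
    X = aligned.configurations.reshape(len(configs), -1)
    total = ((X - X.mean(axis=0)) ** 2).sum() / (len(configs) - 1)
    assert abs(model.variances.sum() - total) < 1e-8 * max(total, 1.0)


def test_planted_mode_is_recovered(rng):
    configs, mode = planted_sample(rng)
    model = shape_pca(superimpose(ShapeSample(configs)))
    corr = np.corrcoef(model.loadings[0], mode.ravel())[0, 1]
    assert abs(corr) > 0.99


def test_reconstruction_at_zero_scores_is_the_mean(rng):
    configs, _ = planted_sample(rng)
    model = shape_pca(superimpose(ShapeSample(configs)))
    assert np.allclose(model.reconstruct([]), model.mean)


def test_plus_minus_two_sd_shapes_are_symmetric_about_the_mean(rng):
    configs, _ = planted_sample(rng)
    model = shape_pca(superimpose(ShapeSample(configs)))
    plus = shape_at_score(model, 0, 2.0)
    minus = shape_at_score(model, 0, -2.0)
    assert np.allclose(0.5 * (plus + minus), model.mean, atol=1e-10)


def test_returned_shape_scores_as_requested(rng):
    configs, _ = planted_sample(rng)
    model = shape_pca(superimpose(ShapeSample(configs)))
    shape = shape_at_score(model, 1, 1.7)
    score = (shape.ravel() - model.mean.ravel()) @ model.loadings[1]
    assert abs(score - 1.7 * np.sqrt(model.variances[1])) < 1e-8


def test_scores_invariant_to_specimen_order(rng):
    configs, _ = planted_sample(rng, n=8)
    aligned = superimpose(ShapeSample(configs))
    model = shape_pca(aligned)
    perm = np.arange(8)[::-1]
    aligned_p = ShapeSample(aligned.configurations[perm],
                            [aligned.specimen_ids[i] for i in perm])
    model_p = shape_pca(aligned_p)
    assert np.allclose(np.abs(model_p.scores[::-1, :3]),
                       np.abs(model.scores[:, :3]), atol=1e-6)


def test_paired_test_on_identical_pairs_is_exactly_null(rng):
    configs, _ = planted_sample(rng, n=6)
    doubled = np.concatenate([configs, configs])
    ids = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    model = shape_pca(superimpose(ShapeSample(doubled, ids)))
    out = paired_score_test(model, [(f"a{i}", f"b{i}") for i in range(6)])
    for comp in out:
        assert comp["mean_diff"] == pytest.approx(0.0, abs=1e-8)
        assert comp["t"] == pytest.approx(0.0, abs=1e-8)


def test_sign_flip_negates_the_statistic(rng):
    configs, _ = planted_sample(rng, n=8)
    model = shape_pca(superimpose(ShapeSample(configs)))
    pairs = [(i, i + 4) for i in range(4)]
    fwd = paired_score_test(model, pairs, n_components=1)[0]
    rev = paired_score_test(model, [(b, a) for a, b in pairs], n_components=1)[0]
    assert fwd["t"] == pytest.approx(-rev["t"])


def test_too_few_pairs_rejected(rng):
    configs, _ = planted_sample(rng, n=6)
    model = shape_pca(superimpose(ShapeSample(configs)))
    with pytest.raises(ValueError):
        paired_score_test(model, [(0, 1), (2, 3)])
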