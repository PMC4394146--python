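"""Statistical shape analysis of corresponded semi-landmark configurations.

Generalised Procrustes superimposition (translation and rotation, with
scaling optional -- by default size is retained, so the first principal
component may express size-related shape change), principal component
analysis of the aligned configurations, score-to-shape reconstruction, and
paired score comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ShapeSample", "ShapePCAModel", "superimpose", "shape_pca",
           "shape_at_score", "paired_score_test", "procrustes_distance"]


@dataclass
class ShapeSample:
    """Equal-length landmark configurations with optional group metadata."""

    configurations: np.ndarray          # (n_specimens, n_points, dim)
    specimen_ids: list[str] | None = None
    groups: list[str] | None = None

    def __post_init__(self):
        self.configurations = np.asarray(self.configurations, dtype=float)
        if self.configurations.ndim != 3:
            raise ValueError("configurations must be (n, points, dim)")
        n = len(self.configurations)
        if self.specimen_ids is None:
            self.specimen_ids = [f"spec{i}" for i in range(n)]
        if len(self.specimen_ids) != n:
            raise ValueError("specimen_ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.configurations)

    def centroid_sizes(self) -> np.ndarray:
        c = self.configurations - self.configurations.mean(axis=1, keepdims=True)
        return np.sqrt((c ** 2).sum(axis=(1, 2)))


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation (proper, via SVD with determinant correction) aligning
    centred ``src`` onto centred ``dst`` in least squares."""
    H = src.T @ dst
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(H.shape[0])
    D[-1, -1] = d
    return U @ D @ Vt


def superimpose(sample: ShapeSample, remove_scale: bool = False,
                max_iter: int = 500, tol: float = 1e-12) -> ShapeSample:
    """Generalised Procrustes alignment.

    Iterates rotation of every centred configuration onto the current mean
    until the mean stabilises.  With ``remove_scale`` each configuration is
    also scaled to unit centroid size (full similarity alignment); otherwise
    sizes are preserved exactly.
    """
    X = sample.configurations.copy()
    if sample.n < 2:
        raise ValueError("need at least two configurations")
    sizes = sample.centroid_sizes()
    if np.any(sizes < 1e-12):
        raise ValueError("degenerate configuration: all points coincide")
    X = X - X.mean(axis=1, keepdims=True)
    if remove_scale:
        X = X / sizes[:, None, None]
    mean = X[0]
    for _ in range(max_iter):
        for i in range(sample.n):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        if np.linalg.norm(new_mean - mean) < tol * max(np.linalg.norm(mean), 1.0):
            mean = new_mean
            break
        mean = new_mean
    return ShapeSample(X, list(sample.specimen_ids),
                       list(sample.groups) if sample.groups else None)


def procrustes_distance(a: np.ndarray, b: np.ndarray,
                        remove_scale: bool = False) -> float:
    """Root-sum-square distance between two configurations after optimal
    translation/rotation (and optional scaling) of ``a`` onto ``b``."""
    sample = superimpose(ShapeSample(np.stack([a, b])), remove_scale=remove_scale)
    A, B = sample.configurations
    return float(np.linalg.norm(A - B))


@dataclass
class ShapePCAModel:
    mean: np.ndarray                 # (points, dim)
    loadings: np.ndarray             # (n_components, points*dim), orthonormal rows
    scores: np.ndarray               # (n_specimens, n_components)
    variances: np.ndarray            # per-component variance of scores
    specimen_ids: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.variances)

    def reconstruct(self, score_vector) -> np.ndarray:
        v = np.zeros(self.loadings.shape[0])
        score_vector = np.atleast_1d(np.asarray(score_vector, dtype=float))
        v[: len(score_vector)] = score_vector
        flat = self.mean.ravel() + v @ self.loadings
        return flat.reshape(self.mean.shape)


def shape_pca(aligned: ShapeSample) -> ShapePCAModel:
    """Covariance PCA of the vectorised aligned configurations."""
    if aligned.n < 3:
        raise ValueError("need at least 3 specimens for a shape PCA")
    X = aligned.configurations.reshape(aligned.n, -1)
    mean = X.mean(axis=0)
    centred = X - mean
    U, svals, Vt = np.linalg.svd(centred, full_matrices=False)
    # fix loading signs so the largest-magnitude element of each is positive
    for j in range(len(svals)):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U * svals
    variances = svals ** 2 / (aligned.n - 1)
    nc = min(aligned.n - 1, X.shape[1])
    return ShapePCAModel(mean.reshape(aligned.configurations.shape[1:]),
                         Vt[:nc], scores[:, :nc], variances[:nc],
                         list(aligned.specimen_ids))


def shape_at_score(model: ShapePCAModel, component: int,
                   sd_multiple: float) -> np.ndarray:
    """Configuration at ``sd_multiple`` standard deviations along a component."""
    if not 0 <= component < model.n_components:
        raise ValueError(f"component {component} outside the model")
    v = np.zeros(model.n_components)
    v[component] = sd_multiple * np.sqrt(model.variances[component])
    return model.reconstruct(v)


def paired_score_test(model: ShapePCAModel, pairs: list[tuple],
                      n_components: int = 2):
    """Paired t-tests on within-pair PC-score differences.

    ``pairs`` holds (specimen_id_a, specimen_id_b) or index tuples.  Returns
    a list of dicts (per component) with the mean difference, its 95%
    confidence interval and the two-sided p-value.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    idx = {sid: i for i, sid in enumerate(model.specimen_ids)}

    def resolve(x):
        return idx[x] if isinstance(x, str) else int(x)

    a = np.array([resolve(p[0]) for p in pairs])
    b = np.array([resolve(p[1]) for p in pairs])
    out = []
    for j in range(min(n_components, model.n_components)):
        d = model.scores[a, j] - model.scores[b, j]
        n = len(d)
        mean = float(d.mean())
        # differences at numerical-noise level (identical pairs) are zero
        noise = 1e-9 * max(float(np.abs(model.scores[:, j]).max()), 1.0)
        if np.abs(d).max() < noise:
            d = np.zeros_like(d)
            mean = 0.0
        se = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        if se > 0:
            t = mean / se
            p = float(2 * stats.t.sf(abs(t), n - 1))
            half = float(stats.t.ppf(0.975, n - 1) * se)
        else:
            t, p, half = 0.0, 1.0, 0.0
        out.append({"component": j, "mean_diff": mean, "t": float(t),
                    "p_value": p, "ci95": (mean - half, mean + half)})
    return out
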