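# anacurve

Identification of anatomical boundary curves on 3-D surface point clouds,
and their use for statistical shape analysis.

Stereo-photogrammetry and laser scanning deliver anatomical surfaces as
dense, unstructured point sets (tens of thousands of 3-D points in mm, with
no anatomical labelling). Landmarks capture only a tiny part of that
information; anatomically defined *curves* — the boundary of a breast on the
chest wall, the three curves outlining closed lips — are far richer, and
once a boundary is known the enclosed surface can be regularised into
corresponded semi-landmarks for point-based shape statistics. `anacurve`
implements that programme for users working with torso and facial images:
clinical shape researchers, morphometricians, and anyone who needs
ridge/valley curves extracted from noisy surface scans with statistical
control over the evidence.

## The method

Navigation across the surface manifold uses **principal curves**: a curve
f(s) = {x(s), y(s)[, z(s)]}, indexed by arc length, is self-consistent when
every curve point is the mean of the observations projecting onto it,
E[P | s_f(P) = s] = f(s). Fitting alternates projection with per-coordinate
**P-spline** smoothing (B-spline basis, second-difference penalty λβᵀD₂ᵀD₂β),
with the flexibility fixed in effective degrees of freedom (the trace of the
smoother matrix).

* **Transects.** A local PCA frame (n₁, n₂, n₃) at a point of interest
  defines planar strips S = {pᵢ : |pᵢᵀn₂| ≤ δ}; each strip reduces the
  problem to a planar curve of depth against position.
* **Boundary evidence.** Along a transect curve, boundary points are
  curvature extrema, κ(s) = (x′y″ − x″y′)/(x′² + y′²)^{3/2}. For lips,
  where many transects do not cross the mouth at all, a crossing of the
  inter-lip valley is declared only when the standardised difference of
  one-sided first-derivative estimates,
  T(s) = (ẑₐ′(s) − ẑᵦ′(s)) / se, se² = (wₐ − wᵦ)ᵀ(wₐ − wᵦ)σ̂²,
  exceeds 5 in absolute value (σ̂ estimated by local differencing).
* **Boundary curves.** Breast: 51 radial transects from the most prominent
  point, landmark-based screening of candidates, gap interpolation from
  extended side curves, and a closed 12-df principal curve. Lips: 50
  vertical strips, mouth corners from the first and last strong curvature
  maxima of the 3-D midline curve, then 25-df P-spline fits per coordinate
  constrained exactly through the corners,
  β̂_c = β̂ + G⁻¹Aᵀ[AG⁻¹Aᵀ]⁻¹(c − Aβ̂) with G = BᵀB + λD₂ᵀD₂,
  plus monotonicity and second-derivative-trend penalties (κ = 100λ) over
  the first and last 40% of arc length.
* **Semi-landmarks and shape.** Breast surfaces become an apex + 51×20 grid
  (1021 points) spaced by normalised exponential quantiles along each
  transect; lip surfaces a width-adaptive grid between the boundary curves.
  Corresponded grids feed generalised Procrustes alignment, shape PCA and
  paired score tests.

Everything is testable without any data download: `anacurve.phantoms`
generates torso and lip surfaces with analytically known boundary curves,
landmarks and controllable noise.

## Worked example

```python
import numpy as np
from anacurve import (PhantomSpec, make_torso_phantom, side_landmarks,
                      estimate_breast_boundary)
from anacurve.semilandmarks import breast_grid

cloud, landmarks, truth = make_torso_phantom(PhantomSpec.torso(seed=0))
lms = side_landmarks(landmarks, "r")
result = estimate_breast_boundary(cloud, lms)
grid = breast_grid(result, lms, r=20)

err = np.array([np.linalg.norm(truth.curves["r"] - p, axis=1).min()
                for p in result.boundary.curve_points])
print(len(cloud), len(grid), round(err.max(), 2), round(err.mean(), 2))
```

prints

```
29870 1021 1.51 0.83
```

— a 29,870-point torso phantom, the 1021-point semi-landmark grid (apex plus
51 transects × 20 points), and a recovered boundary lying at most 1.51 mm
(mean 0.83 mm) from the true mound/chest junction circle.

The same pipelines are available from a shell:

```sh
anacurve phantom --kind torso --seed 0 --out ph
anacurve breast --cloud ph/surface.ply --landmarks ph/landmarks.csv --side r --out out
anacurve lips --cloud face.ply --out lips_out
```

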