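# Methods

This note documents the models implemented in `anacurve`, the defaults and
the reasoning behind choices the standard protocol leaves open, and what
the synthetic phantoms do and do not establish about real images.

## Principal curves

A principal curve is fitted by the classical alternating algorithm:
initialise the index from the first linear principal component (or from a
caller-supplied ordering when the point set is symmetric about its first
principal axis and projection would fold), then repeat (i) smooth each
coordinate against the current index and (ii) re-project every point onto
the evaluated curve, until the relative change in the total squared
projection distance falls below `tol` (default 1e-4, `max_iter` 20). The
standard account of the algorithm fixes no convergence rule; ours is documented
behaviour, not a protocol constant. After convergence the curve is
re-expressed in cumulative chord arc length on a 512-point grid, and the
projection/refit cycle is run three more times at fixed parameterisation so
the stored indices and fitted coordinates agree (self-consistency drift
below ~0.05 mm RMS on noisy test curves). Projection uses exact foot points
on the polyline segments, with ties resolved to the smaller arc length, and
extension beyond the fitted range is linear from the endpoint value and
slope.

The coordinate smoother is a penalised B-spline (cubic basis on equally
spaced knots, second-difference coefficient penalty). Flexibility is always
specified in effective degrees of freedom; λ is solved by monotone root
finding so that the hat-matrix trace matches the request to ±0.05 (in
practice to near machine precision). The basis holds 30 functions by
default; the protocol constants fix df (6, 8, 12, 25) but not a basis
size, and 30 comfortably exceeds the largest df used.

## Curvature and boundary candidates

Curvature comes from the spline derivatives: signed planar curvature
(x′y″ − x″y′)/(x′²+y′²)^{3/2}, positive when the curve bends toward the
outward ordinate n₃, and non-negative space curvature |f′×f″|/|f′|³.
Because spline derivatives are unreliable at the ends, the outer 2% of arc
length is excluded from maxima searches (5% for lip ridge candidates). On
curvature plateaus the first grid index is reported.

Under the outward-positive sign convention the crease where a breast mound
joins the chest wall bends positively, while lip boundary *ridges* bend
negatively; the lip pipeline therefore searches maxima of the ridge-sense
(negated) curvature. This is the reading under which the exclusion of
spurious negative-curvature maxima on the breast and the ridge detection on
the lips are coherent within a single convention.

## Change-point statistic

The evidence for a valley crossing is the standardised difference of
first-derivative estimates fitted separately to the data below and above
each candidate arc length, se² = (wₐ−wᵦ)ᵀ(wₐ−wᵦ)σ̂², with σ̂ from
second-difference pseudo-residuals generalised to irregular spacing (each
interior value compared with the line through its neighbours, normalised so
iid noise of sd σ yields expectation σ²). Both one-sided fits are P-splines
with df 8 on a basis spanning the whole signal; Gram matrices of every
left/right split are accumulated by cumulative sums, so a full scan costs
one pass over the data plus a small eigenproblem per grid point. The
evaluation grid is the observed arc lengths thinned to ≤200 points, with
10% of the range masked at each end (one-sided fits are unstable there) and
sides smaller than df+2 masked. The global least-squares line is removed
from the signal first: it carries no derivative-change information and its
removal makes the statistic exactly invariant to constant and linear terms.
A feature is declared at the location of max |T| when it exceeds the
threshold (default 5); the rule applies to the pointwise maximum over the
scan grid rather than to any pre-chosen location. Under a smooth null with iid noise the statistic's pointwise sd
is within a few percent of 1 (the acceptance script recomputes this), and a
unit slope jump at noise sd 0.05 is localised within 5% of the range
essentially always.

## Constrained and shape-penalised fits

Equality constraints Aβ = c (through the mouth corners) are applied in
closed form, β̂_c = β̂ + G⁻¹Aᵀ[AG⁻¹Aᵀ]⁻¹(c − Aβ̂), where G must be the
penalised Gram G = BᵀB + λD₂ᵀD₂ of the fit being adjusted: dropping λ in
front of D₂ᵀD₂ inside the inverses would make the adjustment inconsistent
with the objective being minimised. Shape requirements (upper lip monotone increasing over the
first 40% of arc length and decreasing over the last 40%, the reverse for
the lower lip; second derivative decreasing then increasing for the upper,
the reverse for the lower) are soft penalties κβᵀD₁ᵀV₁D₁β + κβᵀD₂ᵀV₂D₂β
with κ = 100λ and 0/1 masks on the rows currently violating the pattern.
The masks depend on β, so the fit iterates a fixed-point loop (≤50 rounds);
violations below numerical noise are ignored, and if the masks have not
stabilised after half the budget they become cumulative, which guarantees
termination. Constraints are exact to machine precision; the shape
penalties, as intended, enforce their pattern only in large measure.

## Breast pipeline

Radial half-strips (slab tolerance δ = 1 mm) fan out from prom in 51 equal
clockwise steps, starting toward the lateral landmark (the starting
direction is not specified by the protocol; any fixed choice gives the same
correspondence). Strips stop at the plane through ssn and xipho spanned by
their mean surface normal (the midline rule, applied to every direction —
it only binds toward the other breast), and, once two previous transects
hold candidates, at 1.5× the larger of their candidate arc lengths; because
point arc lengths are only known after fitting, the strip is fitted, clipped
by projected arc length, and refitted when the cap binds. Candidates are
positive curvature maxima of the df-6 transect curve; screening uses the
three landmark rules with proportion 0.7 and tolerance 10 mm (both
config-exposed, since adjusting them is the protocol's own manual
intervention mechanism), with projections taken relative to the cloud
centroid so the inequalities are origin-invariant. The highest-curvature
retained candidate represents each transect; gaps are filled by the
weighted average ((l+1−i)·b̂_L i + i·b̂_R i)/(l+1) of side curves fitted
per coordinate against transect angle and extended linearly. The closed
boundary is fitted per coordinate against angle with df 12 after
duplicating 10% of the points across the wrap — a periodic continuation
device; closure is then sub-millimetre by construction.

On noiseless phantoms across ten mound geometries the fitted boundary stays
within 2 mm of the true junction circle everywhere (typically ~1 mm RMS),
and within ~1.2 mm RMS at measurement noise sd 0.3 mm. Two regimes degrade
it, and are deliberate limitations: mounds whose footprint approaches the
sampled domain edge or the torso midline (the transect then ends inside the
smoother's support around the junction), and flanks much sharper than the
df-6 transect curve can track (the curvature peak of an underfit corner
shifts toward the flat side). The established remedy in such cases
is the same as ours: inspect and adjust the screening constants.

## Lip pipeline

The mouth-region frame comes from whole-region PCA: n₁ along the elongated
mouth, n₂ vertical (oriented by an upright-capture hint), n₃ along the
mean surface normal. Fifty vertical strips (δ = 1.2 mm) each yield a df-8
principal curve of depth against height; the change-point scan of its
derivative flags the midline crossing at threshold 5, and only then are
ridge candidates collected above and below, with micro-maxima suppressed by
a floor at 20% of the strip's strongest ridge maximum (a documented
addition — the smooth convex face otherwise sprinkles weak maxima
everywhere). Multi-candidate strips are resolved against a preliminary
curve through the single-candidate strips: the candidate whose arc length
along its own vertical curve is nearest the preliminary crossing wins, ties
to the smaller arc length.

Corners are the first and last strong curvature maxima of a 3-D principal
curve (df 18) through the midline points — the midline reading of the
corner rule, which the figure-level description supports; a config switch
is not provided because the alternative ("lower boundary") reading proved
strictly less stable on the phantoms. Three robustness devices are
documented implementation choices: midline points are screened against a
local linear prediction from their neighbours (a single marginal-evidence
strip can otherwise plant its point on the wrong feature and dominate the
curvature profile), maxima must reach 35% of the strongest and lie outside
the outer 4% of the curve (end flare), and ripple maxima within 5 mm of arc
merge into one curvature-weighted peak.

The three final curves share the midline's arc length; each candidate is
assigned the arc length of its strip's midline point (projecting the ridge
point itself onto the curving midline would pile near-corner candidates
onto the corner arc length), strips whose midline point projects beyond
the corners are discarded, and each coordinate is fitted at df 25
constrained through the corners, the vertical coordinate additionally
carrying the lip shape penalties. Validation follows the 51-equally-spaced-
points protocol: root of the average squared distance to the true curve,
decomposable per axis in the frontal frame. On the default phantom the
corners are recovered to ~1 mm and all three curves to 0.7–1.0 mm RMS.

## Semi-landmarks and shape analysis

Along each breast transect, positions are proportional distances of the arc
from prom to the boundary. The proportions are normalised exponential
quantiles τᵢ = q(i·p_max/r)/q(p_max) (p_max = 0.99 — the quantile function
is unbounded, so a cap is mandatory), laid out so that spacing is *largest
at the apex* and tightens toward the boundary: the transects converge at
the apex, so sparse radial spacing there gives the most even surface
coverage, which is the stated purpose of the construction. The grid is the
apex plus k·r points (1021 at the defaults k=51, r=20), the last ring
exactly on the boundary, and the triangulation is an apex fan plus two
triangles per quad (2k(r−1)+k faces). Lip grids place 50 points on each
boundary curve and on the midline, joined by cross-lip principal curves
(df 4, chord fallback for thin pairs) carrying 3 points near the corners
up to 24 at the widest pair, the count ramping with the local lip width.

Superimposition is generalised Procrustes (translation + rotation; scaling
optional and off by default, so size may legitimately appear in the first
principal component), PCA is on the covariance of the vectorised aligned
configurations in raw mm (matching the size-in-PC1 interpretation), loading
signs are fixed by the largest-magnitude element, and paired comparisons
are per-component paired t-tests; score differences at numerical-noise
level are treated as exactly zero.

## What the phantoms do and do not show

The torso phantom is a dome-plus-erf-flank mound pair on a cylindrical
chest wall; the lip phantom a curved face patch with Gaussian boundary
ridges (heights 2.0/1.6 mm, width 4 mm narrowing toward the corners,
separations 10/13 mm from the meeting line) and a Gaussian valley (depth
2.5 mm, width 2.5 mm) that curls upward just inside the nominal mouth width
and fades into the cheek. Ground truth is always the exact
differential-geometric feature line of the analytic surface — curvature
crests for ridges, the depth minimum for the valley, the strongest
curvature maxima of the exact valley-floor curve for the corners — never
the generator's guide curves, because superposed fields shift the true
feature lines away from the guides. Sampling is jittered (unstructured) at
densities matching the reported image resolutions (~30,000 torso points;
a high-density option near 150,000 for the mouth region scale); noise is
iid plus a Gaussian-field "orange peel" whose autocorrelation reaches 1/e
at the stated correlation length.

Passing on these phantoms shows that the estimators recover known smooth
ridge/valley geometry at realistic resolution and noise; it does not show
robustness to reconstruction holes, pose-induced folds, specular artefacts
or anatomy far from the modelled shape families. Two measured limitations
worth restating: features narrower than the transect smoother's bandwidth
are attenuated before the boundary fit ever sees them (a 1.5 mm cupid's-bow
notch survives the constrained fit when present in its input, but is
already flattened to ~0.2 mm at the detection stage), and curvature crests
of weak asymmetric ridges are displaced systematically by up to ~1 mm
toward the flatter side — the same corner-region difficulty the method
resolves by constraining the fits through the well-estimated
corners.
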