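# Methods

## Contour hypothesis and parametrization

The segmentation curve is a closed, C²-periodic cubic spline through N
control knots (uᵢ, vᵢ); the knots themselves are the trainable weights.
Each of the N segments carries a local parameter s ∈ [0, 1] (uniform
parametrization, unit knot spacing).  With this convention the
continuity/smoothness/periodicity conditions reduce to the cyclic
tridiagonal system `M[i−1] + 4M[i] + M[i+1] = 6(y[i+1] − 2y[i] + y[i−1])`
for the knot second derivatives of each coordinate; the matrix is
strictly diagonally dominant, so the interpolant exists, is unique, and a
dense double-precision solve is exact to rounding.  Chord-length
parametrization is deliberately not the default: uniform spacing keeps
the internal-energy magnitudes independent of the pixel scale of the
contour, and the test suite pins the uniform convention against an
independent dense solve of the full 8N-coefficient system.

Knot order is canonicalized to counter-clockwise (shoelace sign test) at
ingest so that curvature
κ = (v_ss·u_s − u_ss·v_s)/(u_s² + v_s²)^{3/2}
is positive on convex contours.  Degenerate inputs fail loudly: fewer
than 4 knots or two coincident consecutive knots raise before any
optimization starts, and a vanishing tangent at a knot raises when
curvature is requested.

## Pixel model and rasterization

Images are min–max normalized to [0, 1] at ingest.  The region energy is
scale sensitive, so normalization is what makes one set of coefficients
transferable between images; all shipped presets assume it.  Pixel (p, q)
has its center at continuous coordinates (p, q), 0-based; knots live in
the same frame.

The mask χ is computed by an even-odd (crossing-number) test of every
pixel center against the polygon **through the knots** (no curve
densification — the polygon is the paper-thin approximation that keeps
the optimizer's inner loop cheap; a densified variant changed end-to-end
Dice by less than the pixel quantization in exploratory runs).  A pixel
center exactly on an edge counts as outside (strict interior): this makes
rasterization deterministic and direction-independent, and it is the rule
the brute-force oracles and the shapely cross-check in the tests encode.
Transient self-intersections during descent are filled by the same
even-odd rule with a warning rather than aborting the run.

## Energies

* Membrane and bending energies are knot averages (1/N Σ) of the squared
  first/second parametric derivatives, evaluated analytically from the
  spline coefficients (exact for the cubic basis).
* The region term is an **unnormalized pixel sum**; its γ-weighted
  gradient-uniformity term uses the squared gradient magnitude
  (I_x² + I_y²)·χ with centered differences, one-sided at image borders.
  Keeping the printed normalizations (knot average vs pixel sum) is what
  gives the preset coefficient magnitudes their meaning.
* The convexity prior is the knot average of κ²; the breakdown stores the
  raw term and applies σ at composition, so the total is an exactly
  linear function of (α, β, μ, σ) at fixed geometry — a property the
  tests assert.

## Gradients and optimization

The mask is piecewise constant in the knot positions, so the objective
has no useful analytic derivative.  Gradients are central finite
differences over the 2N knot coordinates.  The step must be large enough
to flip pixel memberships; the default is **h = 1.0 pixel** — the single
most important numerical choice in the scheme.  Each perturbed loss is
evaluated incrementally: moving one knot changes pixel memberships only
inside the convex hull of {previous knot, old position, new position,
next knot} (the even-odd symmetric difference of the two polygons is
bounded by the old and new boundary paths), so only a small patch is
re-classified and whole-image sums are updated in O(patch).  The
incremental route is verified against from-scratch evaluations to 1e−12
relative in the tests.

Updates use Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with base step
λ = 0.5 px.  The run stops at `max_iters` or when the mean knot
displacement stays below **0.05 px averaged over a 10-iteration window**.
The tolerance was chosen from measured plateau dynamics: with a
pixel-quantized region term Adam never settles below ~0.02–0.09 px of
per-iteration wiggle, so a much tighter tolerance never fires and a much
looser one stops mid-growth (displacements during expansion are ≈ λ).

## OPI and adaptive μ

OPI_k = 1 − ⟨θ, P⟩/(2Σθ) with P the per-step sign pattern over the last
w = 10 energy changes and θ normalized exponential weights (most recent
step weighted most).  sign(0) = 0, so flat histories score 1 ("no
evidence of a wrong direction").  Under the default convention
P = sign(ΔJ_int) − sign(ΔJ_ext), a healthy run (both falling) scores
exactly 1 and a shrinking snake (internal falling, external rising)
scores 2 — the failure registers at the *high* extreme, which is why the
adaptation trigger is two-sided: |OPI − 1| > 1 − threshold, threshold
0.8.  The mirrored convention (P with the roles swapped), under which the
same failure scores 0, is available as `opi_convention="flipped"`; the
default is kept as printed above and both are tested.

When OPI is off-nominal, μ ← μ + 2^{log10(J_ext/J_int)}, frozen once
J_ext ≥ 10⁴·J_int (ratio reading of the cap; "order" could also be read
as order-of-magnitude, but the ratio is the direct reading and is what
the cap test implements).  μ only ever increases.  On noisy plateaus OPI
fluctuates and μ keeps creeping until the cap; for fixed-preset protocols
(the volume studies) adaptation is turned off, matching the practice of
running each image class with fixed coefficients.

## Coefficient scales

Two conventions — intensity normalization to [0, 1] and per-segment
parametrization — fix the absolute scale of every energy term, and
coefficient values are only meaningful relative to those scales.  The
shipped presets keep the historical values for reference, but the
internal-dominated shrinkage regime used in the failure-mode study is
(α, β, μ) = (1e4, 2e2, 1e2): with normalized intensities the literal
low-α settings leave the internal term several orders below the region
term and the snake simply grows.  The shape-prior study uses
(α, β, μ, γ, σ) = (5e−1, 1e−3, 5e4, 2.0, 1e9): σ must beat the region
cost of the notch (≈ μ·area·contrast²) without dominating the global
curvature statistics, and γ > 0 suppresses the ballooning that a strong
convexity prior otherwise induces by penalizing inclusion of
high-gradient boundary pixels.

## Synthetic phantoms — what they do and do not show

All studies run on seeded, exactly-labeled phantoms:

* **disk** — bright disk (r = 20) on black, 128×128; the basic recovery
  condition from both an inside (r₀ = 8) and an enclosing (r₀ = 40)
  initialization.
* **u-cavity** — bright 80×68 rectangle minus a 24×44 top notch; the
  classic concavity that edge-based snakes cannot enter.  With adaptive μ
  the contour fully excludes the cavity.
* **notched-convex** — bright disk (r = 26) with a 28×26 intermediate-
  gray (0.35) notch intruding from the boundary, emulating papillary
  muscles whose intensity resembles surrounding tissue; ground truth is
  the **full** disk, per the clinical convention that the ventricle
  outline is the convex envelope.  The notch is deliberately large and
  mid-gray: a background-black notch makes the convex outline cross pure
  background, and no σ then separates "ignore the notch" from "balloon
  everywhere" — measured gradient balances showed the two failure modes
  meet before the prior wins.
* **disk volume** — 8 slices of disks (default constant r = 20) for the
  transfer-learning study.

Noise, when enabled, is additive Gaussian clipped to [0, 1] (default
off, matching piecewise-constant test imagery).  The phantoms are
piecewise constant with sharp boundaries; passing on them demonstrates
the optimizer, the adaptive-μ escape and the prior's direction of effect,
not robustness to bias fields, partial-volume blur, Rician noise or
topology changes — real-scan performance is out of scope here, and
topology change across slices is an explicit non-goal.

## Problem sizes and runtime

Default studies use 128×128 images with 16–35 knots and 80–800
iterations; a full acceptance run (all studies) is a couple of minutes on
one CPU.  These sizes were chosen as the smallest at which the phantoms'
geometric features (notch widths, cavity arms) span several knot
spacings.

## Known limitations

* The knot-sampled convexity prior can be partially evaded by knot
  placements whose sampled curvature is small while the curve bends
  between knots; the prior's working window in σ is therefore bounded
  above (ballooning) as well as below (no effect).
* One object per seed; topology changes across slices are not handled.
* Heterogeneous-intensity objects violate the two-region Chan–Vese
  assumption.
* Iterations-to-convergence depends on a displacement-noise threshold
  and is best compared within a run (as the transfer-learning study
  does), not across machines.
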