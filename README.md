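# pics — physics-informed contour selection

Label-free 2D/3D image segmentation with a spline snake that is trained
like a tiny machine-learning model.  The contour hypothesis is a closed
periodic cubic spline whose **control knots are the trainable weights**
(a 10-knot snake has just 20 parameters); the objective combines the
classic snake internal energies with a Chan–Vese region energy, so no
edge map, no labels and no Euler–Lagrange machinery are needed.  The
intended users are researchers who need quick, reproducible single-object
masks — e.g. bootstrapping annotations for cardiac left-ventricle MRI —
from nothing but one seed click per object.

## The model

The contour is ψ(s) = (u(s), v(s)), a C²-periodic cubic spline through N
knots (uᵢ, vᵢ).  Fitting minimizes

J = α·J_ψs + β·J_ψss + μ·J_cv + σ·J_shape

* J_ψs  = (1/N) Σᵢ (u_s² + v_s²)ᵢ — membrane energy (first parametric
  derivative at the knots),
* J_ψss = (1/N) Σᵢ (u_ss² + v_ss²)ᵢ — bending energy,
* J_cv  = Σ_pixels ((I−μ_in)χ)² + γ(∇I·χ)² + ((I−μ_out)(1−χ))² — the
  Chan–Vese region energy of the binary mask χ induced by the knot
  polygon (even-odd point-in-polygon rule), with μ_in/μ_out the mean
  intensities inside/outside,
* J_shape = (1/N) Σᵢ κᵢ² — an optional convexity prior on the contour
  curvature κ, used when the target (like the left ventricle outline) is
  known to be convex.

Because χ changes only when a pixel center flips sides, J is piecewise
constant in the knots and has no useful analytic gradient; optimization
uses **central finite differences with a 1-pixel step** and Adam.  A
health index (OPI — an exponentially weighted sign statistic of the
recent internal/external energy trends) detects stalls and adaptively
raises μ, which is how the snake escapes local minima and enters
concavities.  Volumes are segmented slice by slice, each slice
initialized from the previous converged contour (transfer learning),
which typically halves the iteration count from the second slice on.

## Worked example

```python
import pics

ph = pics.make_disk()                      # 128x128, bright disk r=20, exact truth mask
est = pics.ContourSegmenter(alpha=1e-1, beta=1e-2, mu=1e3, n_knots=16,
                            init_radius=8, max_iters=300, adaptive_mu=False)
est.fit(ph.grid, seed_xy=(64, 64))         # seed click inside the object
print(f"converged: {est.converged_} after {est.n_iter_} iterations")
print(f"mask area: {est.mask_.sum()} px (truth: {ph.truth_mask.sum()} px)")
print(f"Dice vs ground truth: {est.score(ph.grid, ph.truth_mask):.4f}")
```

prints

```
converged: True after 78 iterations
mask area: 1249 px (truth: 1245 px)
Dice vs ground truth: 0.9920
```

The snake started as a 16-knot circle of radius 8 around the seed point,
expanded under the region term, and stopped once the mean knot
displacement stayed below 0.05 px for 10 iterations.  `est.history_` is a
DataFrame with per-iteration energies, OPI and μ for diagnostics, e.g.
`est.history_[["k", "j_int", "j_ext", "opi", "mu"]]`.

The same workflow is available from the shell:

```bash
pics phantom --kind disk --out disk.png --truth-out truth.png
pics segment2d --image disk.png --seed-xy 64,64 --radius 8 --knots 16 \
     --mu 1000 --alpha 0.1 --beta 0.01 --out mask.png --log run.csv
pics dice --a mask.png --b truth.png
```

and `pics segment3d --volume scan.nii.gz --seed-xy 64,64 ...` marches a
contour through a NIfTI stack.  Coefficient presets for the shipped
regimes (`tc1`…`tc4`, `acdc-normal`, `acdc-indistinct`, `acdc-thin`) are
available via `--preset`.

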