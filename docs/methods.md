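# Methods

This note documents the model, the numerical choices and the open design
decisions behind `leeac`, in the order the pipeline executes them.

## Coarse localization and patch placement

A global intermeans (Ridler–Calvard) threshold — the fixed point of
`T ← (mean(I ≤ T) + mean(I > T))/2`, started at the global mean and iterated
until the threshold moves by less than 0.5 intensity units — splits the
image into a darker and a lighter class.  Pigmented lesions are darker than
surrounding skin, so the darker class is taken as the coarse lesion mask
(an `invert` flag covers the converse).  Grayscale for thresholding is the
unweighted channel mean.  A constant image has no bimodal structure and is
rejected.

Sample patches (default 70×90 px) feed the color models.  The foreground
patch is centered on the centroid of the largest foreground connected
component, shifted minimally to stay inside that component's bounding box
and the frame; the background patch is centered on the background pixel at
the maximum of the Euclidean distance transform from the foreground (first
maximum in row-major order — the argmax set can be symmetric, e.g. all four
image corners, and its centroid can fall inside the lesion).  Patches are
shifted apart if they overlap, and an error names the limiting class if one
is too small.  Nothing in the underlying method prescribes patch placement;
this centroid/distance heuristic is this package's choice and is fully
overridable with user-supplied patches.

## Edge-preserving denoising

Perona–Malik anisotropic diffusion, explicit 4-neighbor scheme, per
channel: `I ← I + dt · Σ_d c(|∇_d I|) ∇_d I` over the four forward
differences.  The default conduction coefficient is

    c(∇I) = 1 / (1 + sqrt(1 + |∇I|²/γ²)),

a variant bounded in (0, 0.5] that halves diffusion even in flat regions;
the standard coefficient `1/(1 + |∇I|²/γ²)` is available as
`variant="classic"`.  Defaults γ = 15 (8-bit intensity units — small
texture and noise gradients diffuse, lesion borders with |∇I| ≫ γ do not),
20 iterations, dt = 0.2 (explicit stability requires dt ≤ 0.25).

## SPH edge features

Pixels act as SPH particles with mass = intensity.  The poly6 kernel

    W(r, h) = (315 / (64 π h⁹)) (h² − r²)³,   |r| < h

is used with smoothing length h = 1.  Two conventions need care:

* **Grid spacing.**  On a unit-spaced grid every neighbor of a pixel sits at
  |r| ≥ 1, where a compact-support kernel with h = 1 and its gradient both
  vanish — the interpolated gradient field would be identically zero.  The
  kernel spec therefore carries a `grid_spacing` (default 0.5 kernel units
  per pixel), which places the full 3×3 neighborhood strictly inside the
  h = 1 support (axial neighbors at r = 0.5, diagonals at r ≈ 0.71).
* **Normalization.**  `as_printed_3d` keeps the 3-D constant above;
  `renormalized_2d` (default) divides by the discrete sum of W over the
  support offsets so that a constant intensity field interpolates to itself
  (`sph_density` of a constant-v image is v in the interior).  Only relative
  magnitudes reach the edge indicator, so the choice does not affect
  segmentation.  A quadratic profile `(h² − r²)²` is exposed as
  `exponent_as_printed` for comparison; the kernel gradient is always the
  analytic derivative of the selected profile (verified against central
  differences to 1e-6 relative error in the tests).

The normal field `∇A(rᵢ) = Σⱼ mⱼ ∇W(rᵢ − rⱼ)` is computed by convolution
with the dense gradient stencil (replicate padding, so the border of the
image does not masquerade as an edge); the density sum uses truncated
neighborhoods (zero padding).  The edge indicator is

    g = 1 / (1 + m̂^p),   m̂ = min(m / m_ref, M),

with p = 2 by default, M = 10, and m_ref the 90th percentile of the
magnitude distribution.  The percentile reference makes g invariant to the
kernel normalization; the 90th (rather than a higher one) is used because
the reference must sit at the typical *non-edge* texture level — in images
whose edge pixels exceed the complementary tail fraction (thin structures,
noise-free synthetics) a 99th-percentile reference lands on the edge
magnitudes themselves and flattens g.  When the reference is ~0 (noise-free
flat background) raw magnitudes are used.

## Probability map and the fused edge-stop function

Per channel and per label, the patch pixels give Gaussian models
(population σ, floored at 1e-3 so constant patches stay usable).  The
normalized likelihood `P^i = p_F/(p_F + p_B)` (densities floored at 1e-12)
is averaged over channels with uniform weights by default; `P_F + P_B = 1`
pixelwise by construction.

Geodesic distances are exact shortest paths on the 8-connected pixel graph
(multi-source Dijkstra), with step cost `|P_F(q) − P_F(p)| + ε·len(p→q)`,
ε = 1e-4, diagonal length √2 — the discrete line integral of the
probability change along the path, with a Euclidean tie-breaker.  Crossing
the lesion border is expensive regardless of how blurred the *intensity*
transition is, which is what rescues fuzzy borders.  The combined
probability is `s = D_B/(D_F + D_B)` (1 on the foreground patch, 0 on the
background patch, P_F where both distances vanish); the formula realizes
the labeling rule "foreground iff D_F < D_B" as a continuous field.

The edge-minimized field is `prob(s) = 2(s − c)²` with center c = 0.7 for
dermoscopy (0.5 recovers the generic two-class rule), and the fused
edge-stop function is `g_new = g · prob`.  Values of g_new below 5% of its
maximum are floored to 0 (`prob.edge_threshold = 0.05`): without the hard
floor the g_new valley across a fuzzy border is wide and shallow, the
contour never stalls within the area-change criterion, and evolution runs
to the iteration cap.  The plain-g baseline (`esf="plain"`) receives the
same floor so that fused-vs-plain comparisons isolate the probability
fusion itself.  Whether prob is computed from the geodesic-combined s or
the raw color likelihood is configurable (`prob.source`); the geodesic
field is the default since it is the component that fixes leaks.

## Level-set evolution

One iteration applies the reaction step

    φ ← φ + τ₁ [ μ div(d_p(|∇φ|)∇φ) + λ δ_ε(φ) div(g_new ∇φ/|∇φ|)
                + β v g_new δ_ε(φ) ]

followed by the diffusion regularization `φ ← φ + τ₂ Δφ` (5-point
Laplacian, replicate boundary), which keeps φ stable without
reinitialization.  `d_p` is the standard double-well factor (`p'(s)/s`,
wells at 0 and 1, limit 1 at s → 0; the divergence is evaluated as
`div((d_p − 1)∇φ) + Δφ` for stencil locality), δ_ε is the smoothed Dirac of
half-width ε = 1.5 px, |∇φ| is floored at 1e-10, and v is the propagation
speed constant multiplying the area term.  φ starts as a binary step ±c₀
(c₀ = 2) on the intermeans bounding box dilated by 10 px.

Defaults: τ₁ = 0.3, τ₂ = 0.01, v = 0.7, μ = 0.65, λ = 15, β = 10.  The
weights are chosen so the per-iteration effective magnitudes (μτ₁ ≈ 0.2,
λτ₁ = 4.5, βvτ₁ = 2.1) match common distance-regularized level-set
practice; with weights an order of magnitude smaller the front creeps at
≪ 0.1 px/iteration, pins to the pixel lattice, and the area-change stopping
rule fires during plateaus long before the border is reached.

**Stopping.**  Evolution stops when the enclosed contour area changes by at
most `area_tol = 10 px²` over a 5-iteration window, first checked after a
30-iteration burn-in, with a hard cap of 500 iterations (a non-convergence
flag is set if the cap is hit).  The monitored area is a sub-pixel
smoothed-Heaviside measure rather than a raw pixel count: the discrete
front advances in pulses (period ≈ 7 iterations here) and integer counts
jump by whole rows, so single-iteration pixel-count differences hit zero
spuriously mid-evolution.  The per-iteration pixel-count history is still
recorded and reported.  The final mask keeps only the connected component
overlapping the initial rectangle; no other morphological cleanup is
applied.

## Evaluation

Dice `2|O∩G|/(|O|+|G|)`, Jaccard `|O∩G|/|O∪G|`, and border error
`BE = (FN+FP)/(TN+TP)`.  The BE denominator is deliberately the *correctly*
classified count, not the ground-truth area; the conventional
`(FN+FP)/|G|` is provided separately as `xor_over_gt` and never silently
substituted.  Degenerate inputs (both masks empty; complementary masks with
TN+TP = 0) raise errors rather than returning sentinel values.

## Synthetic data

The generator emulates the four failure modes that break edge-based
contours on dermoscopy images: fuzzy borders (Gaussian blur σ_b of the
region mask before color blending), low lesion/skin contrast, sensor noise
(i.i.d. Gaussian, per channel), and dark curvilinear hairs (quadratic
Bézier strokes, 1–3 px wide).  The lesion is an ellipse (default semi-axes
85×95 px in a 300×300 image, ≥ 10 px margin) whose radius is modulated by a
smooth low-frequency harmonic perturbation; the ground truth is the exact
perturbed-ellipse interior.  Default palette: skin (200, 160, 140), lesion
(110, 70, 60); noise σ = 4.  Everything is a pure function of the spec,
seed included.

The fixture battery is 6 classes × 2 seeds: sharp (σ_b = 0.5, full
contrast), fuzzy_4/8/12 (σ_b ∈ {4, 8, 12} at ≈ 30-unit contrast),
low_contrast (≈ 25 units, σ_b = 2) and fuzzy_hairy (σ_b = 8, six hairs).
The sizes (300×300, 12 images) keep a full suite run around two minutes on
one CPU while leaving the 70×90 default patches room inside both classes.

What the generator does **not** emulate: real pigment-network texture,
multi-modal lesion color, ruler markings, air bubbles, vignetting and
specular highlights.  Passing tests on these fixtures demonstrate the
mechanics of the method (and specifically that probability fusion prevents
leaking where the plain edge indicator fails) — not clinical-grade accuracy
on real dermoscopy, which depends on color-model adequacy for real lesions.

## Known limitations

* The Gaussian color model is unimodal per channel; strongly variegated
  lesions would need a mixture model or a different patch strategy.
* Hair artifacts are only attenuated by denoising; heavy hair coverage
  (the fuzzy_hairy class) degrades both the coarse localization and the
  probability map, and those runs may hit the iteration cap.
* One lesion per image: the output is by construction a single connected
  component overlapping the initial rectangle.
* Automatic patch placement assumes the intermeans mask's largest component
  is the lesion; images dominated by dark artifacts can defeat it (supply
  patches explicitly in that case).
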