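# leeac — local edge-enhanced active contours for skin lesion border detection

Accurate delineation of the lesion border in dermoscopy images is the first
step of automated melanoma assessment, and the classic failure mode of
edge-based active contours is *leaking*: when the border is fuzzy or the
lesion/skin contrast is low, the edge-stop function never approaches zero
and the evolving contour passes straight through the boundary.

`leeac` implements a segmentation pipeline built around a robust edge-stop
function that fuses two independent cues:

1. **SPH local edge features.** Every pixel is an SPH particle whose mass is
   its (denoised, grayscale) intensity.  The poly6 kernel
   `W(r,h) = C (h² − r²)³` (support `|r| < h`, default `h = 1`) and its
   analytic gradient give a surface-normal field `∇A(rᵢ) = Σⱼ mⱼ ∇W(rᵢ−rⱼ, h)`
   whose magnitude replaces the image gradient in the edge indicator
   `g = 1/(1 + m̂ᵖ)`, `p ∈ {1,2}`.
2. **Geodesic probability map.** Per-channel Gaussian color models fitted on
   one foreground and one background sample patch (default 70×90 px, placed
   automatically from an intermeans threshold mask) give a color likelihood
   `P_F`; geodesic distances `D_F, D_B` over the pixel graph — where each
   step costs the probability change `|ΔP_F|` — combine it into
   `s = D_B/(D_F + D_B)`, which stays crisp across fuzzy borders.  The
   edge-minimized field `prob(s) = 2(s − 0.7)²` vanishes on the border level
   set, and the fused edge-stop function is `g_new = g · prob`.

The contour is the zero level set of a field φ evolved by
distance-regularized reaction steps (time step τ₁ = 0.3) alternating with
reaction–diffusion regularization (τ₂ = 0.01), with speed constant
v = 0.7, until the enclosed contour area changes by no more than 10 px²;
because `g_new ≈ 0` on the border even when the raw gradient is weak, the
contour stops there instead of leaking.  Quality is measured by the Dice
coefficient, Jaccard index and the border error `BE = (FN+FP)/(TN+TP)`.

A seeded synthetic-dermoscopy generator (elliptical lesion with irregular
border, controllable blur, contrast, noise and hair artifacts, with exact
ground truth) makes every stage verifiable without clinical data.

## Worked example

```python
from leeac import LesionSpec, generate, run_pipeline, evaluate_masks

image, truth = generate(LesionSpec(blur_sigma=8.0, lesion_color=(170, 130, 110), seed=2))
result = run_pipeline(image)                      # fused edge-stop function
scores = evaluate_masks(result.mask, truth)
print(f"dice={scores.dice:.3f} jaccard={scores.jaccard:.3f} "
      f"border_error={scores.border_error:.3f} iterations={result.iterations}")
```

prints

```
dice=0.935 jaccard=0.877 border_error=0.041 iterations=222
```

meaning the recovered border overlaps 94% of the true lesion (Dice), the
intersection covers 88% of the union (Jaccard), ~4% of pixels are
misclassified relative to the correctly classified ones (border error), and
the contour met the 10 px² area-change stopping rule after 222 iterations.
Running the same image with `PipelineConfig(esf="plain")` — the raw edge
indicator without probability fusion — lets the contour leak through the
σ_b = 8 px fuzzy border and collapse (Dice ≈ 0.0), which is precisely the
failure mode the fused edge-stop function removes.

The same pipeline is available from the shell:

```sh
leeac synth --out fixtures --seed 0
leeac segment fixtures/img_00_sharp.png --out mask.png --save-intermediate inter/
leeac eval mask.png fixtures/truth_00_sharp.png --json
leeac batch fixtures --truth-dir fixtures --out scores/
```

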