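"""Seeded generator of dermoscopy-like test images with known ground truth.

Real dermoscopy images show a darker, roughly elliptical pigmented lesion on
lighter skin, with the failure modes border-detection methods struggle with:
fuzzy (blurred) borders, low lesion/skin contrast, sensor noise and dark
curvilinear hairs.  The generator reproduces each of these as an independent
dial so every pipeline stage can be exercised at a known difficulty, and it
is a pure function of its spec (seed included).

The lesion is an ellipse whose radius is modulated by a smooth low-frequency
radial perturbation (border irregularity); the ground truth is the exact
perturbed-ellipse interior.  The rendered image blends background and lesion
colors through a soft mask (Gaussian blur of the truth with σ_b), then adds
i.i.d. Gaussian noise and quadratic Bézier hair strokes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import bezier_curve

from leeac.errors import ParameterError

__all__ = ["LesionSpec", "generate", "fixture_suite"]


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one synthetic dermoscopy image.

    Distances are in pixels, colors in 8-bit RGB.  ``irregularity`` is the
    relative amplitude of the smooth radial border perturbation (0 = exact
    ellipse).  ``blur_sigma`` (σ_b) controls border fuzziness; ``noise_sigma``
    is the per-channel i.i.d. Gaussian noise level.
    """

    shape: Tuple[int, int] = (300, 300)
    center: Tuple[float, float] | None = None  # defaults to the image center
    semi_axes: Tuple[float, float] = (85.0, 95.0)
    irregularity: float = 0.05
    blur_sigma: float = 1.0
    lesion_color: Tuple[float, float, float] = (110.0, 70.0, 60.0)
    background_color: Tuple[float, float, float] = (200.0, 160.0, 140.0)
    noise_sigma: float = 4.0
    hair_count: int = 0
    hair_darkness: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ParameterError("blur_sigma and noise_sigma must be non-negative")
        if self.irregularity < 0:
            raise ParameterError("irregularity must be non-negative")
        if self.hair_count < 0:
            raise ParameterError("hair_count must be non-negative")
        for c in (*self.lesion_color, *self.background_color):
            if not 0 <= c <= 255:
                raise ParameterError("colors must lie in [0, 255]")
        h, w = self.shape
        cr, cc = self.center if self.center is not None else (h / 2, w / 2)
        a, b = self.semi_axes
        # the radial perturbation has unit variance; 3 sigma bounds its excursion
        reach = max(a, b) * (1.0 + 3.0 * self.irregularity)
        if cr - reach < 10 or cc - reach < 10 or cr + reach > h - 10 or cc + reach > w - 10:
            raise ParameterError("lesion must lie inside the image with a >= 10 px margin")


def _truth_mask(spec: LesionSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    cr, cc = spec.center if spec.center is not None else (h / 2, w / 2)
    a, b = spec.semi_axes
    rows, cols = np.mgrid[0:h, 0:w]
    dr = (rows - cr) / a
    dc = (cols - cc) / b
    radius = np.hypot(dr, dc)
    if spec.irregularity > 0:
        theta = np.arctan2(dr, dc)
        # smooth radial modulation from a few low harmonics
        amp = np.zeros_like(theta)
        for k in range(2, 6):
            amp += rng.normal() * np.cos(k * theta) + rng.normal() * np.sin(k * theta)
        amp /= np.sqrt(8.0)  # unit variance across the harmonics
        boundary = 1.0 + spec.irregularity * amp
    else:
        boundary = 1.0
    return (radius <= boundary).astype(np.uint8)


def _draw_hairs(image: np.ndarray, spec: LesionSpec, rng: np.random.Generator) -> None:
    h, w = spec.shape
    for _ in range(spec.hair_count):
        pts = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2)).astype(int)
        rr, cc = bezier_curve(
            pts[0, 0], pts[0, 1], pts[1, 0], pts[1, 1], pts[2, 0], pts[2, 1], weight=1.0,
            shape=(h, w),
        )
        stroke = np.zeros((h, w), dtype=bool)
        stroke[rr, cc] = True
        width = int(rng.integers(1, 4))
        if width > 1:
            stroke = ndimage.binary_dilation(stroke, iterations=width - 1)
        image[stroke] = spec.hair_darkness


def generate(spec: LesionSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Render one synthetic dermoscopy image and its ground-truth mask.

    Returns ``(image, truth)``: a H×W×3 uint8 image and a H×W uint8 {0,1}
    mask.  Identical specs (including the seed) give identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _truth_mask(spec, rng)
    soft = truth.astype(np.float64)
    if spec.blur_sigma > 0:
        soft = ndimage.gaussian_filter(soft, spec.blur_sigma)
    bg = np.asarray(spec.background_color, dtype=np.float64)
    fg = np.asarray(spec.lesion_color, dtype=np.float64)
    image = bg[None, None, :] + (fg - bg)[None, None, :] * soft[:, :, None]
    if spec.hair_count > 0:
        _draw_hairs(image, spec, rng)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return np.clip(image, 0, 255).astype(np.uint8), truth


def fixture_suite(seed: int = 0) -> List[Tuple[np.ndarray, np.ndarray, str]]:
    """Fixed battery of 12 test images: 6 difficulty classes × 2 seeds.

    Classes: ``sharp`` (crisp border, full contrast), ``fuzzy_4/8/12``
    (border blur σ_b at low ~30-unit contrast), ``low_contrast`` (~25-unit
    contrast, mild blur) and ``fuzzy_hairy`` (σ_b = 8 with 6 hairs).
    Returns ``(image, truth, tag)`` triples.
    """
    base = LesionSpec()
    low = tuple(np.asarray(base.background_color) - 30.0)
    lower = tuple(np.asarray(base.background_color) - 25.0)
    classes = [
        ("sharp", replace(base, blur_sigma=0.5)),
        ("fuzzy_4", replace(base, blur_sigma=4.0, lesion_color=low)),
        ("fuzzy_8", replace(base, blur_sigma=8.0, lesion_color=low)),
        ("fuzzy_12", replace(base, blur_sigma=12.0, lesion_color=low)),
        ("low_contrast", replace(base, blur_sigma=2.0, lesion_color=lower)),
        ("fuzzy_hairy", replace(base, blur_sigma=8.0, hair_count=6)),
    ]
    suite = []
    for i, (tag, spec) in enumerate(classes):
        for j in range(2):
            img, truth = generate(replace(spec, seed=seed + 1000 * i + j))
            suite.append((img, truth, tag))
    return suite
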