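"""End-to-end segmentation pipeline and its configuration.

Stage order: intermeans threshold → patch placement → Perona–Malik
denoising → SPH normal field → edge indicator g → Gaussian color models →
geodesic probability map s → prob(s) → g_new = g·prob → level-set evolution
→ single-component lesion mask.  Images are processed at their original
size; there is no resizing stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from leeac import level_set, prob_map, preprocess, sph_edge
from leeac.errors import LeeacError, ParameterError
from leeac.level_set import EvolutionConfig
from leeac.preprocess import PatchSpec
from leeac.sph_edge import SPHKernelSpec

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PreprocessConfig:
    gamma: float = 15.0
    n_iter: int = 20
    dt: float = 0.2
    variant: str = "as_printed"
    invert: bool = False
    patch_height: int = 70
    patch_width: int = 90


@dataclass(frozen=True)
class SPHConfig:
    h: float = 1.0
    normalization: str = "renormalized_2d"
    exponent_as_printed: bool = False
    grid_spacing: float = 0.5
    p: int = 2
    percentile: float = 90.0
    scale_max: float = 10.0

    def kernel_spec(self) -> SPHKernelSpec:
        return SPHKernelSpec(
            h=self.h,
            normalization=self.normalization,  # type: ignore[arg-type]
            exponent_as_printed=self.exponent_as_printed,
            grid_spacing=self.grid_spacing,
        )


@dataclass(frozen=True)
class ProbConfig:
    center: float = 0.7
    channel_weights: Optional[Tuple[float, ...]] = None  # None = uniform
    edge_threshold: Optional[float] = 0.05
    connectivity: int = 8
    # "geodesic" minimizes prob(s) on the geodesic-combined s; "color" on
    # the raw color likelihood P_F
    source: str = "geodesic"


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for every pipeline stage.

    ``esf`` selects the edge-stop function: ``fused`` (g_new = g·prob,
    default) or ``plain`` (the raw SPH edge indicator g, the leak-prone
    baseline).
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sph: SPHConfig = field(default_factory=SPHConfig)
    prob: ProbConfig = field(default_factory=ProbConfig)
    level_set: EvolutionConfig = field(default_factory=EvolutionConfig)
    esf: str = "fused"
    init_dilation: int = 10

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "PipelineConfig":
        """Build from a nested dict, rejecting unknown keys by path."""
        sections = {
            "preprocess": PreprocessConfig,
            "sph": SPHConfig,
            "prob": ProbConfig,
            "level_set": EvolutionConfig,
        }
        kwargs: Dict[str, Any] = {}
        top_fields = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in top_fields:
                raise ParameterError(f"unknown config key: {key!r}")
            if key in sections:
                sub_cls = sections[key]
                sub_fields = {f.name for f in dataclasses.fields(sub_cls)}
                for sub_key in value:
                    if sub_key not in sub_fields:
                        raise ParameterError(f"unknown config key: {key}.{sub_key}")
                if key == "prob" and value.get("channel_weights") is not None:
                    value = dict(value, channel_weights=tuple(value["channel_weights"]))
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Final mask plus diagnostics and the intermediate fields."""

    mask: np.ndarray
    threshold: float
    fg_patch: PatchSpec
    bg_patch: PatchSpec
    patches_source: str
    iterations: int
    final_area: int
    converged: bool
    area_history: list
    intermediates: Dict[str, np.ndarray]

    def diagnostics(self) -> Dict[str, Any]:
        return {
            "threshold": self.threshold,
            "fg_patch": self.fg_patch.to_dict(),
            "bg_patch": self.bg_patch.to_dict(),
            "patches": self.patches_source,
            "iterations": self.iterations,
            "final_area": self.final_area,
            "converged": self.converged,
        }


def _stage(name: str):
    """Prefix stage name onto any pipeline error."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, LeeacError):
                exc.args = (f"[{name}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
            return False

    return _Ctx()


def _init_rectangle(mask: np.ndarray, dilation: int) -> PatchSpec:
    """Bounding box of the largest coarse-mask component, dilated and clipped."""
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ParameterError("coarse mask is empty")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    rows, cols = np.nonzero(comp)
    h, w = mask.shape
    r0 = max(int(rows.min()) - dilation, 0)
    c0 = max(int(cols.min()) - dilation, 0)
    r1 = min(int(rows.max()) + 1 + dilation, h)
    c1 = min(int(cols.max()) + 1 + dilation, w)
    # keep at least a 1-px exterior band so the initial contour is non-empty
    if r0 == 0 and c0 == 0 and r1 == h and c1 == w:
        r0, c0, r1, c1 = 1, 1, h - 1, w - 1
    return PatchSpec(r0, c0, r1 - r0, c1 - c0, "foreground")


def run_pipeline(
    image: np.ndarray,
    cfg: PipelineConfig | None = None,
    fg: PatchSpec | None = None,
    bg: PatchSpec | None = None,
) -> PipelineResult:
    """Segment one dermoscopy image.

    Parameters
    ----------
    image:
        H×W×3 or H×W array with intensities in [0, 255]; H, W >= 64.
    cfg:
        Pipeline configuration (defaults throughout if omitted).
    fg, bg:
        Optional user-supplied sample patches; placed automatically from the
        intermeans mask when omitted.
    """
    cfg = cfg or PipelineConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim not in (2, 3):
        raise ParameterError("expected a 2-D or 3-D image")
    h, w = image.shape[:2]
    if h < 64 or w < 64:
        raise ParameterError("image must be at least 64x64 for the pipeline")
    if image.min() < 0 or image.max() > 255 or not np.all(np.isfinite(image)):
        raise ParameterError("intensities must be finite and within [0, 255]")
    if cfg.esf not in ("fused", "plain"):
        raise ParameterError(f"unknown esf mode {cfg.esf!r}")

    pp = cfg.preprocess
    with _stage("intermeans"):
        threshold, coarse = preprocess.intermeans_threshold(image, invert=pp.invert)

    if fg is not None and bg is not None:
        patches_source = "user"
        fg.validate((h, w))
        bg.validate((h, w))
    elif fg is None and bg is None:
        patches_source = "auto"
        with _stage("select_patches"):
            fg, bg = preprocess.select_patches(coarse, pp.patch_height, pp.patch_width)
    else:
        raise ParameterError("supply both patches or neither")

    with _stage("denoise"):
        denoised = preprocess.perona_malik_filter(
            image, gamma=pp.gamma, n_iter=pp.n_iter, dt=pp.dt, variant=pp.variant
        )

    with _stage("sph"):
        spec = cfg.sph.kernel_spec()
        gray = preprocess.to_grayscale(denoised)
        _, magnitude = sph_edge.sph_normal_field(gray, spec)
        g = sph_edge.edge_indicator(
            magnitude, cfg.sph.p, percentile=cfg.sph.percentile, scale_max=cfg.sph.scale_max
        )

    intermediates: Dict[str, np.ndarray] = {"g": g}
    if cfg.esf == "fused":
        with _stage("prob_map"):
            fields = prob_map.probability_map(
                denoised, fg, bg,
                weights=cfg.prob.channel_weights,
                connectivity=cfg.prob.connectivity,
            )
            source = fields["s"] if cfg.prob.source == "geodesic" else fields["p_f"]
            prob = prob_map.minimize_prob(source, cfg.prob.center)
            g_esf = prob_map.fuse_edge_indicator(g, prob, cfg.prob.edge_threshold)
        intermediates.update(fields)
        intermediates["prob"] = prob
        intermediates["g_new"] = g_esf
    else:
        # the baseline gets the same hard edge floor as the fused path so
        # the comparison isolates the probability fusion itself
        g_esf = (
            np.where(g < cfg.prob.edge_threshold * g.max(), 0.0, g)
            if cfg.prob.edge_threshold is not None
            else g
        )

    with _stage("level_set"):
        init_rect = _init_rectangle(coarse, cfg.init_dilation)
        phi0 = level_set.initialize_phi((h, w), init_rect, cfg.level_set.c0)
        result = level_set.evolve(phi0, g_esf, cfg.level_set, init_rect=init_rect)
    intermediates["phi0_rect"] = np.array(
        [init_rect.row0, init_rect.col0, init_rect.height, init_rect.width]
    )

    return PipelineResult(
        mask=result.mask,
        threshold=threshold,
        fg_patch=fg,
        bg_patch=bg,
        patches_source=patches_source,
        iterations=result.iterations,
        final_area=int(result.mask.sum()),
        converged=result.converged,
        area_history=result.area_history,
        intermediates=intermediates,
    )
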