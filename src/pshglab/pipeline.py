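"""High-level convenience: stack -> maps -> statistics in one call."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RunConfig
from .map_analysis import (
    MolecularMaps,
    SummaryStats,
    fiber_density,
    normalize_and_segment,
    ratio_maps,
    summarize,
)
from .pixel_fit import FitMaps, PolarizationStack, fit_stack

__all__ = ["PipelineResult", "analyze_stack"]


@dataclass
class PipelineResult:
    stack: PolarizationStack
    foreground: np.ndarray
    fit: FitMaps
    mol: MolecularMaps
    stats: SummaryStats
    fiber_mask: np.ndarray


def analyze_stack(stack: PolarizationStack, config: RunConfig | None = None) -> PipelineResult:
    """Run segmentation, per-pixel fitting, ratio maps and summaries."""
    cfg = config or RunConfig()
    foreground = normalize_and_segment(stack, threshold=cfg.segmentation_threshold)
    fit = fit_stack(stack, smooth_radius=cfg.smooth_radius, foreground=foreground)
    mol = ratio_maps(fit)
    stats = summarize(
        stack, fit, mol, foreground,
        ratio_bin_width=cfg.ratio_bin_width,
        angle_bin_width=cfg.angle_bin_width,
        fiber_mask_factor=cfg.fiber_mask_factor,
    )
    _, fiber_mask = fiber_density(stack.mean_image(), factor=cfg.fiber_mask_factor)
    return PipelineResult(
        stack=stack, foreground=foreground, fit=fit, mol=mol,
        stats=stats, fiber_mask=fiber_mask,
    )
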