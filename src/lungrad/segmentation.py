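"""Deterministic 2-D lesion segmentation.

Mirrors a semi-automatic clinical workflow: pick the maximum-area slice,
initialize with an intensity window, then refine with a region-based
(piecewise-constant, Chan–Vese-type) or edge-based (geodesic) active contour.
Every stage ends with largest-connected-component selection and hole filling,
so the result is always a single filled lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import (
    inverse_gaussian_gradient,
    morphological_chan_vese,
    morphological_geodesic_active_contour,
)
from skimage.segmentation.morphsnakes import inf_sup, sup_inf

from .images import GrayImage, LesionMask


@dataclass(frozen=True)
class ContourParams:
    """Active-contour settings.

    method : "region" (two-phase piecewise-constant energy) or "edge"
        (evolution under an image-gradient stopping function).
    max_iter : iteration cap, >= 1.
    smoothing : curve-smoothing weight (mu); number of smoothing passes
        per iteration, >= 0.
    lambda1, lambda2 : region weights for inside/outside intensity deviation
        (region method only).
    edge_sensitivity : steepness of the inverse-gradient stopping function
        (edge method only); larger tracks weaker edges less.
    tol : convergence threshold, fraction of pixels changed per iteration.
    """

    method: str = "region"
    max_iter: int = 100
    smoothing: int = 1
    lambda1: float = 1.0
    lambda2: float = 1.0
    edge_sensitivity: float = 200.0
    tol: float = 1e-4

    def __post_init__(self):
        if self.method not in ("region", "edge"):
            raise ValueError(f"unknown method '{self.method}'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if min(self.smoothing, self.lambda1, self.lambda2) < 0:
            raise ValueError("weights must be >= 0")


def max_area_slice(mask_stack: list[LesionMask]) -> int:
    """Index of the mask with the largest pixel area; ties go to the smallest index."""
    if not mask_stack:
        raise ValueError("mask stack is empty")
    areas = [m.area_px for m in mask_stack]
    if max(areas) == 0:
        raise ValueError("all masks in the stack are empty")
    return int(np.argmax(areas))


def _single_filled_component(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component and fill its holes."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(largest)


def threshold_mask(image: GrayImage, low: float, high: float) -> LesionMask:
    """Window the image to [low, high], keep the largest component, fill holes.

    An empty window yields an empty mask (the caller decides how to react).
    """
    if low > high:
        raise ValueError(f"low ({low}) must not exceed high ({high})")
    raw = (image.pixels >= low) & (image.pixels <= high)
    return LesionMask(_single_filled_component(raw), image.spacing)


def refine_active_contour(
    image: GrayImage, init: LesionMask, params: ContourParams
) -> LesionMask:
    """Refine an initial mask with a region- or edge-based active contour.

    The evolution stops at ``max_iter`` or when the fraction of pixels that
    changed in one iteration drops below ``tol``; the result is reduced to a
    single filled component.  Raises if the contour collapses to nothing.
    """
    if init.area_px == 0:
        raise ValueError("initial mask is empty")
    img = image.pixels.astype(float)
    # normalize to [0, 1] for stable energy weights across intensity scales
    lo, hi = img.min(), img.max()
    img_n = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)

    if params.method == "edge":
        gimage = inverse_gaussian_gradient(img_n, alpha=params.edge_sensitivity, sigma=1.0)

    # Step one iteration at a time so the changed-pixel stopping rule applies.
    # Curvature smoothing (the alternating sup-inf/inf-sup morphological
    # operators) is applied here with a locally tracked alternation phase:
    # the library routine keeps that phase in module-global state, which
    # would make results depend on unrelated earlier calls in the process.
    level_set = init.pixels.astype(np.uint8)
    n_px = level_set.size
    for it in range(params.max_iter):
        if params.method == "region":
            new = morphological_chan_vese(
                img_n,
                num_iter=1,
                init_level_set=level_set,
                smoothing=0,
                lambda1=params.lambda1,
                lambda2=params.lambda2,
            )
        else:
            new = morphological_geodesic_active_contour(
                gimage,
                num_iter=1,
                init_level_set=level_set,
                smoothing=0,
                balloon=0,
            )
        new = np.asarray(new, dtype=np.uint8)
        for s in range(int(params.smoothing)):
            if (it + s) % 2 == 0:
                new = sup_inf(inf_sup(new))
            else:
                new = inf_sup(sup_inf(new))
        new = np.asarray(new, dtype=np.uint8)
        changed = np.count_nonzero(new != level_set)
        level_set = new
        if changed / n_px < params.tol:
            break
    final = _single_filled_component(level_set.astype(bool))
    if not final.any():
        raise RuntimeError("contour collapsed")
    return LesionMask(final, image.spacing)


def dice(a: LesionMask, b: LesionMask) -> float:
    """Dice overlap 2|a∩b|/(|a|+|b|); two empty masks agree perfectly (1.0)."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    pa, pb = a.pixels, b.pixels
    denom = pa.sum() + pb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(pa, pb).sum() / denom
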