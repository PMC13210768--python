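"""Focus stacking: fuse a z-stack into one extended-depth-of-field image.

The fusion rule is per-pixel selection of the plane with maximal local
Laplacian energy (sum of the squared discrete Laplacian over a square
window), optionally after Gaussian smoothing of the decision maps to
suppress speckle in plane selection. Ties break toward the lowest plane
index, i.e. the plane nearest the filter surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import InputError, ParameterError
from .synth import ZStack

__all__ = ["SharpnessMap", "CompositeImage", "sharpness_map", "focus_stack"]


@dataclass
class SharpnessMap:
    """Per-plane, per-pixel sharpness scores (non-negative)."""

    scores: np.ndarray  # (n_planes, H, W)
    window_radius: int


@dataclass
class CompositeImage:
    """An extended-depth-of-field composite with per-pixel provenance."""

    raster: np.ndarray  # (H, W)
    pixel_size: float
    provenance: np.ndarray  # (H, W) source plane index per pixel


def sharpness_map(stack: ZStack, window_radius: int = 4) -> SharpnessMap:
    """Local Laplacian energy of every plane.

    For each pixel the score is the sum of the squared 4-neighbour discrete
    Laplacian over the (2r+1) x (2r+1) window centred on it. Constant
    planes score zero everywhere, and the score is invariant to adding a
    constant offset to a plane.
    """
    if window_radius < 1:
        raise ParameterError("window_radius must be >= 1")
    if stack.n_planes == 0:
        raise InputError("empty stack")
    size = 2 * int(window_radius) + 1
    scores = np.empty_like(stack.planes, dtype=np.float64)
    for j in range(stack.n_planes):
        lap = ndi.laplace(stack.planes[j].astype(np.float64), mode="nearest")
        scores[j] = ndi.uniform_filter(lap * lap, size=size, mode="nearest") * size**2
    return SharpnessMap(scores=np.clip(scores, 0.0, None), window_radius=int(window_radius))


def focus_stack(
    stack: ZStack, window_radius: int = 4, smooth_radius: float = 2.0
) -> CompositeImage:
    """Fuse a stack into a composite by per-pixel maximal sharpness.

    ``smooth_radius`` (pixels) is the sigma of a Gaussian applied to each
    plane's sharpness map before the argmax; 0 disables smoothing, in which
    case the result equals the brute-force per-pixel argmax selection. A
    single-plane stack is returned unchanged.
    """
    if stack.n_planes == 0:
        raise InputError("empty stack")
    if stack.n_planes == 1:
        return CompositeImage(
            raster=np.array(stack.planes[0], dtype=np.float64),
            pixel_size=stack.pixel_size,
            provenance=np.zeros(stack.planes[0].shape, dtype=np.intp),
        )
    scores = sharpness_map(stack, window_radius).scores
    if smooth_radius > 0:
        for j in range(len(scores)):
            scores[j] = ndi.gaussian_filter(scores[j], smooth_radius, mode="nearest")
    provenance = np.argmax(scores, axis=0)  # ties -> lowest plane index
    raster = np.take_along_axis(
        stack.planes.astype(np.float64), provenance[None, :, :], axis=0
    )[0]
    return CompositeImage(raster=raster, pixel_size=stack.pixel_size, provenance=provenance)
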