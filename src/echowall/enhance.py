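"""Speckle-robust enhancement of the located region.

Two steps, in order: non-local means (NLM) denoising, then grayscale
morphological opening. NLM replaces each pixel with a weighted average of
the pixels in its search window; the weight of a candidate pixel is

    w(i, j) = exp(-||P(i) - P(j)||_a^2 / h^2) / Z(i)

where ``||.||_a^2`` is the Gaussian-weighted (std ``a``, kernel normalized
to sum 1) mean of squared differences between the two patches, ``h`` is the
filtering intensity, and ``Z(i)`` normalizes the weights to sum exactly 1.
The center pixel participates like any other candidate (its
pre-normalization weight is 1). Borders are handled by reflection padding.

Opening (erosion then dilation) removes isolated bright glitches and thin
bright bridges while leaving the large-scale wall shape unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import ParameterError, as_echo_image


@dataclass
class NlmParams:
    """patch_size 7, search_size 21, h 8 suit echo-like speckle while
    preserving wall-edge detail; ``a`` (Gaussian std of the patch norm, in
    pixels) is a free smoothing knob — ``inf`` gives uniform patch
    weighting."""

    patch_size: int = 7
    search_size: int = 21
    h: float = 8.0
    a: float = 1.5

    def validate(self) -> None:
        if self.patch_size % 2 == 0 or self.search_size % 2 == 0:
            raise ParameterError("patch_size and search_size must be odd")
        if self.patch_size > self.search_size:
            raise ParameterError(
                f"patch_size ({self.patch_size}) must be <= search_size "
                f"({self.search_size})")
        if self.h <= 0:
            raise ParameterError(f"h ({self.h}) must be > 0")
        if not self.a > 0:
            raise ParameterError(f"a ({self.a}) must be > 0")


def _patch_kernel_1d(params: NlmParams) -> np.ndarray:
    p = params.patch_size
    ax = np.arange(-(p // 2), p // 2 + 1, dtype=float)
    if np.isinf(params.a):
        g = np.ones(p)
    else:
        g = np.exp(-(ax**2) / (2.0 * params.a**2))
    return g / g.sum()


def patch_kernel(params: NlmParams) -> np.ndarray:
    """The normalized Gaussian patch-weighting kernel (sums to 1).

    Separable by construction: the outer product of two normalized 1-D
    Gaussians."""
    g = _patch_kernel_1d(params)
    return np.outer(g, g)


def _padded(image: np.ndarray, params: NlmParams) -> tuple[np.ndarray, int]:
    margin = params.search_size // 2 + params.patch_size // 2
    return np.pad(image.astype(np.float64), margin, mode="reflect"), margin


def nlm_filter(image: np.ndarray, params: NlmParams | None = None,
               *, quantize: bool = True) -> np.ndarray:
    """Non-local means denoising of an 8-bit grayscale image.

    The per-offset distance maps are computed with a separable Gaussian
    correlation, so the cost is O(pixels x search_size^2 x patch_size)
    rather than the quadruple loop of the defining formula. With
    ``quantize`` the result is rounded half-up back to uint8.
    """
    params = params or NlmParams()
    params.validate()
    image = as_echo_image(image)
    h_img, w_img = image.shape
    if h_img < params.patch_size or w_img < params.patch_size:
        raise ParameterError("image smaller than the patch size")

    pad, m = _padded(image, params)
    half_s = params.search_size // 2
    half_p = params.patch_size // 2
    g1 = _patch_kernel_1d(params)
    h2 = params.h ** 2

    # region around the core needed for patch correlation
    u0 = m - half_p
    u = pad[u0:u0 + h_img + 2 * half_p, u0:u0 + w_img + 2 * half_p]
    num = np.zeros((h_img, w_img))
    den = np.zeros((h_img, w_img))
    for dr in range(-half_s, half_s + 1):
        for dc in range(-half_s, half_s + 1):
            v = pad[u0 + dr:u0 + dr + h_img + 2 * half_p,
                    u0 + dc:u0 + dc + w_img + 2 * half_p]
            sq = (u - v) ** 2
            dist = ndimage.correlate1d(sq, g1, axis=0)
            dist = ndimage.correlate1d(dist, g1, axis=1)
            dist = dist[half_p:half_p + h_img, half_p:half_p + w_img]
            w = np.exp(-dist / h2)
            num += w * pad[m + dr:m + dr + h_img, m + dc:m + dc + w_img]
            den += w
    out = num / den
    if quantize:
        return np.floor(out + 0.5).astype(np.uint8)
    return out


def nlm_weights(image: np.ndarray, params: NlmParams,
                center: tuple[int, int]) -> np.ndarray:
    """Normalized NLM weights of one pixel over its search window.

    Returns a ``(search_size, search_size)`` array summing to 1 — the
    diagnostic counterpart of :func:`nlm_filter` for verifying the weight
    normalization pixel by pixel.
    """
    params.validate()
    image = as_echo_image(image)
    pad, m = _padded(image, params)
    r, c = center
    half_s = params.search_size // 2
    half_p = params.patch_size // 2
    kern = patch_kernel(params)
    pr, pc = r + m, c + m
    ref = pad[pr - half_p:pr + half_p + 1, pc - half_p:pc + half_p + 1]
    w = np.empty((params.search_size, params.search_size))
    for i, dr in enumerate(range(-half_s, half_s + 1)):
        for j, dc in enumerate(range(-half_s, half_s + 1)):
            cand = pad[pr + dr - half_p:pr + dr + half_p + 1,
                       pc + dc - half_p:pc + dc + half_p + 1]
            dist = float((kern * (ref - cand) ** 2).sum())
            w[i, j] = np.exp(-dist / params.h**2)
    return w / w.sum()


# ---------------------------------------------------------------------------
# morphology


@dataclass(frozen=True)
class StructuringElement:
    """Binary mask plus origin. The pipeline default is a full 3x3 square
    with the origin at its center."""

    mask: tuple[tuple[int, ...], ...] = ((1, 1, 1), (1, 1, 1), (1, 1, 1))
    origin: tuple[int, int] = (1, 1)

    def __post_init__(self):
        arr = np.asarray(self.mask, dtype=bool)
        if arr.ndim != 2 or not arr.any():
            raise ParameterError("structuring element mask must be a non-empty 2-D grid")
        r, c = self.origin
        if not (0 <= r < arr.shape[0] and 0 <= c < arr.shape[1]):
            raise ParameterError(f"origin {self.origin} outside mask of shape {arr.shape}")

    @property
    def footprint(self) -> np.ndarray:
        return np.asarray(self.mask, dtype=bool)

    @property
    def ndimage_origin(self) -> tuple[int, int]:
        """scipy.ndimage origin offsets (relative to the footprint center)."""
        fp = self.footprint
        return (self.origin[0] - fp.shape[0] // 2,
                self.origin[1] - fp.shape[1] // 2)

    @classmethod
    def square(cls, side: int) -> "StructuringElement":
        if side < 1:
            raise ParameterError("side must be >= 1")
        return cls(tuple(tuple(1 for _ in range(side)) for _ in range(side)),
                   (side // 2, side // 2))


def erode(image: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """Neighborhood minimum under the element (grayscale erosion)."""
    se = se or StructuringElement()
    return ndimage.grey_erosion(image, footprint=se.footprint,
                                origin=se.ndimage_origin, mode="reflect")


def dilate(image: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """Neighborhood maximum under the reflected element (grayscale
    dilation), the adjoint of :func:`erode`."""
    se = se or StructuringElement()
    fp = se.footprint[::-1, ::-1]
    # reflecting the footprint flips the origin offset; for even sizes the
    # center index also moves, handled by recomputing from the flipped mask
    orow = (se.footprint.shape[0] - 1 - se.origin[0]) - fp.shape[0] // 2
    ocol = (se.footprint.shape[1] - 1 - se.origin[1]) - fp.shape[1] // 2
    return ndimage.grey_dilation(image, footprint=fp, origin=(orow, ocol),
                                 mode="reflect")


def opening(image: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """Erosion followed by dilation; removes isolated bright glitches and
    thin bright bridges while preserving the overall shape."""
    se = se or StructuringElement()
    return dilate(erode(image, se), se)
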