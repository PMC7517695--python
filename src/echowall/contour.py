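"""Posterior-wall contour extraction by two-stage threshold segmentation.

Stage one segments the enhanced region with a *prior* gray range — the
analyst's knowledge of which intensities the wall occupies — and keeps the
largest 8-connected component. Stage two re-estimates the threshold by
Otsu's inter-class-variance criterion inside a small sampling window
automatically placed on each initially segmented edge (one adjustment for
the upper edge, one for the lower), clamping the result back into the
prior range. The final upper/lower contours are the per-column minimum and
maximum rows of the re-segmented component, which makes them continuous
(exactly one point per spanned column) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label

from .types import ContourPoint, ParameterError, RoiWindow, StageError, as_echo_image


@dataclass(frozen=True)
class PriorRange:
    """Inclusive gray range the wall is expected to occupy.

    The defaults [100, 255] are calibrated on phantoms: after opening, the
    speckled tissue background stays below ~75 while the wall stays above
    ~110, so 100 separates them with margin on both sides. Clinical frames
    need their own prior analysis.
    """

    gray_min: int = 100
    gray_max: int = 255

    def __post_init__(self):
        if not (0 <= self.gray_min < self.gray_max <= 255):
            raise ParameterError(
                f"prior range [{self.gray_min}, {self.gray_max}] must satisfy "
                f"0 <= min < max <= 255")


@dataclass(frozen=True)
class OtsuStats:
    """Threshold statistics at the optimum: class proportions (w0, w1),
    class means (mu0, mu1), global mean mu, and the inter-class variance g
    = w0*w1*(mu0-mu1)^2."""

    T: int
    w0: float
    w1: float
    mu0: float
    mu1: float
    mu: float
    g: float


def otsu_threshold(pixels: np.ndarray) -> tuple[int, OtsuStats]:
    """Smallest intensity T' maximizing the inter-class variance.

    Class 0 is intensity <= T, class 1 is intensity > T; the variance is
    evaluated at all 256 candidate levels and the smallest argmax wins.
    Raises on a constant input (degenerate histogram).
    """
    values = as_echo_image(np.atleast_2d(np.asarray(pixels))).ravel()
    hist = np.bincount(values, minlength=256).astype(float)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise StageError("otsu", "degenerate histogram: fewer than 2 distinct values")
    p = hist / n
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * levels)
    mu = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, cum_mean / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu - cum_mean) / w1, 0.0)
    g = w0 * w1 * (mu0 - mu1) ** 2
    t = int(np.argmax(g))          # first (smallest) maximizer
    stats = OtsuStats(T=t, w0=float(w0[t]), w1=float(w1[t]),
                      mu0=float(mu0[t]), mu1=float(mu1[t]),
                      mu=float(mu), g=float(g[t]))
    return t, stats


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected True component of a binary mask (empty-safe)."""
    lab, n = label(mask, connectivity=2, return_num=True)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def prior_segment(image: np.ndarray, prior: PriorRange) -> np.ndarray:
    """Binary mask of the prior gray range, reduced to its largest
    8-connected component."""
    image = as_echo_image(image)
    mask = (image >= prior.gray_min) & (image <= prior.gray_max)
    comp = largest_component(mask)
    if not comp.any():
        raise StageError("segment", "no wall candidate in the prior gray range")
    return comp


def _edge_points(comp: np.ndarray, which: str) -> list[ContourPoint]:
    cols = np.flatnonzero(comp.any(axis=0))
    pts = []
    for c in cols:
        rows = np.flatnonzero(comp[:, c])
        r = rows.min() if which == "upper" else rows.max()
        pts.append(ContourPoint(int(r), int(c)))
    return pts


def extract_contours(mask: np.ndarray,
                     min_span: int = 10) -> tuple[list[ContourPoint], list[ContourPoint]]:
    """Upper (per-column min row) and lower (max row) contours of the
    retained component, in increasing-column order."""
    comp = largest_component(np.asarray(mask, dtype=bool))
    if not comp.any():
        raise StageError("contour", "empty mask: nothing to trace")
    span = int(comp.any(axis=0).sum())
    if span < min_span:
        raise StageError("contour", f"contour too short: component spans "
                         f"{span} columns (< {min_span})")
    return _edge_points(comp, "upper"), _edge_points(comp, "lower")


def contours_to_json(upper: list[ContourPoint],
                     lower: list[ContourPoint]) -> dict[str, list[list[int]]]:
    """Contours as JSON-ready lists of [row, col] pairs."""
    return {"upper": [[p.row, p.col] for p in upper],
            "lower": [[p.row, p.col] for p in lower]}


def select_sampling_window(edge: list[ContourPoint], image_shape: tuple[int, int],
                           side: int = 31) -> RoiWindow:
    """Square window centered on the edge's median point (middle element in
    column order), clipped to the image."""
    if not edge:
        raise ParameterError("edge must be non-empty")
    pts = sorted(edge, key=lambda p: p.col)
    mid = pts[len(pts) // 2]
    h, w = image_shape[:2]
    half = (side - 1) // 2
    r0 = int(np.clip(mid.row - half, 0, max(0, h - side)))
    c0 = int(np.clip(mid.col - half, 0, max(0, w - side)))
    return RoiWindow(r0, c0, min(side, h, w))


def refine_threshold(image: np.ndarray, initial_mask: np.ndarray,
                     prior: PriorRange, side: int = 31,
                     passes: int = 1) -> tuple[int, int]:
    """Otsu re-adjustment of the segmentation threshold, once per edge.

    Runs :func:`otsu_threshold` in a sampling window on the initially
    segmented upper edge and again on the lower edge — the two threshold
    adjustments — clamping each result into the prior range. A degenerate
    (constant) window keeps the prior lower bound. With ``passes`` = 2 each
    edge's window is re-centered on the re-segmented edge and Otsu is run a
    second time (the alternate reading of "adjusted twice").

    Returns ``(upper_threshold, lower_threshold)``.
    """
    image = as_echo_image(image)
    results = []
    for which in ("upper", "lower"):
        thr = prior.gray_min
        mask = np.asarray(initial_mask, dtype=bool)
        for _ in range(max(1, passes)):
            comp = largest_component(mask)
            if not comp.any():
                break
            edge = _edge_points(comp, which)
            win = select_sampling_window(edge, image.shape, side)
            sample = win.extract(image)
            try:
                t, _ = otsu_threshold(sample)
            except StageError:
                break                      # degenerate window: keep prior bound
            thr = int(np.clip(t, prior.gray_min, prior.gray_max))
            mask = (image >= thr) & (image <= prior.gray_max)
        results.append(thr)
    return results[0], results[1]


def segment_wall(image: np.ndarray, prior: PriorRange, side: int = 31,
                 passes: int = 1,
                 min_span: int = 10) -> tuple[list[ContourPoint], list[ContourPoint], dict]:
    """Full two-stage extraction: prior segmentation, per-edge Otsu
    refinement, final contours.

    Returns (upper, lower, diagnostics)."""
    image = as_echo_image(image)
    initial = prior_segment(image, prior)
    t_up, t_lo = refine_threshold(image, initial, prior, side, passes)
    upper_mask = largest_component((image >= t_up) & (image <= prior.gray_max))
    lower_mask = largest_component((image >= t_lo) & (image <= prior.gray_max))
    if not upper_mask.any() or not lower_mask.any():
        raise StageError("segment", "refined threshold removed every pixel")
    upper, _ = extract_contours(upper_mask, min_span)
    _, lower = extract_contours(lower_mask, min_span)
    diag = {"threshold_upper": t_up, "threshold_lower": t_lo,
            "initial_area": int(initial.sum())}
    return upper, lower, diag
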