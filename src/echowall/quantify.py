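"""Thickness quantification and scale-bar calibration.

Pixel thickness ``d``: measurement points are the intersections of the
*lower* wall contour with a group of 45-degree lines ``r + c = b`` at
evenly spaced intercepts (window-local coordinates; the processing window
is the located 200x200 region). Each point's Euclidean distance to the
nearest pixel of the *upper* contour enters a reference distance group;
after dropping one maximum and one minimum, the mean of the rest is ``d``.

Calibration: the on-screen ruler is found by low-gray binarization, then
length and area screening of the connected segments; the surviving ticks
give the pixel pitch ``l`` of one scale unit, and the normalized scale is
``k = unit_mm / l`` (mm per pixel). The reported thickness is
``LVPWT = k x d`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage.measure import label, regionprops

from .types import ContourPoint, ParameterError, StageError, as_echo_image


class SelectedPoint(NamedTuple):
    """A measurement point on the lower contour plus the intercept of the
    45-degree line that produced it."""

    row: int
    col: int
    intercept: int


@dataclass(frozen=True)
class PointSelectionParams:
    """45-degree line group: intercepts start, start+step, ...,
    start+(n-1)*step within the 200x200 processing window. ``orientation``
    selects the line family: "sum" means r + c = b (slope -1 on screen,
    i.e. a 45-degree line), "diff" means r - c = b."""

    intercept_start: int = 140
    n_points: int = 10
    intercept_step: int = 5
    orientation: str = "sum"

    def intercepts(self) -> list[int]:
        return [self.intercept_start + i * self.intercept_step
                for i in range(self.n_points)]


@dataclass(frozen=True)
class ScaleResult:
    """Detected ruler pitch ``l`` (pixels per scale unit) and normalized
    scale ``k = unit_mm / l`` (mm per pixel)."""

    l: float
    unit_mm: float = 10.0

    @property
    def k(self) -> float:
        return self.unit_mm / self.l


@dataclass
class MeasurementReport:
    """End-to-end result: pixel distance d, scale k, LVPWT = k*d in mm, the
    hypertrophy call against the configured cutoff, and per-stage
    diagnostics."""

    d_px: float | None = None
    l_px: float | None = None
    k_mm_per_px: float | None = None
    lvpwt_mm: float | None = None
    lvh_positive: bool | None = None
    cutoff_mm: float | None = None
    n_points_used: int | None = None
    distances: list[float] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    failure: str | None = None

    def to_dict(self) -> dict:
        return {
            "d_px": self.d_px, "l_px": self.l_px,
            "k_mm_per_px": self.k_mm_per_px, "lvpwt_mm": self.lvpwt_mm,
            "lvh_positive": self.lvh_positive, "cutoff_mm": self.cutoff_mm,
            "n_points_used": self.n_points_used, "distances": self.distances,
            "diagnostics": self.diagnostics, "failure": self.failure,
        }


def select_lower_points(lower: list[ContourPoint],
                        params: PointSelectionParams | None = None) -> list[SelectedPoint]:
    """Intersections of the lower contour with the 45-degree line group.

    A contour pixel with ``row + col == b`` (or ``row - col == b`` for the
    "diff" orientation) is an intersection; intercepts with no hit
    contribute no point; multiple hits on one line keep the smallest
    column.
    """
    params = params or PointSelectionParams()
    if not lower:
        raise ParameterError("lower contour must be non-empty")
    key = ((lambda p: p.row + p.col) if params.orientation == "sum"
           else (lambda p: p.row - p.col))
    points = []
    for b in params.intercepts():
        hits = sorted((p for p in lower if key(p) == b), key=lambda p: p.col)
        if hits:
            points.append(SelectedPoint(hits[0].row, hits[0].col, b))
    return points


def filter_degenerate_points(points: list[SelectedPoint],
                             lower: list[ContourPoint],
                             orientation: str = "sum") -> list[SelectedPoint]:
    """Drop points whose 45-degree line threads between contour pixels.

    In a 2x2 pixel block a contour can occupy only the block diagonal, so
    that a line of intermediate intercept crosses the contour without
    landing on any pixel. A point is kept iff some contour pixel in the
    2x2 block anchored at the point lies exactly on the point's line.
    """
    contour_set = {(p.row, p.col) for p in lower}
    key = ((lambda r, c: r + c) if orientation == "sum"
           else (lambda r, c: r - c))
    kept = []
    for pt in points:
        block = [(pt.row + dr, pt.col + dc) for dr in (0, 1) for dc in (0, 1)]
        if any(q in contour_set and key(*q) == pt.intercept for q in block):
            kept.append(pt)
    return kept


def nearest_distance(point: tuple[int, int], upper: list[ContourPoint]) -> float:
    """Euclidean distance from the point to the nearest upper-contour pixel."""
    if not upper:
        raise ParameterError("upper contour must be non-empty")
    arr = np.asarray(upper, dtype=float)
    d = np.hypot(arr[:, 0] - point[0], arr[:, 1] - point[1])
    return float(d.min())


def trimmed_mean_distance(distances: list[float]) -> float:
    """Mean after removing one occurrence each of the max and the min.

    With one or two values the plain mean is returned; an empty group is
    an error (no valid measurement points survived).
    """
    if len(distances) == 0:
        raise StageError("distance", "no valid measurement points")
    ds = sorted(float(d) for d in distances)
    if any(not np.isfinite(d) or d < 0 for d in ds):
        raise ParameterError("distances must be finite and non-negative")
    if len(ds) >= 3:
        ds = ds[1:-1]
    return float(np.mean(ds))


@dataclass(frozen=True)
class ScaleDetectParams:
    """Ruler screening thresholds: binarize at ``low_gray``, keep segments
    whose length (largest bounding-box extent) lies in
    [length_min, length_max] and whose area is <= area_max, then keep the
    largest column-aligned group of survivors (the ruler is a vertical
    stack of ticks; stray bright fragments elsewhere do not line up)."""

    low_gray: int = 140
    length_min: float = 2.0
    length_max: float = 12.0
    area_max: float = 60.0
    unit_mm: float = 10.0
    align_tol_px: float = 2.0

    def __post_init__(self):
        if not self.length_min < self.length_max:
            raise ParameterError("length_min must be < length_max")


def detect_scale(image: np.ndarray,
                 params: ScaleDetectParams | None = None) -> ScaleResult:
    """Find the ruler ticks and return the pixel pitch of one scale unit.

    Binarizes at ``low_gray``, screens connected segments by length and
    area, groups the survivors by centroid column and keeps the largest
    aligned group, then takes ``l`` as the median gap between consecutive
    tick centers along the ruler axis.
    """
    params = params or ScaleDetectParams()
    image = as_echo_image(image)
    mask = image >= params.low_gray
    lab = label(mask, connectivity=2)
    ticks = []
    for region in regionprops(lab):
        r0, c0, r1, c1 = region.bbox
        length = max(r1 - r0, c1 - c0)
        if params.length_min <= length <= params.length_max \
                and region.area <= params.area_max:
            ticks.append(region.centroid)
    if len(ticks) < 2:
        raise StageError("scale", "scale not found: fewer than 2 candidate ticks")

    # the ruler is the largest column-aligned stack of ticks
    ticks = sorted(ticks, key=lambda t: t[1])
    groups: list[list[tuple[float, float]]] = []
    for t in ticks:
        if groups and abs(t[1] - np.mean([u[1] for u in groups[-1]])) <= params.align_tol_px:
            groups[-1].append(t)
        else:
            groups.append([t])
    ruler = max(groups, key=len)
    if len(ruler) < 2:
        raise StageError("scale", "scale not found: no aligned tick column")
    rows = np.sort([t[0] for t in ruler])
    gaps = np.diff(rows)
    l = float(np.median(gaps))
    if l <= 0:
        raise StageError("scale", "scale not found: non-positive tick pitch")
    return ScaleResult(l=l, unit_mm=params.unit_mm)


def lvpwt(k: float, d: float) -> float:
    """LVPWT = k x d, in mm, reported to 2 decimals."""
    if k <= 0 or d <= 0:
        raise ParameterError(f"k ({k}) and d ({d}) must be > 0")
    return round(k * d, 2)


def relative_error(measured_mm: float, reference_mm: float) -> float:
    """100 x |measured - reference| / reference, % to 2 decimals."""
    if reference_mm <= 0:
        raise ParameterError(f"reference ({reference_mm}) must be > 0")
    return round(100.0 * abs(measured_mm - reference_mm) / reference_mm, 2)


def classify_lvh(lvpwt_mm: float, cutoff_mm: float) -> bool:
    """Hypertrophy call: strictly thicker than the clinical cutoff.

    No universal cutoff ships with the method; the pipeline default of
    11 mm is an external clinical convention supplied by configuration.
    """
    if cutoff_mm is None or cutoff_mm <= 0:
        raise ParameterError("a positive cutoff_mm must be configured")
    return lvpwt_mm > cutoff_mm
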