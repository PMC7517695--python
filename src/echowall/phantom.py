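"""Synthetic echocardiogram phantoms with known ground truth.

Clinical echo data are private, so every downstream stage of the pipeline is
exercised on phantoms that emulate the relevant structure of a B-mode still:

* a dark background with a bright circular *sector* (the imaged fan),
* a bright band of known, constant vertical thickness — the stand-in for the
  left-ventricular posterior wall — at a gray level well above the
  surrounding tissue speckle,
* multiplicative speckle noise (mean-1 Gaussian factor, clipped to 8-bit),
* a ruler of evenly spaced ticks of known pixel pitch on the right margin,
  drawn as an overlay *after* speckling, as device graphics are.

Every random draw flows through one ``numpy.random.default_rng(seed)`` per
call, so identical parameters and seed give bit-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .types import ParameterError, RoiWindow

#: Gray level of the non-anatomical area outside the sector.
OUTSIDE_GRAY = 5
#: Sector apex row (apex sits above the image top edge looks unnatural; a
#: small inset keeps the fan fully visible).
SECTOR_APEX_ROW = 10.0
#: Sector half-opening angle, degrees from the vertical.
SECTOR_HALF_ANGLE_DEG = 35.0
#: Ruler tick geometry: 1 row tall, 3 columns wide, drawn at full intensity.
TICK_HALF_WIDTH = 1
TICK_GRAY = 255
TICK_TOP_ROW = 40
TICK_BOTTOM_MARGIN = 20


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic phantom.

    Defaults describe a mid-sized adult parasternal view scanned at roughly
    0.4 mm/px: a 20 px (8 mm) wall on a 600x800 frame with moderate speckle.
    """

    image_height: int = 600
    image_width: int = 800
    band_upper_row: int = 380
    band_thickness_px: int = 20
    band_tilt_deg: float = 0.0
    band_halfwidth_px: int = 130
    band_gray: int = 200
    background_gray: int = 60
    speckle_sigma: float = 0.2
    ruler_pitch_px: int = 25
    ruler_col: int | None = None
    mm_per_scale_unit: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.background_gray < self.band_gray <= 255):
            raise ParameterError(
                f"band_gray ({self.band_gray}) must exceed background_gray "
                f"({self.background_gray}) and lie in 0..255")
        if not (0 < self.band_thickness_px < self.image_height):
            raise ParameterError(
                f"band_thickness_px ({self.band_thickness_px}) must lie in "
                f"(0, image_height)")
        if self.ruler_pitch_px < 2:
            raise ParameterError(f"ruler_pitch_px ({self.ruler_pitch_px}) must be >= 2")
        if self.image_height < 200 or self.image_width < 200:
            raise ParameterError("image must host at least one 200x200 window")
        if self.speckle_sigma < 0:
            raise ParameterError(f"speckle_sigma ({self.speckle_sigma}) must be >= 0")
        if self.mm_per_scale_unit <= 0:
            raise ParameterError("mm_per_scale_unit must be > 0")
        lower = self.band_upper_row + self.band_thickness_px
        if self.band_upper_row < 0 or lower > self.image_height:
            raise ParameterError("band_upper_row: band does not fit in the image")

    @property
    def effective_ruler_col(self) -> int:
        return self.image_width - 30 if self.ruler_col is None else self.ruler_col


@dataclass(frozen=True)
class PhantomGroundTruth:
    """What the generator actually drew, for parameter-recovery checks."""

    true_thickness_mm: float
    true_thickness_px: int
    mm_per_px: float
    band_bounding_box: RoiWindow
    ruler_pitch_px: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_bounding_box"] = {
            "row": self.band_bounding_box.row,
            "col": self.band_bounding_box.col,
            "side": self.band_bounding_box.side,
        }
        return d


def _sector_mask(h: int, w: int) -> np.ndarray:
    rows = np.arange(h)[:, None] - SECTOR_APEX_ROW
    cols = np.arange(w)[None, :] - (w - 1) / 2.0
    radius = h - 40.0
    dist = np.hypot(rows, cols)
    half = np.tan(np.deg2rad(SECTOR_HALF_ANGLE_DEG))
    inside = (dist <= radius) & (rows > 0) & (np.abs(cols) <= rows * half)
    return inside


def band_edges(params: PhantomParams, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower band-edge rows (inclusive) at the given columns."""
    cc = (params.image_width - 1) / 2.0
    slope = np.tan(np.deg2rad(params.band_tilt_deg))
    upper = np.rint(params.band_upper_row + slope * (cols - cc)).astype(int)
    return upper, upper + params.band_thickness_px - 1


def generate_phantom(params: PhantomParams) -> tuple[np.ndarray, PhantomGroundTruth]:
    """Render one phantom and its ground truth.

    Returns the 8-bit grayscale image and a :class:`PhantomGroundTruth`
    whose ``band_bounding_box`` is the 200x200 window centered on the band
    (the target any correct localizer should find).
    """
    params.validate()
    h, w = params.image_height, params.image_width
    rng = np.random.default_rng(params.seed)

    canvas = np.full((h, w), float(OUTSIDE_GRAY))
    sector = _sector_mask(h, w)
    canvas[sector] = float(params.background_gray)

    cc = (w - 1) / 2.0
    c0 = max(0, int(round(cc)) - params.band_halfwidth_px)
    c1 = min(w - 1, int(round(cc)) + params.band_halfwidth_px)
    cols = np.arange(c0, c1 + 1)
    upper, lower = band_edges(params, cols)
    rr = np.arange(h)[:, None]
    in_band = (rr >= upper[None, :]) & (rr <= lower[None, :])
    band_mask = np.zeros((h, w), dtype=bool)
    band_mask[:, c0:c1 + 1] = in_band & sector[:, c0:c1 + 1]
    canvas[band_mask] = float(params.band_gray)

    if params.speckle_sigma > 0:
        noise = 1.0 + params.speckle_sigma * rng.standard_normal((h, w))
        canvas = canvas * noise
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    # ruler overlay: device graphics are not subject to tissue speckle
    col = params.effective_ruler_col
    if not (TICK_HALF_WIDTH <= col < w - TICK_HALF_WIDTH):
        raise ParameterError(f"ruler_col ({col}) leaves no room for tick width")
    tick_rows = np.arange(TICK_TOP_ROW, h - TICK_BOTTOM_MARGIN, params.ruler_pitch_px)
    for r in tick_rows:
        image[r, col - TICK_HALF_WIDTH:col + TICK_HALF_WIDTH + 1] = TICK_GRAY

    mm_per_px = params.mm_per_scale_unit / params.ruler_pitch_px
    center_row = params.band_upper_row + (params.band_thickness_px - 1) / 2.0
    side = 200
    box_row = int(np.clip(round(center_row - (side - 1) / 2.0), 0, h - side))
    box_col = int(np.clip(round(cc - (side - 1) / 2.0), 0, w - side))
    gt = PhantomGroundTruth(
        true_thickness_mm=mm_per_px * params.band_thickness_px,
        true_thickness_px=params.band_thickness_px,
        mm_per_px=mm_per_px,
        band_bounding_box=RoiWindow(box_row, box_col, side),
        ruler_pitch_px=params.ruler_pitch_px,
    )
    return image, gt


def generate_patch_dataset(
    params: PhantomParams,
    n_pos: int,
    n_neg: int,
    *,
    crop_size: int = 200,
    out_size: int = 208,
    center_jitter: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled 208x208 patches for training the window classifier.

    Positives are ``crop_size`` crops centered (with small jitter) on the
    band; negatives are crops that do not intersect the band. Each phantom
    realization gets its own speckle, all derived from ``params.seed``.
    Crops are resized to ``out_size`` with bilinear interpolation.

    Returns ``(patches, labels)`` where ``patches`` is
    ``(n_pos+n_neg, out_size, out_size) uint8`` and ``labels`` is 1 for
    "target", 0 for "non-target".
    """
    if n_pos < 1 or n_neg < 1:
        raise ParameterError("n_pos and n_neg must each be >= 1")
    params.validate()
    h, w = params.image_height, params.image_width
    rng = np.random.default_rng(params.seed)

    center_row = params.band_upper_row + (params.band_thickness_px - 1) / 2.0
    center_col = (w - 1) / 2.0
    half = crop_size // 2
    if not (half - center_jitter <= center_row <= h - half + center_jitter - 1
            and half - center_jitter <= center_col <= w - half + center_jitter - 1):
        raise ParameterError("band too close to the border to crop a centered patch")

    patches = np.empty((n_pos + n_neg, out_size, out_size), dtype=np.uint8)
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])

    band_top = params.band_upper_row
    band_bot = params.band_upper_row + params.band_thickness_px - 1

    for i in range(n_pos + n_neg):
        child = PhantomParams(**{**asdict(params),
                                 "seed": int(rng.integers(0, 2**31 - 1))})
        image, _ = generate_phantom(child)
        if i < n_pos:
            jr, jc = rng.integers(-center_jitter, center_jitter + 1, size=2)
            r0 = int(np.clip(round(center_row - half + jr), 0, h - crop_size))
            c0 = int(np.clip(round(center_col - half + jc), 0, w - crop_size))
        else:
            # rejection-sample a window with no band overlap
            for _ in range(1000):
                r0 = int(rng.integers(0, h - crop_size + 1))
                c0 = int(rng.integers(0, w - crop_size + 1))
                if r0 + crop_size <= band_top or r0 > band_bot:
                    break
            else:
                raise ParameterError("could not place a band-free crop")
        crop = image[r0:r0 + crop_size, c0:c0 + crop_size]
        out = resize(crop.astype(float), (out_size, out_size), order=1,
                     preserve_range=True, anti_aliasing=False)
        patches[i] = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return patches, labels


def write_phantom(path: str | Path, image: np.ndarray, gt: PhantomGroundTruth,
                  seed: int | None = None) -> tuple[Path, Path]:
    """Write ``<path>.png`` (8-bit gray) and a JSON ground-truth sidecar."""
    path = Path(path)
    png = path.with_suffix(".png")
    sidecar = path.with_suffix(".json")
    iio.imwrite(png, image)
    payload = gt.to_dict()
    if seed is not None:
        payload["seed"] = seed
    sidecar.write_text(json.dumps(payload, indent=2))
    return png, sidecar
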