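"""Shared value types and error hierarchy.

An *EchoImage* throughout this package is a 2-D :class:`numpy.ndarray` of
``uint8`` grayscale intensities, indexed ``[row, col]`` with the origin at
the top-left corner (row grows downward, col grows rightward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np


class EchoWallError(Exception):
    """Base class for all package errors."""


class ParameterError(EchoWallError, ValueError):
    """A parameter violated an invariant; the message names the field."""


class StageError(EchoWallError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class RoiWindow:
    """Axis-aligned square sub-region of an image.

    Attributes
    ----------
    row, col : int
        Top-left corner (0-based).
    side : int
        Side length in pixels.
    probability : float or None
        Optional classifier probability of the target class.
    """

    row: int
    col: int
    side: int
    probability: float | None = None

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.side),
                slice(self.col, self.col + self.side))

    @property
    def center(self) -> tuple[float, float]:
        return (self.row + (self.side - 1) / 2.0,
                self.col + (self.side - 1) / 2.0)

    def extract(self, image: np.ndarray) -> np.ndarray:
        return image[self.slices]

    def iou(self, other: "RoiWindow") -> float:
        """Intersection-over-union with another square window."""
        r0 = max(self.row, other.row)
        c0 = max(self.col, other.col)
        r1 = min(self.row + self.side, other.row + other.side)
        c1 = min(self.col + self.side, other.col + other.side)
        inter = max(0, r1 - r0) * max(0, c1 - c0)
        union = self.side**2 + other.side**2 - inter
        return inter / union if union else 0.0


class ContourPoint(NamedTuple):
    """A pixel on a contour, (row, col)."""

    row: int
    col: int


def as_echo_image(image: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to the EchoImage convention."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ParameterError(f"image must be 2-D grayscale, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating) or np.issubdtype(arr.dtype, np.integer):
            arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
        else:
            raise ParameterError(f"image dtype {arr.dtype} is not intensity-like")
    return arr
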