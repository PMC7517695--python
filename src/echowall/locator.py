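"""Coarse localization of the posterior-wall region.

A 200x200 window slides over the frame at a 25 px step. Windows whose mean
gray falls below a threshold are discarded outright (they are
non-anatomical background), the survivors are resized to 208x208 and scored
by the CNN classifier, and the window with the highest target-class
probability wins (ties go to the smallest ``(row, col)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .cnn import EchoNet, LocatorConfig, conv_output_size  # noqa: F401 (re-export)
from .types import ParameterError, RoiWindow, StageError, as_echo_image


@dataclass
class TrainConfig:
    """SGD settings. The full-scale run uses 5000 iterations; scaled-down
    studies (and the test suite) use a few hundred, which is already enough
    to separate phantom target from non-target patches."""

    iterations: int = 5000
    batch_size: int = 20
    learning_rate: float = 1e-4
    momentum: float = 0.0
    seed: int = 0


@dataclass
class WindowScanParams:
    """Sliding-window traversal: 200 px windows, 25 px step; windows with
    mean gray strictly below ``gray_threshold`` are filtered before any
    probability prediction (typical thresholds: 50, or 70 for brighter
    acquisitions)."""

    window_side: int = 200
    step: int = 25
    gray_threshold: float = 50.0


def build_locator(config: LocatorConfig | None = None, seed: int = 0) -> EchoNet:
    """Construct the (untrained) window classifier with seeded init."""
    return EchoNet(config or LocatorConfig(), seed=seed)


def train_locator(
    model: EchoNet,
    patches: np.ndarray,
    labels: np.ndarray,
    train: TrainConfig | None = None,
) -> tuple[EchoNet, dict[str, list[float]]]:
    """Train in place; returns the model and a per-iteration history.

    ``patches`` is ``(N, S, S)`` uint8, ``labels`` 0/1. History records the
    mini-batch cross-entropy loss and accuracy at every iteration.
    """
    train = train or TrainConfig()
    patches = np.asarray(patches)
    labels = np.asarray(labels, dtype=int)
    if patches.ndim != 3 or len(patches) == 0:
        raise ParameterError("patches must be a non-empty (N, S, S) stack")
    if len(labels) != len(patches):
        raise ParameterError("labels length must match patches")
    if len(np.unique(labels)) < 2:
        raise ParameterError("training needs at least one patch per class")

    rng = np.random.default_rng(train.seed)
    n = len(patches)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    for _ in range(train.iterations):
        idx = rng.choice(n, size=min(train.batch_size, n), replace=n < train.batch_size)
        xb, yb = patches[idx], labels[idx]
        caches: list[dict] = [None] * 7  # type: ignore[list-item]
        probs = model.forward(xb, training=True, rng=rng, caches=caches)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + eps)))
        acc = float(np.mean(probs.argmax(axis=1) == yb))
        model.backward(probs, yb, caches)
        model.sgd_step(train.learning_rate, train.momentum)
        history["loss"].append(loss)
        history["accuracy"].append(acc)
    return model, history


def evaluate_accuracy(model: EchoNet, patches: np.ndarray, labels: np.ndarray) -> float:
    """Inference-mode classification accuracy on a labeled patch set."""
    probs = model.predict_proba(patches)
    return float(np.mean(probs.argmax(axis=1) == np.asarray(labels)))


def window_grid(image_shape: tuple[int, int], scan: WindowScanParams) -> list[RoiWindow]:
    """All windows with top-left at multiples of ``step`` that fit entirely
    inside the image, in row-major order."""
    h, w = image_shape[:2]
    side, step = scan.window_side, scan.step
    if h < side or w < side:
        raise ParameterError(
            f"image {h}x{w} smaller than the {side}x{side} scan window")
    rows = range(0, h - side + 1, step)
    cols = range(0, w - side + 1, step)
    return [RoiWindow(r, c, side) for r in rows for c in cols]


def prefilter_windows(image: np.ndarray, windows: list[RoiWindow],
                      gray_threshold: float) -> list[RoiWindow]:
    """Keep windows whose mean intensity is >= the threshold (strictly
    darker windows are filtered without any prediction)."""
    image = as_echo_image(image)
    # integral image: window means in O(1) each
    ii = np.zeros((image.shape[0] + 1, image.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(image, axis=0, dtype=np.int64), axis=1, out=ii[1:, 1:])
    kept = []
    for win in windows:
        r, c, s = win.row, win.col, win.side
        total = ii[r + s, c + s] - ii[r, c + s] - ii[r + s, c] + ii[r, c]
        if total / (s * s) >= gray_threshold:
            kept.append(win)
    return kept


def _resize_window(image: np.ndarray, win: RoiWindow, out_size: int) -> np.ndarray:
    crop = win.extract(image).astype(float)
    if win.side == out_size:
        out = crop
    else:
        out = resize(crop, (out_size, out_size), order=1,
                     preserve_range=True, anti_aliasing=False)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def score_windows(image: np.ndarray, model: EchoNet, windows: list[RoiWindow],
                  batch_size: int = 16) -> list[RoiWindow]:
    """Attach the target-class probability to each window."""
    size = model.config.input_size
    stack = np.stack([_resize_window(image, w, size) for w in windows])
    probs = model.predict_proba(stack, batch_size=batch_size)[:, 1]
    return [RoiWindow(w.row, w.col, w.side, float(p))
            for w, p in zip(windows, probs)]


def locate_target(image: np.ndarray, model: EchoNet,
                  scan: WindowScanParams | None = None) -> RoiWindow:
    """Best-scoring surviving window; ties break to smallest (row, col)."""
    scan = scan or WindowScanParams()
    image = as_echo_image(image)
    windows = window_grid(image.shape, scan)
    kept = prefilter_windows(image, windows, scan.gray_threshold)
    if not kept:
        raise StageError("locate", "no candidate region: every window fell "
                         "below the gray threshold")
    scored = score_windows(image, model, kept)
    best = max(scored, key=lambda w: (w.probability, -w.row, -w.col))
    return best
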