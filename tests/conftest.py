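"""Shared fixtures.

The trained classifier and the 20-phantom recovery bench are expensive
(minutes of CPU), so they are built once per session and shared by the
pipeline and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from echowall.locator import TrainConfig, build_locator, train_locator
from echowall.phantom import PhantomParams, generate_patch_dataset, generate_phantom
from echowall.pipeline import PipelineConfig, run_pipeline

TRAIN_SEED = 0
N_TRAIN_PATCHES = 30          # per class
TRAIN_ITERATIONS = 200        # scaled-down run; separates phantom classes


@pytest.fixture(scope="session")
def training_set():
    return generate_patch_dataset(PhantomParams(seed=TRAIN_SEED),
                                  N_TRAIN_PATCHES, N_TRAIN_PATCHES)


@pytest.fixture(scope="session")
def trained_model(training_set):
    patches, labels = training_set
    model = build_locator(seed=TRAIN_SEED)
    model, history = train_locator(
        model, patches, labels,
        TrainConfig(iterations=TRAIN_ITERATIONS, batch_size=20,
                    learning_rate=1e-4, seed=TRAIN_SEED))
    return model, history


def bench_phantoms(n: int = 20, seed: int = 123, speckle: float = 0.2):
    """Seeded phantom geometries spanning 12-30 px walls at 0.3-0.6 mm/px."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        thickness = int(rng.integers(12, 31))
        pitch = int(rng.integers(17, 34))       # k = 10/pitch in [0.30, 0.59]
        out.append(PhantomParams(seed=1000 + i, band_thickness_px=thickness,
                                 ruler_pitch_px=pitch, speckle_sigma=speckle))
    return out


@pytest.fixture(scope="session")
def phantom_bench(trained_model):
    """Full-pipeline runs over 20 speckled phantoms: (params, truth, report)."""
    model, _ = trained_model
    results = []
    for params in bench_phantoms():
        image, gt = generate_phantom(params)
        report = run_pipeline(image, model, PipelineConfig())
        results.append((params, gt, report))
    return results
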