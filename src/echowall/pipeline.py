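"""End-to-end orchestration: locate -> enhance -> segment -> quantify.

Given a frame and a trained window classifier, the pipeline runs the full
measurement chain and returns a :class:`~echowall.quantify.MeasurementReport`
with every stage's key scalars in ``diagnostics``. Stage failures are
caught and reported through the ``failure`` field rather than raised, so a
batch run always produces one (possibly partial) report per frame.

The whole chain is deterministic: same image + same weights + same config
give a byte-identical JSON report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cnn import EchoNet
from .contour import PriorRange, segment_wall
from .enhance import NlmParams, StructuringElement, nlm_filter, opening
from .locator import WindowScanParams, locate_target
from .quantify import (MeasurementReport, PointSelectionParams,
                       ScaleDetectParams, classify_lvh,
                       filter_degenerate_points, lvpwt, nearest_distance,
                       relative_error, select_lower_points,
                       trimmed_mean_distance, detect_scale)
from .types import EchoWallError, ParameterError, as_echo_image

#: Defaults that are artifact choices rather than published parameter
#: values (the published ones: 200/25 scan, 7/21/8 NLM, 140/10/5 points).
ARTIFACT_DEFAULTS = ("prior", "sampling_side", "se_side", "scale", "cutoff_mm")


@dataclass
class PipelineConfig:
    scan: WindowScanParams = field(default_factory=WindowScanParams)
    nlm: NlmParams = field(default_factory=NlmParams)
    se_side: int = 3
    prior: PriorRange = field(default_factory=PriorRange)
    sampling_side: int = 31
    otsu_passes: int = 1
    points: PointSelectionParams = field(default_factory=PointSelectionParams)
    scale: ScaleDetectParams = field(default_factory=ScaleDetectParams)
    #: Pixel-span convention: the distance between the centers of the two
    #: edge pixels of a wall spanning t pixel rows is t - 1, so one pixel
    #: (half a pixel at each boundary) is added to report the full spanned
    #: extent — the quantity a caliper placed on the outer edges reads.
    edge_correction_px: float = 1.0
    cutoff_mm: float = 11.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in [("scan", WindowScanParams), ("nlm", NlmParams),
                         ("prior", PriorRange), ("points", PointSelectionParams),
                         ("scale", ScaleDetectParams)]:
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_pipeline(image: np.ndarray, model: EchoNet,
                 config: PipelineConfig | None = None,
                 *, keep_intermediates: bool = False) -> MeasurementReport:
    """Measure LVPWT on one frame; never raises on a stage failure."""
    config = config or PipelineConfig()
    image = as_echo_image(image)
    report = MeasurementReport(cutoff_mm=config.cutoff_mm)
    diag = report.diagnostics
    intermediates: dict = {}
    if keep_intermediates:
        diag["intermediates"] = intermediates

    log = logging.getLogger(__name__)

    def _stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        dt = round(time.perf_counter() - t0, 4)
        diag.setdefault("timings_s", {})[name] = dt
        log.debug("stage=%s elapsed_s=%.4f", name, dt)
        return result

    try:
        win = _stage("locate", lambda: locate_target(image, model, config.scan))
        diag["roi"] = {"row": win.row, "col": win.col, "side": win.side,
                       "probability": win.probability}
        roi = win.extract(image)

        denoised = _stage("nlm", lambda: nlm_filter(roi, config.nlm))
        enhanced = _stage("opening", lambda: opening(
            denoised, StructuringElement.square(config.se_side)))
        if keep_intermediates:
            intermediates.update(roi=roi, denoised=denoised, enhanced=enhanced)

        upper, lower, seg_diag = _stage("segment", lambda: segment_wall(
            enhanced, config.prior, config.sampling_side, config.otsu_passes))
        diag["segment"] = seg_diag
        if keep_intermediates:
            intermediates.update(upper=upper, lower=lower)

        def _points():
            pts = select_lower_points(lower, config.points)
            return filter_degenerate_points(pts, lower, config.points.orientation)

        points = _stage("points", _points)
        diag["n_points_selected"] = len(points)

        distances = _stage("distances", lambda: [
            nearest_distance((p.row, p.col), upper) for p in points])
        report.distances = [round(float(d), 4) for d in distances]
        report.n_points_used = max(0, len(distances) - 2) if len(distances) >= 3 \
            else len(distances)
        report.d_px = round(trimmed_mean_distance(distances)
                            + config.edge_correction_px, 4)

        scale = _stage("scale", lambda: detect_scale(image, config.scale))
        report.l_px = round(scale.l, 4)
        report.k_mm_per_px = round(scale.k, 6)

        report.lvpwt_mm = lvpwt(scale.k, report.d_px)
        report.lvh_positive = classify_lvh(report.lvpwt_mm, config.cutoff_mm)
    except EchoWallError as exc:
        report.failure = str(exc)
    return report


def report_json(report: MeasurementReport) -> str:
    """Canonical (sorted-key) JSON serialization of a report."""
    d = report.to_dict()
    d["diagnostics"] = {k: v for k, v in d["diagnostics"].items()
                        if k != "timings_s" and k != "intermediates"}
    return json.dumps(d, sort_keys=True)


def error_table(samples: list[tuple[str, float, float]]) -> pd.DataFrame:
    """Per-sample error arithmetic from (sample, reference_mm, measured_mm).

    Mirrors the standard clinical comparison table: absolute error in mm
    and relative error in percent against the reference reading.
    """
    if not samples:
        raise ParameterError("error_table needs at least one sample")
    rows = []
    for name, ref, meas in samples:
        rows.append({
            "sample": name,
            "reference_mm": ref,
            "measured_mm": meas,
            "abs_error_mm": round(abs(meas - ref), 2),
            "rel_error_pct": relative_error(meas, ref),
        })
    return pd.DataFrame(rows)


def batch_report(images: list[np.ndarray], references_mm: list[float],
                 model: EchoNet, config: PipelineConfig | None = None,
                 ) -> tuple[pd.DataFrame, dict]:
    """Measure a batch of frames against reference readings.

    Returns the per-sample table plus a summary dict with the max and mean
    relative error over the samples that produced a measurement.
    """
    if len(images) == 0:
        raise ParameterError("batch_report needs at least one image")
    if len(images) != len(references_mm):
        raise ParameterError("images and references must have equal length")
    samples, failures = [], []
    for i, (img, ref) in enumerate(zip(images, references_mm)):
        rep = run_pipeline(img, model, config)
        if rep.failure is None:
            samples.append((f"No.{i + 1}", float(ref), rep.lvpwt_mm))
        else:
            failures.append((f"No.{i + 1}", rep.failure))
    table = error_table(samples) if samples else pd.DataFrame()
    summary = {
        "n_measured": len(samples),
        "n_failed": len(failures),
        "failures": failures,
        "max_rel_error_pct": float(table["rel_error_pct"].max()) if len(table) else None,
        "mean_rel_error_pct": float(table["rel_error_pct"].mean()) if len(table) else None,
    }
    return table, summary
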