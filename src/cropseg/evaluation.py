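"""Pixel-based accuracy assessment of a segment layer against validation plots.

Both layers are rasterized on the evaluation grid with the same
pixel-center-inside rule the rest of the pipeline uses, restricted to the AOI
mask, and compared pixel-wise:

    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)
    F_beta    = (1 + beta^2) * precision * recall / (beta^2 * precision + recall)

``beta`` defaults to 1 (the balanced harmonic mean); commission error is
1 - precision and omission error is 1 - recall.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geo_io import FieldImage, FieldMask, PlotSegment, check_crs, rasterize_polygons

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_beta: float
    beta: float
    commission_error: float
    omission_error: float
    grid: str

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["precision_pct"] = round(100 * self.precision, 2)
        payload["recall_pct"] = round(100 * self.recall, 2)
        payload["f_beta_pct"] = round(100 * self.f_beta, 2)
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def f_beta(precision: float, recall: float, beta: float = 1.0) -> float:
    """Weighted harmonic mean of precision and recall.

    Returns 0 when precision = recall = 0 (the empty-overlap convention).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def pixel_confusion(
    pred: Sequence[PlotSegment],
    truth: Sequence[PlotSegment],
    grid: FieldImage,
    mask: FieldMask,
) -> tuple[int, int, int]:
    """Pixel confusion counts (tp, fp, fn) within the AOI mask."""
    if not truth:
        raise ValueError("empty truth layer: nothing to validate against")
    for seg in list(pred) + list(truth):
        check_crs(seg.crs, grid.crs, "segment layer and evaluation grid")
    pred_bits = rasterize_polygons([s.polygon for s in pred], grid.shape, grid.transform)
    truth_bits = rasterize_polygons([s.polygon for s in truth], grid.shape, grid.transform)
    pred_bits &= mask.bits
    truth_bits &= mask.bits
    tp = int(np.count_nonzero(pred_bits & truth_bits))
    fp = int(np.count_nonzero(pred_bits & ~truth_bits))
    fn = int(np.count_nonzero(~pred_bits & truth_bits))
    return tp, fp, fn


def evaluate(
    pred: Sequence[PlotSegment],
    truth: Sequence[PlotSegment],
    grid: FieldImage,
    mask: FieldMask,
    beta: float = 1.0,
) -> EvalReport:
    """Full pixel-based accuracy report for a predicted segment layer."""
    tp, fp, fn = pixel_confusion(pred, truth, grid, mask)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    score = f_beta(precision, recall, beta)
    rows, cols = grid.shape
    report = EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f_beta=score,
        beta=beta,
        commission_error=1.0 - precision,
        omission_error=1.0 - recall,
        grid=f"{rows}x{cols} @ {abs(grid.transform.xres)} m",
    )
    logger.info(
        "evaluation: precision=%.4f recall=%.4f F%.2g=%.4f (commission %.4f, omission %.4f)",
        precision,
        recall,
        beta,
        score,
        report.commission_error,
        report.omission_error,
    )
    return report
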