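"""Nine-metric evaluation suite and multi-model comparison tables.

Metrics follow the regulatory air-quality evaluation conventions: mean bias
(MB), mean absolute error (MAE), mean square error (MSE) and its root (RMSE),
relative error of totals (RE), sum-normalized mean error (NME), mean of
cellwise gross error ratios (NMGE), and the mean fractional bias/error pair
(MFB in [-2, 2], MFE in [0, 2]) that is robust near zero concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

METRIC_NAMES = ("MB", "MAE", "MSE", "RMSE", "RE", "NME", "NMGE", "MFB", "MFE")

#: Default evaluation mask threshold (µg/m³): cells with truth at or below
#: this are excluded so the ratio metrics cannot blow up.
TRUTH_FLOOR = 0.01


class EvaluationError(ValueError):
    pass


@dataclass
class MetricsReport:
    values: dict
    model: str = ""
    month: str = ""
    n_cells: int = 0

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_row(self) -> dict:
        return {"model": self.model, "month": self.month,
                "n_cells": self.n_cells, **self.values}


def compute_metrics(pred: np.ndarray, truth: np.ndarray,
                    mask: Optional[np.ndarray] = None,
                    model: str = "", month: str = "") -> MetricsReport:
    """Evaluate a prediction field against truth over masked cells.

    With P the prediction and O the truth on the n masked cells:
    MB = mean(P-O); MAE = mean|P-O|; MSE = mean((P-O)^2); RMSE = sqrt(MSE);
    RE = |sum(P)-sum(O)|/sum(O); NME = sum|P-O|/sum(O);
    NMGE = mean(|P-O|/O); MFB = (2/n) sum((P-O)/(P+O));
    MFE = (2/n) sum(|P-O|/(P+O)).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise EvaluationError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if mask is None:
        mask = truth > TRUTH_FLOOR
    p, o = pred[mask], truth[mask]
    if p.size == 0:
        raise EvaluationError("empty evaluation mask")
    if np.sum(o) <= 0:
        raise EvaluationError("truth sums to zero; normalized metrics undefined")
    d = p - o
    denom = p + o
    frac = np.divide(d, denom, out=np.zeros_like(d), where=denom != 0)
    gross = np.divide(np.abs(d), denom, out=np.zeros_like(d), where=denom != 0)
    mse = float(np.mean(d ** 2))
    values = {
        "MB": float(np.mean(d)),
        "MAE": float(np.mean(np.abs(d))),
        "MSE": mse,
        "RMSE": float(np.sqrt(mse)),
        "RE": float(abs(p.sum() - o.sum()) / o.sum()),
        "NME": float(np.abs(d).sum() / o.sum()),
        "NMGE": float(np.mean(np.abs(d) / o)),
        "MFB": float(2.0 * np.mean(frac)),
        "MFE": float(2.0 * np.mean(gross)),
    }
    return MetricsReport(values=values, model=model, month=month, n_cells=p.size)


def compare_models(predictions: dict, test_samples: Sequence,
                   truth_fn: Callable, mask: Optional[np.ndarray] = None
                   ) -> pd.DataFrame:
    """Build a (model x month) metrics matrix.

    ``predictions`` maps model name -> {month -> predict(sample) returning a
    shipping-PM2.5 field}; ``truth_fn(sample)`` returns the matching truth
    field.  Missing month models raise rather than being silently skipped.
    Cells are pooled over all test samples of a month before metrics are
    computed.
    """
    months = sorted({s.month_label for s in test_samples})
    rows = []
    for name, by_month in predictions.items():
        missing = [m for m in months if m not in by_month]
        if missing:
            raise EvaluationError(f"model {name!r} lacks months {missing}")
        for month in months:
            samples = [s for s in test_samples if s.month_label == month]
            preds = np.concatenate([np.ravel(by_month[month](s)) for s in samples])
            truths = np.concatenate([np.ravel(truth_fn(s)) for s in samples])
            msk = None
            if mask is not None:
                msk = np.concatenate([np.ravel(mask)] * len(samples))
                msk = msk & (truths > TRUTH_FLOOR)
            rows.append(compute_metrics(preds, truths, msk, name, month).as_row())
    return pd.DataFrame(rows)
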