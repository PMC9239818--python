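"""Segmentation error rate with optimal label matching, and the comparison
harness that runs several methods over a phantom suite.

Cluster indices are arbitrary, so before counting misclassified pixels the
prediction labels are mapped onto the truth labels by the correspondence
that maximizes agreement: an injective assignment-problem solution when the
prediction has at most as many labels as the truth, and a per-label
majority (many-to-one) mapping when it has more — e.g. when mean shift
finds surplus modes.  Runtimes are recorded for information only.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import RunConfig
from .phantom import Phantom
from .segment import segment_image

__all__ = [
    "EvalReport",
    "contingency",
    "match_labels",
    "error_rate",
    "evaluate_segmentation",
    "run_comparison",
    "reports_to_csv",
    "summarize",
]


@dataclass
class EvalReport:
    """Outcome of one (image, method) cell of the comparison."""

    phantom_id: str
    method: str
    params: dict
    error_rate: float | None
    mapping: dict | None
    confusion: list | None
    runtime_seconds: float | None
    seed: int | None = None
    failure: str | None = None

    def to_dict(self) -> dict:
        return {
            "phantom_id": self.phantom_id,
            "method": self.method,
            "params": self.params,
            "error_rate": self.error_rate,
            "mapping": self.mapping,
            "confusion": self.confusion,
            "runtime_seconds": self.runtime_seconds,
            "seed": self.seed,
            "failure": self.failure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(**d)


def _check_labels(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.min() < 0 or truth.min() < 0:
        raise ValueError("labels must be nonnegative")
    return pred.ravel(), truth.ravel()


def contingency(pred, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contingency counts C[p, t] over the distinct labels of each side."""
    p, t = _check_labels(pred, truth)
    plabels, pinv = np.unique(p, return_inverse=True)
    tlabels, tinv = np.unique(t, return_inverse=True)
    table = np.zeros((plabels.size, tlabels.size), dtype=np.int64)
    np.add.at(table, (pinv, tinv), 1)
    return table, plabels, tlabels


def match_labels(pred, truth) -> dict[int, int]:
    """Prediction-to-truth label mapping maximizing total agreement.

    Injective (assignment problem) when the prediction has at most as many
    distinct labels as the truth; per-prediction-label majority vote — the
    optimal many-to-one map — when it has more.
    """
    table, plabels, tlabels = contingency(pred, truth)
    if plabels.size <= tlabels.size:
        rows, cols = linear_sum_assignment(table, maximize=True)
        return {int(plabels[r]): int(tlabels[c]) for r, c in zip(rows, cols)}
    return {int(plabels[r]): int(tlabels[np.argmax(table[r])]) for r in range(plabels.size)}


def error_rate(pred, truth) -> float:
    """Fraction of pixels misclassified after optimal label matching."""
    table, plabels, tlabels = contingency(pred, truth)
    mapping = match_labels(pred, truth)
    tindex = {int(t): j for j, t in enumerate(tlabels)}
    agreement = sum(
        int(table[i, tindex[mapping[int(p)]]]) for i, p in enumerate(plabels)
    )
    n = int(table.sum())
    return 1.0 - agreement / n


def evaluate_segmentation(pred, truth) -> tuple[float, dict, np.ndarray]:
    """Error rate, optimal mapping and truth x pred confusion counts."""
    table, plabels, tlabels = contingency(pred, truth)
    mapping = match_labels(pred, truth)
    return error_rate(pred, truth), mapping, table.T  # truth rows, pred cols


def run_comparison(
    phantoms: Sequence[Phantom],
    configs: Sequence[RunConfig],
    phantom_ids: Sequence[str] | None = None,
) -> list[EvalReport]:
    """Run every method on every phantom; one report per cell.

    A method failure on one phantom is recorded in that cell's report and
    does not abort the rest of the grid.  Wall-clock runtime wraps the
    segmentation call only (no I/O) and is informational.
    """
    if not phantoms:
        raise ValueError("need at least one phantom")
    if phantom_ids is None:
        phantom_ids = [
            f"{p.spec.layout}-{p.spec.width}x{p.spec.height}-s{p.spec.seed}"
            for p in phantoms
        ]
    reports: list[EvalReport] = []
    for pid, ph in zip(phantom_ids, phantoms):
        for cfg in configs:
            cfg.validate()
            try:
                t0 = time.perf_counter()
                labels, _info = segment_image(ph.image, cfg)
                runtime = time.perf_counter() - t0
                err, mapping, conf = evaluate_segmentation(labels, ph.truth)
                reports.append(
                    EvalReport(
                        phantom_id=pid,
                        method=cfg.method,
                        params=cfg.to_dict(),
                        error_rate=err,
                        mapping={str(k): v for k, v in mapping.items()},
                        confusion=conf.tolist(),
                        runtime_seconds=round(runtime, 3),
                        seed=cfg.seed,
                    )
                )
            except Exception as exc:  # record the cell failure, keep going
                reports.append(
                    EvalReport(
                        phantom_id=pid,
                        method=cfg.method,
                        params=cfg.to_dict(),
                        error_rate=None,
                        mapping=None,
                        confusion=None,
                        runtime_seconds=None,
                        seed=cfg.seed,
                        failure=f"{type(exc).__name__}: {exc}",
                    )
                )
    return reports


def summarize(reports: Sequence[EvalReport]) -> dict[str, dict[str, float]]:
    """Per-method mean error rate and mean runtime over successful cells."""
    out: dict[str, dict[str, float]] = {}
    for method in sorted({r.method for r in reports}):
        errs = [r.error_rate for r in reports if r.method == method and r.error_rate is not None]
        times = [
            r.runtime_seconds
            for r in reports
            if r.method == method and r.runtime_seconds is not None
        ]
        out[method] = {
            "mean_error_rate": float(np.mean(errs)) if errs else float("nan"),
            "sd_error_rate": float(np.std(errs)) if errs else float("nan"),
            "mean_runtime_seconds": float(np.mean(times)) if times else float("nan"),
            "n_cells": len(errs),
        }
    return out


def reports_to_csv(reports: Sequence[EvalReport], path) -> None:
    """Aggregate table, one row per (phantom, method) cell."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["phantom_id", "method", "error_rate", "runtime_seconds", "seed", "failure"]
        )
        for r in reports:
            writer.writerow(
                [r.phantom_id, r.method, r.error_rate, r.runtime_seconds, r.seed, r.failure]
            )


def reports_to_json(reports: Sequence[EvalReport], path) -> None:
    payload = {
        "reports": [r.to_dict() for r in reports],
        "summary": summarize(reports),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
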