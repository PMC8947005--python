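"""Cohort-level agreement metrics for midline-shift measurements.

The evaluation protocol for an automatic MLS reader against a reference:

* mean and maximum absolute error (mm) over paired scans,
* intraclass correlation (two-way random effects, absolute agreement,
  single rater — ICC(2,1)) with its F statistic and 95% CI,
* sensitivity and specificity of detecting an MLS strictly greater than
  clinically used cutoffs (2, 5 and 10 mm by default),
* optionally, Pearson correlation of the predicted MLS with a covariate.

All statistics are computed at scan level. A prediction with no detected
slice scores 0 mm (a missed detection must not silently drop a scan).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .geometry import MLSResult

__all__ = [
    "EvalReport",
    "mae",
    "threshold_classify",
    "sens_spec",
    "icc_agreement",
    "evaluate_cohort",
]


@dataclass
class ThresholdRow:
    threshold_mm: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class EvalReport:
    """Agreement metrics of a predicted cohort against its reference."""

    n_scans: int
    mae_mm: float
    max_ae_mm: float
    icc: tuple[float, float, float, float]  # (estimate, F, ci_low, ci_high)
    per_threshold: list[ThresholdRow] = field(default_factory=list)
    pearson_r: Optional[float] = None
    pearson_p: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n_scans": self.n_scans,
            "mae_mm": self.mae_mm,
            "max_ae_mm": self.max_ae_mm,
            "icc": {
                "estimate": self.icc[0],
                "F": self.icc[1],
                "ci_low": self.icc[2],
                "ci_high": self.icc[3],
            },
            "per_threshold": [
                {
                    "threshold_mm": r.threshold_mm,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "tp": r.tp,
                    "fp": r.fp,
                    "tn": r.tn,
                    "fn": r.fn,
                }
                for r in self.per_threshold
            ],
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def mae(gt: Sequence[float], pred: Sequence[float]) -> tuple[float, float]:
    """Mean and maximum absolute error over paired per-scan MLS values (mm)."""
    g = np.asarray(gt, dtype=float)
    p = np.asarray(pred, dtype=float)
    if g.shape != p.shape or g.ndim != 1:
        raise ValueError(f"paired 1-D inputs required, got {g.shape} vs {p.shape}")
    if g.size == 0:
        raise ValueError("need at least one pair")
    ae = np.abs(g - p)
    return float(ae.mean()), float(ae.max())


def threshold_classify(mls: Sequence[float], threshold_mm: float) -> np.ndarray:
    """Binary labels: positive iff MLS is strictly greater than the cutoff.

    The strict inequality means a scan measuring exactly 2.0 mm is negative
    at the 2 mm cutoff ("greater than", not "at least").
    """
    values = np.asarray(mls, dtype=float)
    if np.any(values < 0):
        raise ValueError("MLS values must be non-negative")
    return values > threshold_mm


def sens_spec(
    gt_labels: Sequence[bool], pred_labels: Sequence[bool]
) -> tuple[Optional[float], Optional[float], int, int, int, int]:
    """Sensitivity and specificity with the 2x2 confusion counts.

    When the reference has no positives (or no negatives), the corresponding
    rate is undefined and reported as ``None`` rather than 0.
    """
    g = np.asarray(gt_labels, dtype=bool)
    p = np.asarray(pred_labels, dtype=bool)
    if g.shape != p.shape or g.ndim != 1:
        raise ValueError("paired 1-D label arrays required")
    if g.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum(g & p))
    fn = int(np.sum(g & ~p))
    tn = int(np.sum(~g & ~p))
    fp = int(np.sum(~g & p))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec, tp, fp, tn, fn


def icc_agreement(ratings: np.ndarray) -> tuple[float, float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n_subjects, k_raters) matrix with no missing cells.
    Returns (estimate, F, ci_low, ci_high) with a 95% CI. The absolute-
    agreement form penalises systematic between-rater bias, so a rater with
    a constant offset lowers the estimate even at perfect correlation.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) matrix")
    n, k = r.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 raters, got {n}x{k}")
    if not np.all(np.isfinite(r)):
        raise ValueError("ratings contain missing or non-finite cells (no imputation)")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": r.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    # two-way random, absolute agreement, single rater: labelled ICC2 or
    # ICC(A,1) depending on the pingouin version
    label = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    return float(row["ICC"]), float(row["F"]), ci_low, ci_high


def _pred_value(r: MLSResult) -> float:
    # undefined prediction scores 0 mm: a missed detection stays in the cohort
    return r.scan_mls_mm if r.defined and not math.isnan(r.scan_mls_mm) else 0.0


def evaluate_cohort(
    gt: Sequence[MLSResult],
    pred: Sequence[MLSResult],
    thresholds: Sequence[float] = (2.0, 5.0, 10.0),
    covariate: Optional[Sequence[float]] = None,
) -> EvalReport:
    """Assemble the full agreement report for a cohort of scans.

    ``gt`` and ``pred`` are matched by ``scan_id`` (an error lists any
    mismatch). ``covariate``, when given, is ordered like ``gt`` and enters
    a Pearson correlation against the predicted MLS.
    """
    gt_by_id = {r.scan_id: r for r in gt}
    pred_by_id = {r.scan_id: r for r in pred}
    missing = sorted(set(gt_by_id) ^ set(pred_by_id))
    if missing:
        raise ValueError(f"unmatched scan_ids between cohorts: {missing}")
    ids = [r.scan_id for r in gt]

    g = np.array([_pred_value(gt_by_id[i]) for i in ids])
    p = np.array([_pred_value(pred_by_id[i]) for i in ids])
    mean_ae, max_ae = mae(g, p)
    if len(ids) >= 3:
        icc = icc_agreement(np.column_stack([g, p]))
    else:
        # ICC needs at least 3 subjects; report it as undefined
        icc = (float("nan"),) * 4

    rows = []
    for t in thresholds:
        gl = threshold_classify(g, t)
        pl = threshold_classify(p, t)
        sens, spec, tp, fp, tn, fn = sens_spec(gl, pl)
        rows.append(ThresholdRow(float(t), sens, spec, tp, fp, tn, fn))

    pearson_r = pearson_p = None
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != p.shape:
            raise ValueError("covariate length must match the cohort")
        pearson_r, pearson_p = (float(v) for v in stats.pearsonr(p, cov))

    return EvalReport(
        n_scans=len(ids),
        mae_mm=mean_ae,
        max_ae_mm=max_ae,
        icc=icc,
        per_threshold=rows,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
    )
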