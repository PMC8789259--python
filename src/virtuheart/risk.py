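"""Per-patient risk classification and predictive-performance metrics.

A virtual heart is deemed at risk of ventricular arrhythmia when rapid pacing
induces reentry from at least one of the seven endocardial pacing sites.
Predictions (from the virtual-heart models or from the clinical ACCF/AHA and
ESC risk scores, which enter as precomputed verdicts) are compared with the
clinical VA outcome via standard 2x2 confusion metrics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMetrics", "classify_patient", "compute_metrics",
    "reproduce_table3", "round_metric",
]


def round_metric(pct: float) -> float:
    """Half-up rounding of a percentage to one decimal for report output.

    Matches the printed-table style: an intermediate half-up rounding at two
    decimals precedes the final one-decimal rounding (so e.g. 53.846 -> 53.9).
    """
    if pct != pct:  # NaN (undefined metric)
        return pct
    two = math.floor(pct * 100.0 + 0.5) / 100.0
    return math.floor(two * 10.0 + 0.5) / 10.0


@dataclass(frozen=True)
class ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy in percent, plus raw counts.

    A metric with a degenerate denominator is NaN (undefined), never 0.
    """
    tp: int
    fp: int
    tn: int
    fn: int

    def _pct(self, num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._pct(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return self._pct(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    def rounded(self) -> dict:
        """One-decimal report row (half-up, printed-table convention)."""
        return {k: round_metric(getattr(self, k))
                for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy")}


def classify_patient(induction_results) -> bool:
    """A patient is at risk iff at least one of the 7 pacing sites induced VA.

    ``induction_results`` is a sequence of per-site results; each element is
    either a boolean or an object with an ``induced`` attribute.
    """
    flags = [bool(getattr(r, "induced", r)) for r in induction_results]
    if len(flags) != 7:
        raise ValueError(f"expected 7 pacing-site results, got {len(flags)}")
    return any(flags)


def compute_metrics(predictions, outcomes) -> ConfusionMetrics:
    """Confusion metrics of boolean predictions against boolean outcomes."""
    pred = np.asarray(predictions, dtype=bool)
    out = np.asarray(outcomes, dtype=bool)
    if pred.shape != out.shape or pred.ndim != 1:
        raise ValueError("predictions and outcomes must be equal-length 1-D")
    if out.all() or not out.any():
        raise ValueError("need at least one positive and one negative outcome")
    tp = int(np.sum(pred & out))
    fp = int(np.sum(pred & ~out))
    tn = int(np.sum(~pred & ~out))
    fn = int(np.sum(~pred & out))
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


#: Fixture column -> report row label.
_METHODS = {
    "accf_aha": "ACCF/AHA risk model",
    "esc": "ESC risk model",
    "lge_t1": "Virtual-heart technology: LGE-T1",
    "lge_only": "Virtual-heart technology: LGE only",
}


def reproduce_table3(fixture: pd.DataFrame) -> pd.DataFrame:
    """Predictive-performance table for the four risk-assessment methods.

    ``fixture`` carries per-patient boolean columns ``clinical_va`` plus one
    verdict column per method.  Returns one row per method with one-decimal
    rounded sensitivity, specificity, PPV, NPV and accuracy (percent).
    """
    rows = {}
    for col, label in _METHODS.items():
        m = compute_metrics(fixture[col], fixture["clinical_va"])
        rows[label] = m.rounded()
    return pd.DataFrame.from_dict(rows, orient="index")
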