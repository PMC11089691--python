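"""Scoring of per-cell association calls against ground truth.

Two metrics, matched to a three-class problem (positive / negative / null):

* **F1** — positive and negative associations are pooled as "positives"
  and null as "negatives"; F1 is the harmonic mean of precision and recall
  on that binary problem, ignoring direction.
* **FSC** (fraction of sign correctness) — among *true discoveries* (cells
  non-null in both truth and call), the fraction whose called direction
  matches the true direction.  F1 alone can be perfect while every
  direction is flipped; FSC covers that blind spot.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["calls_from_results", "f1_association", "fraction_sign_correct"]

_LABELS = ("positive", "negative", "null")


def calls_from_results(
    lambda_std: np.ndarray, p_value: np.ndarray, threshold: float = 0.05
) -> np.ndarray:
    """Discrete per-cell call: ``positive`` if p < threshold and Lambda > 0,
    ``negative`` if p < threshold and Lambda < 0, else ``null``."""
    lam = np.asarray(lambda_std, dtype=float)
    p = np.asarray(p_value, dtype=float)
    calls = np.full(lam.shape, "null", dtype=object)
    calls[(p < threshold) & (lam > 0)] = "positive"
    calls[(p < threshold) & (lam < 0)] = "negative"
    return calls


def _validate(truth, calls):
    truth = np.asarray(truth, dtype=object)
    calls = np.asarray(calls, dtype=object)
    if truth.shape != calls.shape:
        raise ValueError("truth and calls lengths differ")
    for name, arr in (("truth", truth), ("calls", calls)):
        bad = set(arr) - set(_LABELS)
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    return truth, calls


def f1_association(truth, calls) -> float:
    """F1 with {positive, negative} pooled as signal and null as noise."""
    truth, calls = _validate(truth, calls)
    true_pos = truth != "null"
    called_pos = calls != "null"
    tp = int((true_pos & called_pos).sum())
    fp = int((~true_pos & called_pos).sum())
    fn = int((true_pos & ~called_pos).sum())
    if tp == 0:
        if not true_pos.any() or not called_pos.any():
            warnings.warn("no true or no called discoveries; F1 set to 0",
                          stacklevel=2)
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def fraction_sign_correct(truth, calls) -> float:
    """Among cells non-null in both truth and call, the fraction whose
    direction agrees.  Undefined (NaN, with a warning) without any such
    true discovery."""
    truth, calls = _validate(truth, calls)
    discoveries = (truth != "null") & (calls != "null")
    if not discoveries.any():
        warnings.warn("no true discoveries; FSC undefined", stacklevel=2)
        return float("nan")
    return float((truth[discoveries] == calls[discoveries]).mean())
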