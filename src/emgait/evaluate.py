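"""Classifier evaluation: per-class metrics, ROC/AUC, streaming harness.

Metrics follow the two-class per-sample conventions of the reference
protocol: overall accuracy plus specificity, recall, precision and F-score
for the stance and swing classes separately, all in percent, pooled over
every timestep of every test sequence.  In this two-class setting
recall(stance) = specificity(swing) and vice versa, exactly.

The ROC treats *stance* (class 0) as the positive class; AUC is computed
by the trapezoid rule over the threshold sweep of unique scores.

The streaming harness replays a raw 1500 Hz session through consecutive
windows, running the full preprocessing chain and the classifier per
window, and reports wall-clock timings (informational only: they are
hardware-dependent and never asserted).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .model import BiLSTMPhaseModel
from .preprocess import MvicRecord, preprocess_emg
from .signals import SignalTrace

CLASS_NAMES = {0: "stance", 1: "swing"}


@dataclass
class MetricsReport:
    """Pooled per-sample confusion metrics, percentages."""

    accuracy: float
    per_class: dict[str, dict[str, float]]
    confusion: dict[str, int]
    n_samples: int

    def as_row(self) -> dict[str, float]:
        row = {"accuracy": self.accuracy}
        for cname, m in self.per_class.items():
            for metric, v in m.items():
                row[f"{metric}_{cname}"] = v
        return row


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_class: int = 0  # stance


def confusion_metrics(pred, truth) -> MetricsReport:
    """Accuracy plus per-class specificity/recall/precision/F-score (%).

    ``pred`` and ``truth`` are flat per-sample label arrays in {0, 1}.
    A class absent from the truth yields NaN for its recall/precision with
    a warning rather than an error.
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size == 0 or truth.size == 0:
        raise ValueError("cannot compute metrics on empty inputs")
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    accuracy = 100.0 * float(np.mean(pred == truth))
    per_class: dict[str, dict[str, float]] = {}
    confusion: dict[str, int] = {}
    for c, cname in CLASS_NAMES.items():
        tp = int(np.sum((pred == c) & (truth == c)))
        fn = int(np.sum((pred != c) & (truth == c)))
        fp = int(np.sum((pred == c) & (truth != c)))
        tn = int(np.sum((pred != c) & (truth != c)))
        confusion.update({f"TP_{cname}": tp, f"FN_{cname}": fn,
                          f"FP_{cname}": fp, f"TN_{cname}": tn})
        if tp + fn == 0:
            warnings.warn(f"class {cname!r} absent from truth; "
                          "its recall is undefined")
            recall = np.nan
        else:
            recall = 100.0 * tp / (tp + fn)
        specificity = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        precision = 100.0 * tp / (tp + fp) if tp + fp else np.nan
        if np.isfinite(recall) and np.isfinite(precision) and recall + precision:
            fscore = 2 * precision * recall / (precision + recall)
        else:
            fscore = np.nan
        per_class[cname] = {
            "specificity": specificity, "recall": recall,
            "precision": precision, "fscore": fscore,
        }
    return MetricsReport(accuracy, per_class, confusion, int(pred.size))


def roc_curve_auc(scores, truth) -> RocResult:
    """ROC over stance probabilities with stance (0) as positive class."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel()
    if np.unique(truth).size < 2:
        raise ValueError("ROC needs both classes present in truth")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must be probabilities in [0, 1]")
    fpr, tpr, _ = _roc_curve(truth, scores, pos_label=0)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


def per_subject_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean accuracy per subject and scenario.

    ``table`` has one row per acquisition with columns ``subject``,
    ``scenario`` and ``accuracy``.
    """
    required = {"subject", "scenario", "accuracy"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    out = (table.groupby(["scenario", "subject"], sort=True)["accuracy"]
           .mean().reset_index()
           .rename(columns={"accuracy": "mean_accuracy"}))
    return out


def stream_classify(emg: SignalTrace, model: BiLSTMPhaseModel,
                    refs: dict[str, MvicRecord], rate_out: float = 500.0):
    """Online simulation: window-by-window preprocessing + classification.

    Consumes consecutive non-overlapping windows of the raw 1500 Hz EMG.
    On the 500 Hz path each window spans 1 s (3 x seq_len raw samples and
    seq_len samples after decimation); on the 1500 Hz path each window is
    seq_len raw samples (0.333 s).  Per window the full conditioning chain
    runs followed by the per-timestep prediction.  Returns the
    concatenated hard labels and a timing report (median preprocessing and
    classification wall-times plus the per-window breakdown; informational
    only -- the values are hardware-dependent).
    """
    seq_len = model.cfg.seq_len
    if rate_out == emg.rate_hz:
        win_raw = seq_len
    elif rate_out == emg.rate_hz / 3:
        win_raw = 3 * seq_len
    else:
        raise ValueError("rate_out must equal the EMG rate or a third of it")
    if emg.n_samples < win_raw:
        raise ValueError("session shorter than one classification window")
    labels = []
    rows = []
    n_windows = emg.n_samples // win_raw
    for w in range(n_windows):
        chunk = SignalTrace(emg.values[w * win_raw:(w + 1) * win_raw],
                            emg.rate_hz, emg.channels, emg.units)
        t0 = time.perf_counter()
        x = preprocess_emg(chunk, refs, rate_out=rate_out)
        t1 = time.perf_counter()
        pred = model.predict_labels(x.values)
        t2 = time.perf_counter()
        labels.append(pred)
        rows.append({"window": w,
                     "preprocess_ms": 1e3 * (t1 - t0),
                     "classify_ms": 1e3 * (t2 - t1)})
    timing = pd.DataFrame(rows)
    report = {
        "windows": timing,
        "median_preprocess_ms": float(timing["preprocess_ms"].median()),
        "median_classify_ms": float(timing["classify_ms"].median()),
        "window_span_s": win_raw / emg.rate_hz,
    }
    return np.concatenate(labels), report
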