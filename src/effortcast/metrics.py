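"""Performance metrics with brute-force-verifiable definitions.

Stage-1 metrics: ROC AUC (pairwise concordance with ties counted 1/2, via
the trapezoidal rule), precision, recall, and F1. Stage-2 metrics on level
(backtransformed) predictions: traditional sum-of-squares R^2 (can be
negative), squared-correlation R^2, RMSE, and RMSE normalized by the sample
standard deviation (n-1 denominator) of the observed outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


def roc_auc(probabilities, labels) -> float:
    """Concordance probability between positive and negative scores."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(probabilities, dtype=float)))


def confusion_counts(labels, predictions) -> tuple[int, int, int, int]:
    y = np.asarray(labels).astype(bool)
    p = np.asarray(predictions).astype(bool)
    tp = int((y & p).sum())
    fp = int((~y & p).sum())
    fn = int((y & ~p).sum())
    tn = int((~y & ~p).sum())
    return tp, fp, fn, tn


def precision_score(labels, predictions) -> float:
    tp, fp, _, _ = confusion_counts(labels, predictions)
    return tp / (tp + fp) if tp + fp else 0.0


def recall_score(labels, predictions) -> float:
    tp, _, fn, _ = confusion_counts(labels, predictions)
    return tp / (tp + fn) if tp + fn else 0.0


def f1_score_binary(labels, predictions) -> float:
    """Harmonic mean of precision and recall; 0 when there is no true positive."""
    tp, fp, fn, _ = confusion_counts(labels, predictions)
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def rsq_trad(y, yhat) -> float:
    """1 - SSE/SST; unbounded below (negative for predictors worse than the mean)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size < 2 or np.var(y) == 0:
        raise ValueError("rsq_trad requires >= 2 observations with variance > 0")
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - sse / sst


def rsq(y, yhat) -> float:
    """Squared Pearson correlation; in [0, 1]."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("rsq undefined when either vector is constant")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def rmse(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.sqrt(((y - yhat) ** 2).mean()))


def nrmse(y, yhat) -> float:
    """RMSE divided by the sample standard deviation (n-1) of the outcome."""
    y = np.asarray(y, dtype=float)
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("nrmse undefined when sd(y) = 0")
    return rmse(y, yhat) / sd


@dataclass
class MetricReport:
    """Per-scope stage-1 and stage-2 performance."""

    scope: str
    n: int
    stage1: dict = field(default_factory=dict)
    stage2: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"scope": self.scope, "n": self.n, "stage1": self.stage1,
                "stage2": self.stage2, "notes": self.notes}


def stratified_report(probabilities, class_predictions, level_predictions,
                      occurrence, level_observed, regions) -> dict[str, MetricReport]:
    """Metric reports for global plus each region scope.

    ``regions`` partitions the rows into inside/partial/outside; the global
    scope is recomputed on all rows, never averaged over scopes. Stage-2
    metrics use the positive observed rows of each scope. Empty scopes are
    omitted with a note on the global report; metrics undefined within a
    scope (single class, no positives) are left out with a note.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    class_predictions = np.asarray(class_predictions).astype(int)
    level_predictions = np.asarray(level_predictions, dtype=float)
    occurrence = np.asarray(occurrence).astype(int)
    level_observed = np.asarray(level_observed, dtype=float)
    regions = np.asarray(regions)
    if not len(regions) == len(occurrence) == len(probabilities):
        raise ValueError("inputs must align row-wise")

    out: dict[str, MetricReport] = {}
    global_notes = []
    scopes = [("global", np.ones(len(regions), dtype=bool))]
    for r in ("inside", "partial", "outside"):
        mask = regions == r
        if not mask.any():
            global_notes.append(f"scope {r!r} empty; omitted")
            continue
        scopes.append((r, mask))

    for name, mask in scopes:
        rep = MetricReport(scope=name, n=int(mask.sum()))
        y = occurrence[mask]
        if len(np.unique(y)) == 2:
            rep.stage1["roc_auc"] = roc_auc(probabilities[mask], y)
        else:
            rep.notes.append("roc_auc undefined: single class")
        rep.stage1["precision"] = precision_score(y, class_predictions[mask])
        rep.stage1["recall"] = recall_score(y, class_predictions[mask])
        rep.stage1["f_meas"] = f1_score_binary(y, class_predictions[mask])
        pos = mask & (occurrence == 1)
        if pos.sum() >= 2 and np.var(level_observed[pos]) > 0:
            rep.stage2["rsq_trad"] = rsq_trad(level_observed[pos], level_predictions[pos])
            rep.stage2["rsq"] = rsq(level_observed[pos], level_predictions[pos])
            rep.stage2["rmse"] = rmse(level_observed[pos], level_predictions[pos])
            rep.stage2["nrmse"] = nrmse(level_observed[pos], level_predictions[pos])
        else:
            rep.notes.append("stage-2 metrics undefined: too few positive rows")
        out[name] = rep
    out["global"].notes.extend(global_notes)
    return out


def reports_to_frame(reports: dict[str, "MetricReport"], **keys) -> pd.DataFrame:
    """Flatten scope reports to one row per scope, with optional id columns."""
    rows = []
    for scope, rep in reports.items():
        row = {"scope": scope, "n": rep.n, **keys}
        row.update({f"stage1_{k}": v for k, v in rep.stage1.items()})
        row.update({f"stage2_{k}": v for k, v in rep.stage2.items()})
        rows.append(row)
    return pd.DataFrame(rows)
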