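"""Simpler-model robustness comparators.

Four specifications of the same hurdle protocol are fit and evaluated on a
common temporal split: bagged trees with all features, bagged trees with the
lagged-effort feature only, logistic + linear regression with all features,
and logistic + linear regression with the lag feature only. The linear
specifications have no hyperparameters, so cross-validated tuning is skipped
for them (the threshold is still tuned on the folds).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .hurdle import FittedHurdle, HurdleSpec, fit_hurdle
from .metrics import MetricReport, reports_to_frame, stratified_report
from .panel import FoldPlan


def comparator_specs(base: HurdleSpec) -> dict[str, HurdleSpec]:
    lag_only = ("lag_log_effort",)
    return {
        "trees_all_features": base,
        "trees_lag_only": base.with_subset(lag_only),
        "linear_all_features": replace(base, learner="linear"),
        "linear_lag_only": replace(base, learner="linear", feature_subset=lag_only),
    }


def evaluate_hurdle(model: FittedHurdle, test: pd.DataFrame) -> dict[str, MetricReport]:
    """Region-stratified out-of-sample report for a fitted hurdle."""
    p = model.predict_proba(test)
    cls = (p >= model.tau).astype(int)
    level_pred = model.smear * np.exp(model.predict_log(test))
    level_obs = np.where(test["outcome_hours"] > 0,
                         np.exp(test["outcome_log"].fillna(0.0)), 0.0)
    regions = (test["mpa_region"].values if "mpa_region" in test.columns
               else np.array(["outside"] * len(test)))
    return stratified_report(p, cls, level_pred, test["outcome_occurrence"].values,
                             level_obs, regions)


def run_comparators(train: pd.DataFrame, plan: FoldPlan, test: pd.DataFrame,
                    schema, base_spec: HurdleSpec, horizon: int = 1) -> pd.DataFrame:
    """Fit all four specifications and emit one comparable metric row per
    specification and scope."""
    frames = []
    for name, spec in comparator_specs(base_spec).items():
        model = fit_hurdle(train, plan, spec, schema, horizon=horizon)
        reports = evaluate_hurdle(model, test)
        frames.append(reports_to_frame(reports, specification=name, horizon=horizon))
    return pd.concat(frames, ignore_index=True)
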