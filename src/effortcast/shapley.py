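"""Sampling-based Shapley attribution with background marginalization.

Shapley values are estimated by Monte-Carlo permutation sampling: for each
random feature ordering, features are switched one by one from a background
row's value to the foreground row's value, and each feature is credited with
the resulting change in prediction, averaged over the full background sample
and over orderings. Because every ordering telescopes, local accuracy is
exact by construction for any number of orderings:

    base + sum_j phi_j = f(x),  base = mean over background of f

Stage-1 attributions live on the probability scale and stage-2 on the
log-intensity scale; group attributions follow from additivity by summing
member features per observation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .features import FEATURE_GROUPS

PAPER_GROUP_NAMES = {
    "mpa": "MPA Implementation",
    "environmental": "Environmental",
    "geographic": "Geographic",
    "governance": "Governance",
    "economic": "Economic",
    "technological": "Technological",
}


@dataclass
class ShapleyResult:
    """Per-observation, per-feature attributions phi plus the base value."""

    values: np.ndarray  # (n_foreground, n_features)
    base_value: float
    feature_names: list[str]
    foreground: pd.DataFrame
    predictions: np.ndarray
    n_samples: int
    seed: int

    def mean_abs(self) -> pd.Series:
        return pd.Series(np.abs(self.values).mean(axis=0), index=self.feature_names,
                         name="mean_abs_phi").sort_values(ascending=False)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.values.shape[0]):
            for j, name in enumerate(self.feature_names):
                rows.append({"observation": i, "feature": name,
                             "feature_value": self.foreground.iloc[i][name],
                             "phi": self.values[i, j]})
        return pd.DataFrame(rows)

    def summary_json(self, path, group_map: Mapping[str, str] | None = None) -> None:
        payload = {"base_value": self.base_value,
                   "mean_abs_phi": self.mean_abs().to_dict()}
        if group_map is not None:
            payload["group_mean_abs_phi"] = group_shapley(self, group_map)[1].to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def shapley(predict: Callable[[pd.DataFrame], np.ndarray], foreground: pd.DataFrame,
            background: pd.DataFrame, n_samples: int = 2000, seed: int = 0) -> ShapleyResult:
    """Monte-Carlo permutation-sampling Shapley values.

    ``n_samples`` counts (ordering x background row) model-evaluation passes;
    the number of orderings is ``ceil(n_samples / len(background))``.
    Deterministic given ``seed``.
    """
    features = list(foreground.columns)
    p = len(features)
    if len(background) == 0:
        raise ValueError("background must be nonempty")
    if n_samples < p + 2:
        raise ValueError(f"n_samples must be >= n_features + 2 = {p + 2}")
    rng = np.random.default_rng(seed)
    n_fg, n_bg = len(foreground), len(background)
    n_perm = max(1, int(np.ceil(n_samples / n_bg)))

    bg = background[features].reset_index(drop=True)
    fg = foreground[features].reset_index(drop=True)
    base_preds = np.asarray(predict(bg), dtype=float)
    base = float(base_preds.mean())

    # tiled design: for each foreground row, a copy of every background row
    tiled = pd.concat([bg] * n_fg, ignore_index=True)
    fg_rep = fg.loc[fg.index.repeat(n_bg)].reset_index(drop=True)
    base_tile = np.tile(base_preds, n_fg)

    phi = np.zeros((n_fg, p))
    for _ in range(n_perm):
        order = rng.permutation(p)
        current = tiled.copy()
        prev = base_tile.copy()
        for j in order:
            col = features[j]
            current[col] = fg_rep[col].values
            new = np.asarray(predict(current), dtype=float)
            delta = (new - prev).reshape(n_fg, n_bg).mean(axis=1)
            phi[:, j] += delta
            prev = new
    phi /= n_perm

    preds = np.asarray(predict(fg), dtype=float)
    return ShapleyResult(values=phi, base_value=base, feature_names=features,
                         foreground=fg, predictions=preds,
                         n_samples=n_perm * n_bg, seed=seed)


def stage1_predictor(model) -> Callable[[pd.DataFrame], np.ndarray]:
    """Class-1 probability of a fitted hurdle's stage 1."""
    return lambda X: model.stage1.predict_proba(X)[:, 1]


def stage2_predictor(model) -> Callable[[pd.DataFrame], np.ndarray]:
    """Log-intensity prediction of a fitted hurdle's stage 2."""
    return lambda X: model.stage2.predict(X)


def default_group_map(feature_names) -> dict[str, str]:
    """The eight reporting groups: the seven thematic groups with previous
    fishing effort and year kept as their own singletons."""
    lookup = {}
    for g, feats in FEATURE_GROUPS.items():
        for name, _ in feats:
            if g == "residual":
                lookup[name] = "Previous fishing effort" if name == "lag_log_effort" else "Year"
            else:
                lookup[name] = PAPER_GROUP_NAMES[g]
    return {n: lookup[n] for n in feature_names if n in lookup}


def group_shapley(result: ShapleyResult, group_map: Mapping[str, str]):
    """Per-observation group values (sum of member phi) and the mean
    absolute group value across observations."""
    unmapped = [n for n in result.feature_names if n not in group_map]
    if unmapped:
        raise ValueError(f"features missing from group_map: {unmapped}")
    groups = sorted(set(group_map[n] for n in result.feature_names))
    per_obs = pd.DataFrame(0.0, index=range(result.values.shape[0]), columns=groups)
    for j, name in enumerate(result.feature_names):
        per_obs[group_map[name]] += result.values[:, j]
    summary = per_obs.abs().mean(axis=0).rename("mean_abs_group_phi")
    return per_obs, summary.sort_values(ascending=False)


def dependence_table(result: ShapleyResult, feature: str) -> pd.DataFrame:
    """(feature value, phi) pairs across the foreground, export-ready."""
    if feature not in result.feature_names:
        raise ValueError(f"feature {feature!r} not in the Shapley result")
    j = result.feature_names.index(feature)
    return pd.DataFrame({"feature_value": result.foreground[feature].values,
                         "phi": result.values[:, j]})
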