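"""Two-stage hurdle model of gridded fishing effort.

Stage 1 is a probability-emitting classifier for whether any fishing occurs;
stage 2 is a regressor for log effort density, log(h/m^2), fit on the
positive rows only. Hyperparameters for the default bagged-trees learners
are tuned over a 10-point maximin Latin-hypercube grid on time-based CV
folds (stage 1 by ROC AUC, stage 2 by sum-of-squares R^2 on smeared level
predictions); the classification threshold tau maximizes the mean
across-fold F1 over an exhaustive candidate set; retransformation bias is
corrected with Duan's nonparametric smearing estimator S = mean(exp(log
residual)). Composed prediction per pixel:

    hours = 1{p >= tau} * S * exp(yhat_log) * pixel_area
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .features import FeatureSchema
from .metrics import f1_score_binary, roc_auc, rsq_trad
from .panel import FoldPlan, fold_partitions


@dataclass(frozen=True)
class HurdleSpec:
    """Learner contract and tuning protocol for both stages."""

    learner: str = "random_forest"  # or "linear"
    n_trees: int = 500
    grid_size: int = 10
    min_n_range: tuple[int, int] = (2, 40)
    threshold: str | float = "tuned"  # tuned tau, or a fixed float
    feature_subset: tuple[str, ...] | None = None  # e.g. lag-only comparator
    seed: int = 0

    def with_subset(self, names: Sequence[str]) -> "HurdleSpec":
        return replace(self, feature_subset=tuple(names))


@dataclass
class FittedHurdle:
    """Stage-1 classifier + threshold tau + stage-2 regressor + smearing S."""

    stage1: Pipeline
    tau: float
    stage2: Pipeline
    smear: float
    horizon: int
    schema_hash: str
    feature_names: list[str]
    stage1_params: dict = field(default_factory=dict)
    stage2_params: dict = field(default_factory=dict)

    def check_schema(self, schema_hash: str) -> None:
        if schema_hash != self.schema_hash:
            raise ValueError("feature schema hash mismatch between fit and prediction")

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        _check_columns(X, self.feature_names)
        return self.stage1.predict_proba(X[self.feature_names])[:, 1]

    def predict_log(self, X: pd.DataFrame) -> np.ndarray:
        _check_columns(X, self.feature_names)
        return self.stage2.predict(X[self.feature_names])

    def predict_hours(self, X: pd.DataFrame, pixel_areas: np.ndarray) -> np.ndarray:
        """hours = 1{p >= tau} * S * exp(yhat_log) * area, elementwise."""
        p = self.predict_proba(X)
        yhat = self.predict_log(X)
        cls = (p >= self.tau).astype(float)
        return cls * self.smear * np.exp(yhat) * np.asarray(pixel_areas, dtype=float)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "stage1.pkl", "wb") as fh:
            pickle.dump(self.stage1, fh)
        with open(d / "stage2.pkl", "wb") as fh:
            pickle.dump(self.stage2, fh)
        with open(d / "metadata.json", "w") as fh:
            json.dump({"tau": self.tau, "smear": self.smear, "horizon": self.horizon,
                       "schema_hash": self.schema_hash, "feature_names": self.feature_names,
                       "stage1_params": self.stage1_params,
                       "stage2_params": self.stage2_params}, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "FittedHurdle":
        d = Path(directory)
        with open(d / "metadata.json") as fh:
            meta = json.load(fh)
        with open(d / "stage1.pkl", "rb") as fh:
            s1 = pickle.load(fh)
        with open(d / "stage2.pkl", "rb") as fh:
            s2 = pickle.load(fh)
        return cls(stage1=s1, tau=meta["tau"], stage2=s2, smear=meta["smear"],
                   horizon=meta["horizon"], schema_hash=meta["schema_hash"],
                   feature_names=meta["feature_names"],
                   stage1_params=meta["stage1_params"], stage2_params=meta["stage2_params"])


def _check_columns(X: pd.DataFrame, names: Sequence[str]) -> None:
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")


def _active_features(schema: FeatureSchema, spec: HurdleSpec) -> list[str]:
    names = schema.names
    if spec.feature_subset is not None:
        unknown = set(spec.feature_subset) - set(names)
        if unknown:
            raise ValueError(f"feature_subset names not in schema: {sorted(unknown)}")
        names = [n for n in names if n in spec.feature_subset]
    return names


def _encoder(schema: FeatureSchema, names: Sequence[str]) -> ColumnTransformer:
    cat = [n for n in names if schema.kinds.get(n) == "categorical"]
    num = [n for n in names if n not in cat]
    transformers = [("num", "passthrough", num)]
    if cat:
        transformers.append(("cat", OneHotEncoder(
            categories=[schema.categorical_levels[c] for c in cat],
            handle_unknown="ignore", sparse_output=False), cat))
    return ColumnTransformer(transformers)


def encoded_width(schema: FeatureSchema, names: Sequence[str]) -> int:
    w = 0
    for n in names:
        w += len(schema.categorical_levels[n]) if schema.kinds.get(n) == "categorical" else 1
    return w


def hyperparameter_grid(spec: HurdleSpec, n_encoded: int) -> list[dict]:
    """Seeded maximin Latin-hypercube draw of (mtry, min_n) combinations."""
    lo = np.array([1, spec.min_n_range[0]])
    hi = np.array([max(1, n_encoded), spec.min_n_range[1]])
    sampler = qmc.LatinHypercube(d=2, optimization="random-cd",
                                 rng=np.random.default_rng(spec.seed))
    pts = sampler.random(spec.grid_size)
    grid = []
    for x in pts:
        mtry = int(np.clip(np.floor(lo[0] + x[0] * (hi[0] - lo[0] + 1)), lo[0], hi[0]))
        min_n = int(np.clip(np.floor(lo[1] + x[1] * (hi[1] - lo[1] + 1)), lo[1], hi[1]))
        grid.append({"mtry": mtry, "min_n": min_n})
    return grid


def _make_stage1(spec: HurdleSpec, params: dict | None, schema: FeatureSchema,
                 names: Sequence[str]) -> Pipeline:
    if spec.learner == "random_forest":
        p = params or {}
        est = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=min(p.get("mtry", 1), encoded_width(schema, names)),
            min_samples_split=max(2, p.get("min_n", 2)),
            random_state=spec.seed, n_jobs=1)
    elif spec.learner == "linear":
        est = LogisticRegression(max_iter=2000)
    else:
        raise ValueError(f"unknown learner {spec.learner!r}")
    steps = [("encode", _encoder(schema, names))]
    if spec.learner == "linear":
        steps.append(("scale", StandardScaler()))
    return Pipeline(steps + [("model", est)])


def _make_stage2(spec: HurdleSpec, params: dict | None, schema: FeatureSchema,
                 names: Sequence[str]) -> Pipeline:
    if spec.learner == "random_forest":
        p = params or {}
        est = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_features=min(p.get("mtry", 1), encoded_width(schema, names)),
            min_samples_split=max(2, p.get("min_n", 2)),
            random_state=spec.seed, n_jobs=1)
    elif spec.learner == "linear":
        est = LinearRegression()
    else:
        raise ValueError(f"unknown learner {spec.learner!r}")
    return Pipeline([("encode", _encoder(schema, names)), ("model", est)])


def smearing_coefficient(log_residuals) -> float:
    """Duan's nonparametric smearing estimator: mean of exp(residual)."""
    r = np.asarray(log_residuals, dtype=float)
    if r.size == 0:
        raise ValueError("smearing coefficient undefined for empty residuals")
    return float(np.exp(r).mean())


def tune_stage1(train: pd.DataFrame, plan: FoldPlan, spec: HurdleSpec,
                schema: FeatureSchema) -> dict:
    """Pick the grid combination maximizing mean across-fold ROC AUC.

    Folds whose partitions are single-class are skipped with a warning; ties
    break toward smaller model complexity (fewer features per split, larger
    node size) and then grid order.
    """
    names = _active_features(schema, spec)
    grid = hyperparameter_grid(spec, encoded_width(schema, names))
    scores = np.full(len(grid), np.nan)
    folds = list(fold_partitions(train, plan))
    for gi, params in enumerate(grid):
        fold_scores = []
        for a, b in folds:
            ya, yb = a["outcome_occurrence"].values, b["outcome_occurrence"].values
            if len(np.unique(ya)) < 2 or len(np.unique(yb)) < 2:
                warnings.warn("single-class fold skipped for roc_auc", stacklevel=2)
                continue
            clf = _make_stage1(spec, params, schema, names)
            clf.fit(a[names], ya)
            fold_scores.append(roc_auc(clf.predict_proba(b[names])[:, 1], yb))
        if not fold_scores:
            raise ValueError("all folds single-class; stage-1 tuning impossible")
        scores[gi] = float(np.mean(fold_scores))
    best = max(range(len(grid)),
               key=lambda i: (scores[i], -grid[i]["mtry"], grid[i]["min_n"], -i))
    return grid[best]


def tune_stage2(train: pd.DataFrame, plan: FoldPlan, spec: HurdleSpec,
                schema: FeatureSchema) -> dict:
    """Pick the combination maximizing mean across-fold rsq_trad on level
    (smeared, backtransformed) predictions; smearing is refit inside each
    fold from the analysis-split residuals."""
    names = _active_features(schema, spec)
    grid = hyperparameter_grid(spec, encoded_width(schema, names))
    scores = np.full(len(grid), np.nan)
    folds = list(fold_partitions(train, plan))
    for gi, params in enumerate(grid):
        fold_scores = []
        for a, b in folds:
            a_pos = a[a["outcome_hours"] > 0]
            b_pos = b[b["outcome_hours"] > 0]
            if len(a_pos) < 2 or len(b_pos) < 2:
                warnings.warn("fold without enough positive rows skipped", stacklevel=2)
                continue
            reg = _make_stage2(spec, params, schema, names)
            reg.fit(a_pos[names], a_pos["outcome_log"].values)
            s = smearing_coefficient(a_pos["outcome_log"].values - reg.predict(a_pos[names]))
            level_pred = s * np.exp(reg.predict(b_pos[names]))
            level_obs = np.exp(b_pos["outcome_log"].values)
            fold_scores.append(rsq_trad(level_obs, level_pred))
        if not fold_scores:
            raise ValueError("no usable folds; stage-2 tuning impossible")
        scores[gi] = float(np.mean(fold_scores))
    best = max(range(len(grid)),
               key=lambda i: (scores[i], -grid[i]["mtry"], grid[i]["min_n"], -i))
    return grid[best]


def threshold_candidates(probabilities: np.ndarray) -> np.ndarray:
    """Exhaustive threshold set: midpoints of sorted unique probabilities,
    plus one candidate below the minimum and one above the maximum, so every
    achievable confusion matrix is reachable."""
    u = np.unique(np.asarray(probabilities, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    above = (u[-1] + 1.0) / 2.0 if u[-1] < 1.0 else np.nextafter(1.0, 2.0)
    return np.concatenate([[u[0] / 2.0], mids, [above]])


def select_threshold(train: pd.DataFrame, plan: FoldPlan, spec: HurdleSpec,
                     schema: FeatureSchema, stage1_params: dict | None) -> float:
    """tau maximizing the mean across-fold F1 over the exhaustive candidate
    set (smallest tau on ties). Falls back to 0.5 with a warning if no
    threshold yields a positive prediction with a true positive."""
    names = _active_features(schema, spec)
    per_fold = []
    for a, b in fold_partitions(train, plan):
        ya, yb = a["outcome_occurrence"].values, b["outcome_occurrence"].values
        if len(np.unique(ya)) < 2:
            continue
        clf = _make_stage1(spec, stage1_params, schema, names)
        clf.fit(a[names], ya)
        per_fold.append((clf.predict_proba(b[names])[:, 1], yb))
    if not per_fold:
        warnings.warn("no usable folds for threshold selection; tau = 0.5", stacklevel=2)
        return 0.5
    cands = threshold_candidates(np.concatenate([p for p, _ in per_fold]))
    mean_f1 = np.array([
        np.mean([f1_score_binary(y, p >= c) for p, y in per_fold]) for c in cands
    ])
    if mean_f1.max() <= 0.0:
        warnings.warn("no threshold achieves a true positive; tau = 0.5", stacklevel=2)
        return 0.5
    return float(cands[int(np.argmax(mean_f1))])


def fit_hurdle(train: pd.DataFrame, plan: FoldPlan, spec: HurdleSpec,
               schema: FeatureSchema, horizon: int = 1) -> FittedHurdle:
    """Tune (trees learner only), select tau, fit both stages on the full
    fitting partition, and compute the final smearing coefficient from its
    positive-row residuals."""
    names = _active_features(schema, spec)
    y_occ = train["outcome_occurrence"].values
    if train.empty or len(np.unique(y_occ)) < 2:
        raise ValueError("training data must contain both occurrence classes")
    pos = train[train["outcome_hours"] > 0]
    if pos.empty:
        raise ValueError("no positive-effort rows; stage 2 cannot be fit")

    if spec.learner == "random_forest":
        p1 = tune_stage1(train, plan, spec, schema)
        p2 = tune_stage2(train, plan, spec, schema)
    else:
        p1 = p2 = {}

    if spec.threshold == "tuned":
        tau = select_threshold(train, plan, spec, schema, p1 or None)
    else:
        tau = float(spec.threshold)

    stage1 = _make_stage1(spec, p1 or None, schema, names)
    stage1.fit(train[names], y_occ)
    stage2 = _make_stage2(spec, p2 or None, schema, names)
    stage2.fit(pos[names], pos["outcome_log"].values)
    resid = pos["outcome_log"].values - stage2.predict(pos[names])
    smear = smearing_coefficient(resid)

    return FittedHurdle(stage1=stage1, tau=tau, stage2=stage2, smear=smear,
                        horizon=horizon, schema_hash=schema.hash(),
                        feature_names=names, stage1_params=p1, stage2_params=p2)


def predict_hours(model: FittedHurdle, features: pd.DataFrame,
                  pixel_areas: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`FittedHurdle.predict_hours`."""
    return model.predict_hours(features, pixel_areas)
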