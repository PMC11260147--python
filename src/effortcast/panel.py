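"""Supervised dataset assembly: time-led outcomes, temporal and
leave-one-ocean-out splits, and time-based cross-validation folds.

Pair-years are indexed by ``outcome_year`` throughout: a row pairs features
at ``feature_year`` with effort at ``outcome_year = feature_year + t`` for
forecast horizon t, so the lag feature embedded in the features is a t-year
lag relative to the outcome.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable, log_density
from .grid import ToyWorld


@dataclass
class LeadDataset:
    """Rows of (pixel_id, feature_year, outcome_year) x features + outcome."""

    horizon: int
    df: pd.DataFrame  # features + outcome_hours, outcome_log, outcome_occurrence
    feature_names: list[str]
    schema_hash: str

    @property
    def pair_years(self) -> list[int]:
        return sorted(self.df["outcome_year"].unique())

    def X(self) -> pd.DataFrame:
        return self.df[self.feature_names]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class FoldPlan:
    """Time-based CV folds plus the terminal train/test split, as years."""

    folds: list[tuple[list[int], int]]  # (analysis outcome-years, assessment outcome-year)
    train_years: list[int] = field(default_factory=list)
    test_year: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"folds": [[list(a), b] for a, b in self.folds],
                       "train_years": self.train_years,
                       "test_year": self.test_year}, fh, indent=2, default=int)


def make_lead_dataset(features: FeatureTable, effort: pd.DataFrame,
                      world: ToyWorld, t: int) -> LeadDataset:
    """Pair features at year y with effort at year y + t.

    The number of pair-years shrinks with t: with n feature years, n - t
    pairs remain. Raises when fewer than one pair would remain.
    """
    if t < 1:
        raise ValueError("horizon t must be >= 1")
    f_years = sorted(features.df["year"].unique())
    e_years = set(effort["year"].unique())
    pairs = [(y, y + t) for y in f_years if y + t in e_years]
    if not pairs:
        raise ValueError(
            f"insufficient years for horizon t={t}: need at least {t + 1} "
            "overlapping feature/effort years")

    out = effort[["pixel_id", "year", "hours"]].copy()
    out["outcome_log"] = log_density(effort, world)
    out = out.rename(columns={"hours": "outcome_hours", "year": "outcome_year"})
    out["outcome_occurrence"] = (out["outcome_hours"] > 0).astype(int)

    frames = []
    for fy, oy in pairs:
        rows = features.df[features.df["year"] == fy].copy()
        rows = rows.rename(columns={"year": "feature_year"})
        if "year" in features.schema.names:
            rows["year"] = rows["feature_year"]  # the model's year feature
        rows["outcome_year"] = oy
        rows = rows.merge(out[out["outcome_year"] == oy], on=["pixel_id", "outcome_year"])
        frames.append(rows)
    df = pd.concat(frames, ignore_index=True)
    return LeadDataset(horizon=t, df=df, feature_names=list(features.schema.names),
                       schema_hash=features.schema.hash())


def temporal_split(dataset: LeadDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test = rows of the last outcome year; train = all earlier rows."""
    years = dataset.pair_years
    if len(years) < 2:
        raise ValueError("temporal split needs at least 2 pair-years")
    last = years[-1]
    test = dataset.df[dataset.df["outcome_year"] == last].reset_index(drop=True)
    train = dataset.df[dataset.df["outcome_year"] < last].reset_index(drop=True)
    return train, test


def spatiotemporal_splits(dataset: LeadDataset, ocean_labels: pd.Series):
    """One leave-one-ocean-out split per ocean.

    For ocean k: test = last pair-year restricted to ocean k; train = earlier
    pair-years from the other oceans only. Oceans with no pixels are skipped
    with a warning.
    """
    labels = ocean_labels.loc[dataset.df["pixel_id"]].values
    oceans = sorted(set(labels))
    if len(oceans) < 2:
        raise ValueError("leave-one-ocean-out requires at least 2 oceans")
    years = dataset.pair_years
    last = years[-1]
    out = {}
    for k in oceans:
        in_k = labels == k
        test = dataset.df[(dataset.df["outcome_year"] == last) & in_k]
        if test.empty:
            warnings.warn(f"ocean {k!r} has no test rows; skipped", stacklevel=2)
            continue
        train = dataset.df[(dataset.df["outcome_year"] < last) & ~in_k]
        out[k] = (train.reset_index(drop=True), test.reset_index(drop=True))
    return out


def make_time_folds(train: pd.DataFrame, scheme: str = "sliding") -> FoldPlan:
    """Sliding one-year folds over the training pair-years.

    For each candidate assessment year y (second through last training
    pair-year), the analysis split is the preceding pair-year (``sliding``)
    or all preceding pair-years (``cumulative``).
    """
    years = sorted(train["outcome_year"].unique())
    if len(years) < 2:
        raise ValueError("time-based folds need at least 2 training pair-years")
    folds = []
    for i in range(1, len(years)):
        if scheme == "sliding":
            analysis = [years[i - 1]]
        elif scheme == "cumulative":
            analysis = years[:i]
        else:
            raise ValueError(f"unknown fold scheme {scheme!r}")
        folds.append((analysis, years[i]))
    return FoldPlan(folds=folds, train_years=years)


def fold_partitions(train: pd.DataFrame, plan: FoldPlan):
    """Yield (analysis_rows, assessment_rows) per fold."""
    for analysis_years, assessment_year in plan.folds:
        a = train[train["outcome_year"].isin(analysis_years)]
        b = train[train["outcome_year"] == assessment_year]
        yield a.reset_index(drop=True), b.reset_index(drop=True)


def audit_no_leakage(train: pd.DataFrame, test: pd.DataFrame) -> bool:
    """Assert no (pixel_id, outcome_year) appears in both partitions."""
    a = set(map(tuple, train[["pixel_id", "outcome_year"]].values))
    b = set(map(tuple, test[["pixel_id", "outcome_year"]].values))
    return not (a & b)
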