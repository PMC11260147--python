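"""Counterfactual scenario engine: hypothetical MPA networks, BAU vs
scenario predictions, and their differences and aggregations.

Hypothetical networks close fully protected pixels at the start of the base
year. Ranked rules (``most_fished`` descending reference-year hours with
pixel-id tie-break; ``random`` a seeded permutation; ``unfished`` a seeded
sample of zero-effort pixels) are built from one ranking per seed, so the
networks for successive area targets are nested. Predictions for both the
business-as-usual (baseline network only) and each scenario (baseline union
hypothetical) use the same fitted per-horizon hurdle models on base-year
feature rows.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effort import ocean_graph
from .features import FeatureTable, build_feature_table, mpa_distance
from .grid import ToyWorld
from .hurdle import FittedHurdle
from .network import MPANetwork, MPARecord

DEFAULT_TARGETS = (0.03, 0.05, 0.10, 0.16, 0.20, 0.30)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    rule: str  # random | most_fished | unfished | file
    targets: tuple[float, ...] = DEFAULT_TARGETS
    seed: int = 0
    reference_effort_year: int | None = None
    path: str | None = None  # file rule

    def __post_init__(self):
        if list(self.targets) != sorted(self.targets):
            raise ValueError("targets must be sorted ascending")
        if self.rule not in {"random", "most_fished", "unfished", "file"}:
            raise ValueError(f"unknown scenario rule {self.rule!r}")


def _ranking(rule: str, world: ToyWorld, effort_reference: pd.Series, seed: int) -> np.ndarray:
    """Pixel closure order for a ranked rule (one ranking per seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7363656E]).spawn(1)[0])
    ocean = world.ocean_ids
    if rule == "random":
        return rng.permutation(ocean)
    hours = effort_reference.reindex(ocean).fillna(0.0)
    if rule == "most_fished":
        order = sorted(ocean, key=lambda p: (-hours.loc[p], p))
        return np.array(order, dtype=int)
    if rule == "unfished":
        zero = np.array([p for p in ocean if hours.loc[p] == 0.0], dtype=int)
        return rng.permutation(zero)
    raise ValueError(f"unknown ranked rule {rule!r}")


def build_network(rule: str, world: ToyWorld, effort_reference: pd.Series,
                  target: float, seed: int, start_date: dt.date | None = None,
                  name: str | None = None) -> MPANetwork:
    """Close pixels in rule order until the target ocean-area fraction is
    reached (within one pixel); full coverage, implemented at ``start_date``."""
    nets = build_networks(rule, world, effort_reference, [target], seed,
                          start_date=start_date, name=name)
    return nets[target]


def build_networks(rule: str, world: ToyWorld, effort_reference: pd.Series,
                   targets, seed: int, start_date: dt.date | None = None,
                   name: str | None = None) -> dict[float, MPANetwork]:
    """Nested networks across targets, sharing one seeded ranking."""
    if start_date is None:
        start_date = dt.date(int(max(world.config.years)), 1, 1)
    order = _ranking(rule, world, effort_reference, seed)
    areas = world.pixels["area_m2"].values
    ocean_area = areas[world.is_ocean].sum()
    cum = np.cumsum(areas[order]) if order.size else np.array([])
    out = {}
    for target in targets:
        goal = target * ocean_area
        k = int(np.searchsorted(cum, goal)) + 1 if cum.size else 0
        if k > order.size:
            maxf = cum[-1] / ocean_area if cum.size else 0.0
            raise ValueError(
                f"target {target:.0%} unreachable under rule {rule!r}; "
                f"max achievable {maxf:.1%}")
        closed = {int(p): 1.0 for p in order[:k]}
        rec = MPARecord(mpa_id=name or f"{rule}_{target:g}",
                        implementation_date=start_date, no_take=True, coverage=closed)
        out[target] = MPANetwork(records=[rec])
    return out


def scenario_features(world: ToyWorld, environment: pd.DataFrame, effort: pd.DataFrame,
                      network: MPANetwork, base_year: int, schema) -> FeatureTable:
    """Base-year feature rows under a given in-force network."""
    return build_feature_table(world, environment, effort, network,
                               years=[base_year], groups=schema.groups, schema=schema)


def run_bau(models: dict[int, FittedHurdle], world: ToyWorld, environment: pd.DataFrame,
            effort: pd.DataFrame, baseline_network: MPANetwork, base_year: int,
            schema) -> pd.DataFrame:
    """Predicted hours per pixel for each horizon under the baseline network
    only. Pure function of the baseline network and base-year data."""
    feats = scenario_features(world, environment, effort, baseline_network, base_year, schema)
    return _predict_all(models, feats, world)


def run_scenario(models: dict[int, FittedHurdle], world: ToyWorld, environment: pd.DataFrame,
                 effort: pd.DataFrame, baseline_network: MPANetwork,
                 scenario_network: MPANetwork, base_year: int, schema) -> pd.DataFrame:
    """Predicted hours with features recomputed under
    union(baseline, scenario); an empty scenario reproduces BAU exactly."""
    combined = baseline_network.union(scenario_network)
    feats = scenario_features(world, environment, effort, combined, base_year, schema)
    return _predict_all(models, feats, world)


def _predict_all(models: dict[int, FittedHurdle], feats: FeatureTable,
                 world: ToyWorld) -> pd.DataFrame:
    areas = world.pixels["area_m2"].loc[feats.df["pixel_id"]].values
    out = feats.df[["pixel_id"]].copy()
    for t, model in sorted(models.items()):
        model.check_schema(feats.schema.hash())
        out[f"hours_t{t}"] = model.predict_hours(feats.df, areas)
    return out.set_index("pixel_id")


def region_labels(world: ToyWorld, network: MPANetwork, year: int) -> pd.Series:
    cov = network.union_coverage(world, year)
    lab = np.where(cov >= 1.0 - 1e-9, "inside", np.where(cov > 1e-12, "partial", "outside"))
    return pd.Series(lab[world.ocean_ids], index=world.ocean_ids, name="region")


def distance_to_network(world: ToyWorld, network: MPANetwork, year: int) -> pd.Series:
    covered = network.covered_pixels(world, year)
    d = mpa_distance(world, covered)
    return pd.Series(d[world.ocean_ids], index=world.ocean_ids, name="distance_m")


def default_distance_bins(world: ToyWorld) -> list[tuple[str, float, float]]:
    """(label, lo_m, hi_m) distance bins in pixel-widths at the equator."""
    w = world.config.resolution_deg * 111_195.0
    return [("0-1", 0.0, 1 * w), ("1-2", 1 * w, 2 * w), ("2-4", 2 * w, 4 * w),
            (">4", 4 * w, np.inf)]


@dataclass
class ScenarioResult:
    """Pixel-level and aggregated BAU-vs-scenario differences per horizon."""

    pixel: pd.DataFrame  # pixel_id, region, distance bin, per-horizon hours & diffs
    aggregates: pd.DataFrame  # scope x horizon absolute and percent differences
    bins: pd.DataFrame  # distance-bin medians and sums per horizon
    n_excluded_pct: dict[int, int]  # pixels with BAU = 0 per horizon

    def global_percent(self, horizon: int) -> float:
        row = self.aggregates[(self.aggregates["scope"] == "global")
                              & (self.aggregates["horizon"] == horizon)]
        return float(row["pct_diff"].iloc[0])


def compare(scenario_preds: pd.DataFrame, bau_preds: pd.DataFrame,
            regions: pd.Series, distances: pd.Series,
            world: ToyWorld, bins=None) -> ScenarioResult:
    """Absolute and percent differences pixelwise and aggregated.

    Pixels with zero BAU prediction are excluded from pixel-level percent
    change (their count is reported) but included in every aggregate sum.
    """
    if not scenario_preds.index.equals(bau_preds.index):
        raise ValueError("scenario and BAU predictions cover different pixels")
    if bins is None:
        bins = default_distance_bins(world)
    horizons = sorted(int(c.split("_t")[1]) for c in bau_preds.columns if c.startswith("hours_t"))

    px = pd.DataFrame(index=bau_preds.index)
    px["region"] = regions.reindex(px.index)
    px["distance_m"] = distances.reindex(px.index)
    binlab = np.where(px["region"] != "outside", "inside", "")
    for lab, lo, hi in bins:
        sel = (px["region"] == "outside") & (px["distance_m"] > lo - 1e-9) & (px["distance_m"] <= hi)
        binlab = np.where(sel & (binlab == ""), lab, binlab)
    px["distance_bin"] = binlab

    n_excluded = {}
    agg_rows, bin_rows = [], []
    for t in horizons:
        b = bau_preds[f"hours_t{t}"]
        s = scenario_preds[f"hours_t{t}"]
        px[f"bau_t{t}"] = b
        px[f"scenario_t{t}"] = s
        px[f"abs_diff_t{t}"] = s - b
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (s - b) / b
        pct = pct.where(b > 0)
        px[f"pct_diff_t{t}"] = pct
        n_excluded[t] = int((b <= 0).sum())

        scopes = [("global", np.ones(len(px), dtype=bool))]
        scopes += [(r, (px["region"] == r).values) for r in ("inside", "partial", "outside")]
        for scope, mask in scopes:
            sb, ss = float(b[mask].sum()), float(s[mask].sum())
            agg_rows.append({"scope": scope, "horizon": t, "bau_hours": sb,
                             "scenario_hours": ss, "abs_diff": ss - sb,
                             "pct_diff": 100.0 * (ss - sb) / sb if sb > 0 else np.nan})
        order = ["inside"] + [lab for lab, *_ in bins]
        for lab in order:
            mask = (px["distance_bin"] == lab).values
            if not mask.any():
                continue
            sb, ss = float(b[mask].sum()), float(s[mask].sum())
            bin_rows.append({"distance_bin": lab, "horizon": t, "n": int(mask.sum()),
                             "median_pct_diff": float(pct[mask].median()),
                             "abs_diff": ss - sb,
                             "pct_diff": 100.0 * (ss - sb) / sb if sb > 0 else np.nan})

    return ScenarioResult(pixel=px.reset_index(), aggregates=pd.DataFrame(agg_rows),
                          bins=pd.DataFrame(bin_rows), n_excluded_pct=n_excluded)


def overlap_curve(networks: dict[float, MPANetwork], world: ToyWorld,
                  effort_reference: pd.Series, year: int | None = None) -> pd.DataFrame:
    """Percent of ocean area and of reference-year fishing hours inside each
    network's closed pixels."""
    total = float(effort_reference.sum())
    if total <= 0:
        raise ValueError("reference effort is zero; overlap undefined")
    areas = world.pixels["area_m2"]
    ocean_area = float(areas[world.is_ocean].sum())
    if year is None:
        year = max(world.config.years)
    rows = []
    for target, net in sorted(networks.items()):
        cov = net.union_coverage(world, year)
        closed = np.flatnonzero(cov > 1e-12)
        area_share = float((areas.values[closed] * cov[closed]).sum()) / ocean_area
        effort_share = float(effort_reference.reindex(closed).fillna(0.0).sum()) / total
        rows.append({"target": target, "area_pct": 100.0 * area_share,
                     "effort_pct": 100.0 * effort_share})
    return pd.DataFrame(rows)
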