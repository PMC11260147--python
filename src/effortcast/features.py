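"""Model features on any grid + MPA network + effort panel.

Eight feature groups are computed per ocean pixel-year: MPA implementation
(11 features), environmental (12), geographic (7), governance (6), economic
(3), technological (2), and residual effects (lagged log effort and year).
Distances to MPAs and EEZ boundaries use the land-avoiding ocean-graph
metric; neighbourhood coverages use Moore rings; categorical levels are
frozen into a :class:`FeatureSchema` at training time and reused verbatim at
prediction time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .distance import nearest_source_distance
from .effort import ocean_graph
from .grid import ToyWorld, haversine_m
from .network import MPANetwork

NO_MPA_YEARS_SINCE = -1.0

FEATURE_GROUPS: dict[str, list[tuple[str, str]]] = {
    # group -> [(feature name, kind)]
    "mpa": [
        ("mpa_distance_m", "numeric"),
        ("mpa_years_since", "numeric"),
        ("mpa_frac_pixel", "numeric"),
        ("mpa_frac_nb1", "numeric"),
        ("mpa_frac_nb2", "numeric"),
        ("mpa_region", "categorical"),
        ("mpa_frac_of_year", "numeric"),
        ("mpa_lead1_full", "boolean"),
        ("mpa_lead1_partial", "boolean"),
        ("mpa_lead2_full", "boolean"),
        ("mpa_lead2_partial", "boolean"),
    ],
    "environmental": [(c, "numeric") for c in (
        "sst_mean", "sst_sd", "sst_anom_mean", "sst_anom_sd",
        "chl_mean", "chl_sd", "wind_mean", "wind_sd",
        "enso_mean", "enso_sd", "pdo_mean", "pdo_sd")],
    "geographic": [
        ("lat", "numeric"), ("lon", "numeric"),
        ("shore_distance_m", "numeric"), ("seamount_distance_m", "numeric"),
        ("depth_m", "numeric"), ("ocean", "categorical"),
        ("mesopelagic", "categorical"),
    ],
    "governance": [
        ("eez_sovereign", "categorical"), ("eez_fraction", "numeric"),
        ("eez_distance_m", "numeric"), ("eez_nearest_sovereign", "categorical"),
        ("wb_region", "categorical"), ("governance_capacity", "categorical"),
    ],
    "economic": [
        ("port_distance_m", "numeric"),
        ("fuel_price_mean", "numeric"), ("fuel_price_sd", "numeric"),
    ],
    "technological": [("reception_a", "numeric"), ("reception_b", "numeric")],
    "residual": [("lag_log_effort", "numeric"), ("year", "numeric")],
}

DEFAULT_GROUPS = tuple(FEATURE_GROUPS)


def feature_names(groups: Iterable[str] = DEFAULT_GROUPS) -> list[str]:
    return [name for g in groups for name, _ in FEATURE_GROUPS[g]]


@dataclass
class FeatureSchema:
    """Frozen description of the feature set: names, groups, kinds,
    categorical levels, the zero-effort log floor, and the no-MPA distance
    sentinel. The hash guards train/predict consistency."""

    groups: tuple[str, ...]
    kinds: dict[str, str]
    categorical_levels: dict[str, list[str]]
    lag_floor: float
    no_mpa_distance_m: float

    @property
    def names(self) -> list[str]:
        return list(self.kinds)

    def hash(self) -> str:
        payload = {
            "groups": list(self.groups),
            "kinds": self.kinds,
            "levels": self.categorical_levels,
            "lag_floor": self.lag_floor,
            "no_mpa_distance_m": self.no_mpa_distance_m,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "groups": list(self.groups), "kinds": self.kinds,
                "categorical_levels": self.categorical_levels,
                "lag_floor": self.lag_floor,
                "no_mpa_distance_m": self.no_mpa_distance_m,
                "hash": self.hash(),
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            d = json.load(fh)
        return cls(groups=tuple(d["groups"]), kinds=d["kinds"],
                   categorical_levels=d["categorical_levels"],
                   lag_floor=d["lag_floor"], no_mpa_distance_m=d["no_mpa_distance_m"])


@dataclass
class FeatureTable:
    """Rows of (pixel_id, year) x named features plus the frozen schema."""

    df: pd.DataFrame  # columns: pixel_id, year, <features>
    schema: FeatureSchema

    def rows_for_year(self, year: int) -> pd.DataFrame:
        return self.df[self.df["year"] == year].reset_index(drop=True)

    def to_csv(self, path, sidecar_path=None) -> None:
        self.df.to_csv(path, index=False)
        if sidecar_path is not None:
            self.schema.to_json(sidecar_path)


# --- individual operations -----------------------------------------------


def rasterize_union(network: MPANetwork, world: ToyWorld, year: int) -> np.ndarray:
    """Per-pixel union coverage fraction of MPAs implemented on or before
    ``year``; 0 where no no-take record overlaps."""
    return network.union_coverage(world, year)


def mpa_distance(world: ToyWorld, mpa_pixels) -> np.ndarray:
    """Land-avoiding distance (m) to the nearest MPA pixel, 0 inside."""
    mpa_pixels = np.asarray(list(mpa_pixels), dtype=int)
    if mpa_pixels.size == 0:
        raise ValueError("mpa_pixels must be nonempty")
    if not world.is_ocean[mpa_pixels].all():
        raise ValueError("mpa_pixels must be ocean pixels")
    d = dijkstra(ocean_graph(world), directed=False, indices=mpa_pixels, min_only=True)
    return d


def no_mpa_distance_sentinel(world: ToyWorld) -> float:
    """Documented sentinel used before the first MPA exists:
    twice the maximum pairwise great-circle distance between ocean centroids."""
    cached = getattr(world, "_no_mpa_sentinel", None)
    if cached is not None:
        return cached
    ids = world.ocean_ids
    lats = world.pixels["lat"].values[ids]
    lons = world.pixels["lon"].values[ids]
    best = 0.0
    for i in range(len(ids)):
        d = haversine_m(lats[i], lons[i], lats, lons).max()
        best = max(best, float(d))
    world._no_mpa_sentinel = 2.0 * best
    return world._no_mpa_sentinel


def _ring_fraction(world: ToyWorld, coverage: np.ndarray, ring: int) -> np.ndarray:
    """Area-weighted mean coverage over the Moore ring of each ocean pixel."""
    areas = world.pixels["area_m2"].values
    out = np.zeros(len(world.pixels))
    for p in world.ocean_ids:
        ring_ids = world.moore_ring(int(p), ring)
        if ring_ids.size == 0:
            continue
        w = areas[ring_ids]
        out[p] = float((coverage[ring_ids] * w).sum() / w.sum())
    return out


def mpa_pixel_features(world: ToyWorld, network: MPANetwork, year: int) -> pd.DataFrame:
    """The seven non-lead MPA features for every ocean pixel.

    ``years_since`` uses the oldest record covering the pixel; for outside
    pixels it is inherited from the record owning the nearest covered pixel.
    Before any MPA exists, distance takes the no-MPA sentinel and
    years_since is -1.
    """
    ids = world.ocean_ids
    cov = network.union_coverage(world, year)
    recs = network.implemented(year)
    n_pix = len(world.pixels)

    if not recs:
        dist = np.full(n_pix, no_mpa_distance_sentinel(world))
        years_since = np.full(n_pix, NO_MPA_YEARS_SINCE)
        frac_year = np.zeros(n_pix)
    else:
        sources = np.flatnonzero(cov > 1e-12)
        dmat = dijkstra(ocean_graph(world), directed=False, indices=sources)
        dist = dmat.min(axis=0)
        nearest_src = sources[dmat.argmin(axis=0)]
        desig = network.designation_years(world, year)
        years_since = np.array([year - desig[int(s)] for s in nearest_src], dtype=float)
        fy_map = network.pixel_frac_of_year(world, year)
        frac_year = np.zeros(n_pix)
        for p, v in fy_map.items():
            frac_year[p] = v
        frac_year[cov <= 1e-12] = 0.0  # outside pixels always 0

    region = np.where(cov >= 1.0 - 1e-9, "inside",
                      np.where(cov > 1e-12, "partial", "outside"))

    nb1 = _ring_fraction(world, cov, 1)
    nb2 = _ring_fraction(world, cov, 2)

    return pd.DataFrame({
        "pixel_id": ids,
        "mpa_distance_m": dist[ids],
        "mpa_years_since": years_since[ids],
        "mpa_frac_pixel": cov[ids],
        "mpa_frac_nb1": nb1[ids],
        "mpa_frac_nb2": nb2[ids],
        "mpa_region": region[ids],
        "mpa_frac_of_year": frac_year[ids],
    })


def future_coverage_flags(world: ToyWorld, network: MPANetwork, year: int) -> pd.DataFrame:
    """Four booleans per ocean pixel: {1-, 2-year lead} x {fully, partially
    covered}, computed from implementation dates only."""
    ids = world.ocean_ids
    out = {"pixel_id": ids}
    for lead in (1, 2):
        cov = np.zeros(len(world.pixels))
        for rec in network.implemented_in(year + lead):
            for p, f in rec.pixel_fractions(world).items():
                cov[p] = 1.0 - (1.0 - cov[p]) * (1.0 - f)
        out[f"mpa_lead{lead}_full"] = cov[ids] >= 1.0 - 1e-9
        out[f"mpa_lead{lead}_partial"] = (cov[ids] > 1e-12) & (cov[ids] < 1.0 - 1e-9)
    return pd.DataFrame(out)


def eez_features(world: ToyWorld, training_pixels=None,
                 min_share: float = 0.01) -> pd.DataFrame:
    """Governance features per ocean pixel.

    Sovereign labels holding less than ``min_share`` of the training pixels
    collapse to ``"other"`` (``high_seas`` is never collapsed); the EEZ
    boundary distance uses the land-avoiding graph metric with all
    EEZ-covered pixels as sources, so it is 0 inside EEZs.
    """
    px = world.pixels
    ids = world.ocean_ids
    if training_pixels is None:
        training_pixels = ids
    training_pixels = np.asarray(training_pixels, dtype=int)
    if training_pixels.size == 0:
        raise ValueError("training pixel set is empty; label bucketing is undefined")

    sov = px["eez_sovereign"].values.astype(object)
    shares = pd.Series(sov[training_pixels]).value_counts(normalize=True)
    kept = {s for s, v in shares.items() if v >= min_share or s == "high_seas"}

    groups = {}
    for s in sorted(set(sov[ids]) - {"high_seas"}):
        members = np.array([p for p in ids if sov[p] == s and px["eez_fraction"].values[p] > 0])
        if members.size:
            groups[s] = members
    if groups:
        dist, who = nearest_source_distance(ocean_graph(world), groups, len(px))
    else:
        dist = np.full(len(px), np.inf)
        who = np.array(["high_seas"] * len(px), dtype=object)

    def bucket(label):
        return label if label in kept else "other"

    rows = []
    for p in ids:
        own = sov[p]
        frac = float(px["eez_fraction"].values[p])
        if own != "high_seas":
            d, near = 0.0, own
        else:
            d, near = float(dist[p]), who[p] if who[p] is not None else "high_seas"
        rows.append((p, bucket(own), frac, d, bucket(str(near)),
                     px["wb_region"].values[p], px["governance_capacity"].values[p]))
    return pd.DataFrame(rows, columns=["pixel_id", "eez_sovereign", "eez_fraction",
                                       "eez_distance_m", "eez_nearest_sovereign",
                                       "wb_region", "governance_capacity"])


def lagged_log_effort(panel: pd.DataFrame, world: ToyWorld,
                      floor: float | None = None) -> tuple[pd.DataFrame, float]:
    """log(hours / pixel area) per pixel-year, with zero-effort rows carrying
    a documented floor (min positive log in the panel minus 1)."""
    areas = world.pixels["area_m2"]
    dens = panel["hours"].values / areas.loc[panel["pixel_id"]].values
    pos = dens > 0
    if floor is None:
        if not pos.any():
            raise ValueError("panel has no positive effort; log floor undefined")
        floor = float(np.log(dens[pos]).min() - 1.0)
    vals = np.full(len(panel), floor)
    vals[pos] = np.log(dens[pos])
    out = panel[["pixel_id", "year"]].copy()
    out["lag_log_effort"] = vals
    return out, floor


def log_density(panel: pd.DataFrame, world: ToyWorld) -> pd.Series:
    """log(h/m^2) outcome scale; NaN where hours are zero."""
    areas = world.pixels["area_m2"]
    dens = panel["hours"].values / areas.loc[panel["pixel_id"]].values
    with np.errstate(divide="ignore"):
        return pd.Series(np.where(dens > 0, np.log(np.where(dens > 0, dens, 1.0)), np.nan),
                         index=panel.index)


def build_feature_table(world: ToyWorld, environment: pd.DataFrame,
                        effort: pd.DataFrame, network: MPANetwork,
                        years: Iterable[int] | None = None,
                        groups: Iterable[str] = DEFAULT_GROUPS,
                        schema: FeatureSchema | None = None) -> FeatureTable:
    """Assemble the configured feature set, one row per ocean pixel-year.

    With ``schema`` given (prediction time) its categorical levels, lag
    floor, and sentinels are reused verbatim; otherwise they are fit from the
    supplied data and frozen into a new schema.
    """
    groups = tuple(groups)
    if years is None:
        years = sorted(environment["year"].unique())
    years = list(years)
    missing = sorted(set(years) - set(effort["year"].unique()))
    if "residual" in groups and missing:
        raise ValueError(f"effort panel is missing lag years: {missing}")

    px = world.pixels
    ids = world.ocean_ids
    env = environment.set_index(["year", "pixel_id"]).sort_index()

    static_geo = px.loc[ids, ["lat", "lon", "shore_distance_m", "seamount_distance_m",
                              "depth_m", "ocean", "mesopelagic"]].reset_index()
    static_tech = px.loc[ids, ["reception_a", "reception_b"]].reset_index()
    static_port = px.loc[ids, ["port_distance_m"]].reset_index()
    gov = eez_features(world) if "governance" in groups else None

    lag_floor = schema.lag_floor if schema is not None else None
    if "residual" in groups:
        lag_df, lag_floor = lagged_log_effort(effort, world, floor=lag_floor)
        lag_df = lag_df.set_index(["year", "pixel_id"]).sort_index()

    frames = []
    for y in years:
        row = pd.DataFrame({"pixel_id": ids, "year": y})
        if "mpa" in groups:
            row = row.merge(mpa_pixel_features(world, network, y), on="pixel_id")
            row = row.merge(future_coverage_flags(world, network, y), on="pixel_id")
            if schema is not None and not network.implemented(y):
                row["mpa_distance_m"] = schema.no_mpa_distance_m
        if "environmental" in groups:
            env_y = env.loc[y].loc[ids, ["sst_mean", "sst_sd", "sst_anom_mean", "sst_anom_sd",
                                         "chl_mean", "chl_sd", "wind_mean", "wind_sd",
                                         "enso_mean", "enso_sd", "pdo_mean", "pdo_sd"]]
            row = row.merge(env_y.reset_index(), on="pixel_id")
        if "geographic" in groups:
            row = row.merge(static_geo, on="pixel_id")
        if "governance" in groups:
            row = row.merge(gov, on="pixel_id")
        if "economic" in groups:
            row = row.merge(static_port, on="pixel_id")
            fuel = env.loc[y].iloc[0][["fuel_price_mean", "fuel_price_sd"]]
            row["fuel_price_mean"] = float(fuel["fuel_price_mean"])
            row["fuel_price_sd"] = float(fuel["fuel_price_sd"])
        if "technological" in groups:
            row = row.merge(static_tech, on="pixel_id")
        if "residual" in groups:
            row["lag_log_effort"] = lag_df.loc[y].loc[ids, "lag_log_effort"].values
        frames.append(row)
    df = pd.concat(frames, ignore_index=True)

    names = feature_names(groups)
    df = df[["pixel_id", "year"] + [n for n in names if n != "year"]]
    bad = df[[n for n in names if n != "year"]].isna()
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        rid = df.loc[bad[col], ["pixel_id", "year"]].iloc[0].to_dict()
        raise ValueError(f"feature {col!r} undefined for row {rid}")

    kinds = {name: kind for g in groups for name, kind in FEATURE_GROUPS[g]}
    if schema is None:
        levels = {}
        for name, kind in kinds.items():
            if kind == "categorical":
                levels[name] = sorted(df[name].astype(str).unique())
        schema = FeatureSchema(groups=groups, kinds=kinds, categorical_levels=levels,
                               lag_floor=lag_floor if lag_floor is not None else 0.0,
                               no_mpa_distance_m=no_mpa_distance_sentinel(world))
    else:
        for name, lv in schema.categorical_levels.items():
            if name in df.columns:
                vals = df[name].astype(str)
                fallback = "other" if "other" in lv else lv[0]
                df[name] = np.where(vals.isin(lv), vals, fallback)
    return FeatureTable(df=df, schema=schema)
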