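"""Toy ocean world: grid geometry, land mask, and static layers.

The world is a regular latitude/longitude lattice centred on the equator and
prime meridian. Each pixel carries a spherical-band area, a land/ocean flag,
and the static layers the feature engineering expects: EEZ assignment with
sovereign labels, ports, seamounts, depth, AIS reception quality, ocean and
mesopelagic categoricals, and a fleet label (one fleet per EEZ plus one for
the high seas).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

EARTH_RADIUS_M = 6_371_000.0


class WorldConfig(BaseModel):
    """Configuration of the synthetic gridded ocean."""

    n_lat: int = 18
    n_lon: int = 36
    resolution_deg: float = 10.0
    years: list[int] = Field(default_factory=lambda: list(range(2016, 2022)))
    land_fraction: float = 0.25
    n_eez: int = 4
    n_ports: int = 6
    n_seamounts: int = 12
    seed: int = 0

    model_config = {"frozen": True}

    @field_validator("n_lat", "n_lon")
    @classmethod
    def _positive(cls, v: int, info) -> int:
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1")
        return v

    @field_validator("land_fraction")
    @classmethod
    def _land_fraction_range(cls, v: float) -> float:
        if not (0.0 <= v < 0.5):
            raise ValueError("land_fraction must lie in [0, 0.5)")
        return v

    @field_validator("years")
    @classmethod
    def _years_contiguous(cls, v: list[int]) -> list[int]:
        if len(v) < 4:
            raise ValueError("years must contain at least 4 years")
        if list(v) != list(range(v[0], v[0] + len(v))):
            raise ValueError("years must be contiguous")
        return list(v)

    @model_validator(mode="after")
    def _grid_size(self) -> "WorldConfig":
        if self.n_lat * self.n_lon < 25:
            raise ValueError("n_lat * n_lon must be >= 25")
        if self.n_lat * self.resolution_deg > 180 + 1e-9:
            raise ValueError("n_lat * resolution_deg exceeds 180 degrees")
        if self.n_lon * self.resolution_deg > 360 + 1e-9:
            raise ValueError("n_lon * resolution_deg exceeds 360 degrees")
        return self


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres between (lat, lon) degree pairs."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class ToyWorld:
    """Grid geometry plus static layers, one row per pixel in ``pixels``."""

    config: WorldConfig
    lat_centers: np.ndarray  # (n_lat,)
    lon_centers: np.ndarray  # (n_lon,)
    pixels: pd.DataFrame  # indexed by pixel_id
    seamount_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def n_lat(self) -> int:
        return self.config.n_lat

    @property
    def n_lon(self) -> int:
        return self.config.n_lon

    @property
    def wraps_lon(self) -> bool:
        return abs(self.config.n_lon * self.config.resolution_deg - 360.0) < 1e-9

    @property
    def ocean_ids(self) -> np.ndarray:
        return self.pixels.index.values[self.pixels["is_ocean"].values]

    @property
    def is_ocean(self) -> np.ndarray:
        return self.pixels["is_ocean"].values

    @property
    def areas_m2(self) -> pd.Series:
        return self.pixels["area_m2"]

    def rowcol(self, pixel_id: np.ndarray | int):
        return np.divmod(pixel_id, self.n_lon)

    def pixel_id(self, row, col) -> np.ndarray:
        col = np.mod(col, self.n_lon) if self.wraps_lon else col
        return np.asarray(row) * self.n_lon + np.asarray(col)

    def pixel_bounds(self, pixel_id: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of a pixel's box in degrees."""
        r, c = self.rowcol(pixel_id)
        res = self.config.resolution_deg
        lat_top = self.lat_centers[r] + res / 2.0
        lon_left = self.lon_centers[c] - res / 2.0
        return (lon_left, lat_top - res, lon_left + res, lat_top)

    def moore_ring(self, pixel_id: int, ring: int) -> np.ndarray:
        """Pixel ids of the Moore (Chebyshev) ring at the given radius."""
        r, c = self.rowcol(pixel_id)
        out = []
        for dr in range(-ring, ring + 1):
            for dc in range(-ring, ring + 1):
                if max(abs(dr), abs(dc)) != ring:
                    continue
                rr, cc = r + dr, c + dc
                if rr < 0 or rr >= self.n_lat:
                    continue
                if not self.wraps_lon and (cc < 0 or cc >= self.n_lon):
                    continue
                out.append(self.pixel_id(rr, cc))
        return np.array(sorted(set(int(p) for p in out)), dtype=int)

    def export_static_csv(self, path) -> None:
        self.pixels.rename_axis("pixel_id").to_csv(path)

    def digest(self) -> str:
        payload = {
            "config": self.config.model_dump(),
            "pixels": hashlib.sha256(
                pd.util.hash_pandas_object(self.pixels, index=True).values.tobytes()
            ).hexdigest(),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _neighbors(r: int, c: int, n_lat: int, n_lon: int, wrap: bool, diag: bool):
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if diag:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for dr, dc in steps:
        rr, cc = r + dr, c + dc
        if rr < 0 or rr >= n_lat:
            continue
        if wrap:
            cc %= n_lon
        elif cc < 0 or cc >= n_lon:
            continue
        yield rr, cc


def _ocean_components(is_ocean: np.ndarray, n_lat: int, n_lon: int, wrap: bool) -> list[set[int]]:
    """4-connected components of the ocean mask."""
    seen = np.zeros(n_lat * n_lon, dtype=bool)
    comps = []
    for start in np.flatnonzero(is_ocean):
        if seen[start]:
            continue
        comp = set()
        stack = [int(start)]
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.add(p)
            r, c = divmod(p, n_lon)
            for rr, cc in _neighbors(r, c, n_lat, n_lon, wrap, diag=False):
                q = rr * n_lon + cc
                if is_ocean[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        comps.append(comp)
    return comps


def _grow_land(rng: np.random.Generator, n_lat: int, n_lon: int, wrap: bool, target: int) -> np.ndarray:
    """Grow contiguous land blobs until ``target`` pixels are land."""
    land = np.zeros(n_lat * n_lon, dtype=bool)
    if target <= 0:
        return land
    n_seeds = max(1, target // 30)
    seeds = rng.choice(n_lat * n_lon, size=n_seeds, replace=False)
    land[seeds] = True
    frontier = list(int(s) for s in seeds)
    while land.sum() < target and frontier:
        p = frontier[rng.integers(len(frontier))]
        r, c = divmod(p, n_lon)
        cands = [rr * n_lon + cc for rr, cc in _neighbors(r, c, n_lat, n_lon, wrap, diag=False) if not land[rr * n_lon + cc]]
        if not cands:
            frontier.remove(p)
            continue
        q = int(rng.choice(cands))
        land[q] = True
        frontier.append(q)
    return land


def _smooth_field(rng: np.random.Generator, lats: np.ndarray, lons: np.ndarray,
                  n_bumps: int = 6, scale_deg: float = 40.0) -> np.ndarray:
    """Smooth random surface: a sum of Gaussian bumps in degree space."""
    out = np.zeros_like(lats, dtype=float)
    for _ in range(n_bumps):
        lat0 = rng.uniform(lats.min(), lats.max())
        lon0 = rng.uniform(-180, 180)
        amp = rng.normal(0, 1)
        dlon = np.abs(lons - lon0)
        dlon = np.minimum(dlon, 360 - dlon)
        d2 = ((lats - lat0) ** 2 + dlon**2) / scale_deg**2
        out += amp * np.exp(-d2)
    return out


def generate_world(config: WorldConfig) -> ToyWorld:
    """Build the toy world deterministically from ``config.seed``.

    The land mask is grown as contiguous blobs and then any ocean pocket not
    4-connected to the main ocean body is filled in, so every ocean pixel is
    reachable from every other.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n_lat, n_lon = config.n_lat, config.n_lon
    res = config.resolution_deg
    n_pix = n_lat * n_lon
    wrap = abs(n_lon * res - 360.0) < 1e-9

    lat_top = n_lat * res / 2.0
    lat_centers = lat_top - (np.arange(n_lat) + 0.5) * res
    lon_centers = -n_lon * res / 2.0 + (np.arange(n_lon) + 0.5) * res

    rows, cols = np.divmod(np.arange(n_pix), n_lon)
    lats = lat_centers[rows]
    lons = lon_centers[cols]

    # spherical band area: R^2 * dlon * (sin(top) - sin(bottom))
    phi_top = np.radians(lats + res / 2.0)
    phi_bot = np.radians(lats - res / 2.0)
    areas = EARTH_RADIUS_M**2 * np.radians(res) * (np.sin(phi_top) - np.sin(phi_bot))

    target_land = int(round(config.land_fraction * n_pix))
    land = _grow_land(rng, n_lat, n_lon, wrap, target_land)
    is_ocean = ~land
    comps = _ocean_components(is_ocean, n_lat, n_lon, wrap)
    if not comps:
        raise ValueError("land mask left no ocean pixels")
    main = max(comps, key=len)
    for comp in comps:
        if comp is not main:
            for p in comp:
                is_ocean[p] = False

    ocean_ids = np.flatnonzero(is_ocean)

    # --- EEZ assignment: a coastal band around seeded anchors -------------
    coast = [int(p) for p in ocean_ids
             if any(not is_ocean[rr * n_lon + cc]
                    for rr, cc in _neighbors(*divmod(int(p), n_lon), n_lat, n_lon, wrap, diag=False))]
    anchor_pool = np.array(coast if len(coast) >= config.n_eez else ocean_ids)
    anchors = rng.choice(anchor_pool, size=min(config.n_eez, len(anchor_pool)), replace=False)

    eez_label = np.array(["high_seas"] * n_pix, dtype=object)
    eez_fraction = np.zeros(n_pix)
    band_radius = 3  # Chebyshev pixels
    arow, acol = np.divmod(anchors, n_lon)
    for p in ocean_ids:
        r, c = divmod(int(p), n_lon)
        dr = np.abs(arow - r)
        dc = np.abs(acol - c)
        if wrap:
            dc = np.minimum(dc, n_lon - dc)
        cheb = np.maximum(dr, dc)
        k = int(np.argmin(cheb))
        if cheb[k] <= band_radius:
            eez_label[p] = f"eez_{k:02d}"
            eez_fraction[p] = 1.0 if cheb[k] < band_radius else round(float(rng.uniform(0.3, 0.95)), 3)
    eez_label[~is_ocean] = "land"

    sovereigns = sorted(set(eez_label[is_ocean]) - {"high_seas"})
    wb_regions = {s: f"region_{ord(s[-1]) % 3}" for s in sovereigns}
    gov_levels = ["low", "medium", "high", "very_high", "no_data"]
    governance = {s: gov_levels[int(rng.integers(len(gov_levels)))] for s in sovereigns}

    wb_region = np.array([wb_regions.get(s, "high_seas") for s in eez_label], dtype=object)
    gov_cap = np.array([governance.get(s, "high_seas") for s in eez_label], dtype=object)

    # --- ports and seamounts ---------------------------------------------
    port_pool = np.array(coast if len(coast) >= config.n_ports else ocean_ids)
    ports = rng.choice(port_pool, size=min(config.n_ports, len(port_pool)), replace=False)
    n_sm = config.n_seamounts
    sm_ids = rng.choice(ocean_ids, size=min(n_sm, len(ocean_ids)), replace=False)
    seamount_points = np.column_stack([lats[sm_ids] + rng.uniform(-res / 4, res / 4, len(sm_ids)),
                                       lons[sm_ids] + rng.uniform(-res / 4, res / 4, len(sm_ids))])

    from .distance import build_ocean_graph, multi_source_distance

    graph = build_ocean_graph(lats, lons, is_ocean, n_lat, n_lon, wrap)
    dist_port = multi_source_distance(graph, ports, n_pix)
    dist_port[~is_ocean] = np.nan

    land_ids = np.flatnonzero(~is_ocean)
    if len(land_ids):
        dist_shore = np.array([haversine_m(lats[p], lons[p], lats[land_ids], lons[land_ids]).min()
                               for p in range(n_pix)])
        dist_shore[~is_ocean] = 0.0
    else:
        dist_shore = np.full(n_pix, 2.0e7)

    dist_seamount = np.array([
        haversine_m(lats[p], lons[p], seamount_points[:, 0], seamount_points[:, 1]).min()
        if len(seamount_points) else 2.0e7
        for p in range(n_pix)
    ])

    depth = 200.0 + 5300.0 * (1.0 - np.exp(-dist_shore / 2.0e6)) + 150.0 * _smooth_field(rng, lats, lons)
    depth = np.clip(depth, 10.0, None)

    reception_a = np.exp(3.5 + 0.8 * _smooth_field(rng, lats, lons))
    reception_b = np.exp(2.0 + 0.8 * _smooth_field(rng, lats, lons))

    # ocean basins: hemisphere x longitudinal thirds; mesopelagic: latitude bands
    lon_third = np.minimum((lons + 180.0) // 120.0, 2).astype(int)
    hemi = (lats < 0).astype(int)
    ocean_cat = np.array([f"ocean_{h * 3 + t}" for h, t in zip(hemi, lon_third)], dtype=object)
    meso = np.where(np.abs(lats) > 60, "polar", np.where(np.abs(lats) > 30, "temperate", "tropical"))

    is_port = np.zeros(n_pix, dtype=bool)
    is_port[ports] = True
    fleet = np.where(eez_label == "high_seas", "fleet_high_seas",
                     np.char.add("fleet_", eez_label.astype(str)))
    fleet[~is_ocean] = "none"

    pixels = pd.DataFrame({
        "lat": lats,
        "lon": lons,
        "area_m2": areas,
        "is_ocean": is_ocean,
        "eez_sovereign": eez_label,
        "eez_fraction": eez_fraction,
        "wb_region": wb_region,
        "governance_capacity": gov_cap,
        "is_port": is_port,
        "port_distance_m": dist_port,
        "shore_distance_m": dist_shore,
        "seamount_distance_m": dist_seamount,
        "depth_m": depth,
        "reception_a": reception_a,
        "reception_b": reception_b,
        "ocean": ocean_cat,
        "mesopelagic": meso.astype(object),
        "fleet": fleet,
    })
    pixels.index.name = "pixel_id"

    return ToyWorld(config=config, lat_centers=lat_centers, lon_centers=lon_centers,
                    pixels=pixels, seamount_points=seamount_points)
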