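"""MPA networks: records, union coverage, schedules, and file dialects.

An :class:`MPARecord` describes one marine protected area either as explicit
per-pixel coverage fractions (the canonical toy-scale CSV dialect) or as a
shapely polygon in lon/lat degrees (GeoJSON dialect, rasterized against the
grid's pixel boxes). Only fully no-take records participate in coverage and
feature computations.

Overlapping records are combined as a union, never a sum: polygon records are
unioned geometrically (exact), while fraction-only records — which carry no
sub-pixel geometry — combine under an independent-overlap convention
``1 - prod(1 - f_k)``, which is bounded by 1 and reduces to the identity for
a single record.
"""

from __future__ import annotations

import calendar
import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box, shape
from shapely.ops import unary_union

from .grid import ToyWorld


def _as_date(d) -> dt.date:
    if isinstance(d, dt.date):
        return d
    return dt.date.fromisoformat(str(d))


def fraction_of_year(implementation_date: dt.date, year: int) -> float:
    """Fraction of ``year`` during which a record was in force.

    Counts the implementation day through Dec 31 inclusive over the year's
    true day count (leap-aware); 1 for records implemented in earlier years,
    0 for records not yet implemented in ``year``.
    """
    d = _as_date(implementation_date)
    if d.year < year:
        return 1.0
    if d.year > year:
        return 0.0
    days_in_year = 366 if calendar.isleap(year) else 365
    in_force = (dt.date(year, 12, 31) - d).days + 1
    return in_force / days_in_year


@dataclass(frozen=True)
class MPARecord:
    mpa_id: str
    implementation_date: dt.date
    no_take: bool = True
    coverage: Mapping[int, float] | None = None  # pixel_id -> fraction
    geometry: object | None = None  # shapely geometry in lon/lat degrees

    def __post_init__(self):
        object.__setattr__(self, "implementation_date", _as_date(self.implementation_date))
        if (self.coverage is None) == (self.geometry is None):
            raise ValueError(f"record {self.mpa_id}: exactly one of coverage or geometry required")
        if self.coverage is not None:
            for p, f in self.coverage.items():
                if not (0.0 <= f <= 1.0):
                    raise ValueError(f"record {self.mpa_id}: fraction for pixel {p} outside [0, 1]")

    @property
    def designation_year(self) -> int:
        return self.implementation_date.year

    def pixel_fractions(self, world: ToyWorld) -> dict[int, float]:
        """Per-pixel coverage fractions on the world's grid."""
        if self.coverage is not None:
            n_pix = len(world.pixels)
            for p in self.coverage:
                if not (0 <= int(p) < n_pix):
                    raise ValueError(f"record {self.mpa_id}: unknown pixel_id {p}")
            return {int(p): float(f) for p, f in self.coverage.items() if f > 0}
        out = {}
        minx, miny, maxx, maxy = self.geometry.bounds
        for p in world.ocean_ids:
            lon0, lat0, lon1, lat1 = world.pixel_bounds(int(p))
            if lon1 < minx or lon0 > maxx or lat1 < miny or lat0 > maxy:
                continue
            cell = box(lon0, lat0, lon1, lat1)
            inter = self.geometry.intersection(cell)
            if not inter.is_empty:
                f = inter.area / cell.area
                if f > 1e-12:
                    out[int(p)] = min(1.0, f)
        return out


@dataclass
class MPANetwork:
    records: list[MPARecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.mpa_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate mpa_id in network")

    @property
    def no_take_records(self) -> list[MPARecord]:
        return [r for r in self.records if r.no_take]

    def implemented(self, year: int) -> list[MPARecord]:
        """No-take records implemented during or before ``year``."""
        return [r for r in self.no_take_records if r.implementation_date.year <= year]

    def implemented_in(self, year: int) -> list[MPARecord]:
        return [r for r in self.no_take_records if r.implementation_date.year == year]

    def earliest_year(self) -> int | None:
        recs = self.no_take_records
        return min(r.designation_year for r in recs) if recs else None

    def union_coverage(self, world: ToyWorld, year: int, effective: bool = False) -> np.ndarray:
        """Per-pixel union coverage of records implemented on or before ``year``.

        With ``effective=True`` each record's fractions are additionally scaled
        by its in-force fraction of ``year``, giving the full-year-equivalent
        coverage the behavioral model responds to.
        """
        n_pix = len(world.pixels)
        recs = self.implemented(year)
        geo = [r for r in recs if r.geometry is not None]
        frac = [r for r in recs if r.coverage is not None]
        keep_open = np.ones(n_pix)  # probability-style complement product

        if geo and not effective:
            union_geom = unary_union([r.geometry for r in geo])
            proxy = MPARecord("_union", dt.date(1900, 1, 1), True, geometry=union_geom)
            for p, f in proxy.pixel_fractions(world).items():
                keep_open[p] *= 1.0 - f
            geo = []

        for r in geo + frac:
            scale = fraction_of_year(r.implementation_date, year) if effective else 1.0
            if scale == 0.0:
                continue
            for p, f in r.pixel_fractions(world).items():
                keep_open[p] *= 1.0 - f * scale

        cov = 1.0 - keep_open
        return np.clip(cov, 0.0, 1.0)

    def covered_pixels(self, world: ToyWorld, year: int) -> np.ndarray:
        return np.flatnonzero(self.union_coverage(world, year) > 1e-12)

    def designation_years(self, world: ToyWorld, year: int) -> dict[int, int]:
        """Pixel -> oldest designation year among covering records as of ``year``."""
        out: dict[int, int] = {}
        for r in self.implemented(year):
            for p, f in r.pixel_fractions(world).items():
                if f > 1e-12:
                    out[p] = min(out.get(p, r.designation_year), r.designation_year)
        return out

    def pixel_frac_of_year(self, world: ToyWorld, year: int) -> dict[int, float]:
        """Pixel -> max in-force fraction of ``year`` among covering records."""
        out: dict[int, float] = {}
        for r in self.implemented(year):
            fy = fraction_of_year(r.implementation_date, year)
            for p, f in r.pixel_fractions(world).items():
                if f > 1e-12:
                    out[p] = max(out.get(p, 0.0), fy)
        return out

    def union(self, other: "MPANetwork") -> "MPANetwork":
        """Combine two networks; records present in both are kept once."""
        seen = {r.mpa_id for r in self.records}
        merged = list(self.records) + [r for r in other.records if r.mpa_id not in seen]
        return MPANetwork(records=merged)

    # --- file dialects ----------------------------------------------------

    def to_csv(self, path, world: ToyWorld) -> None:
        rows = []
        for r in self.no_take_records:
            for p, f in sorted(r.pixel_fractions(world).items()):
                rows.append((r.mpa_id, p, f, r.implementation_date.isoformat(), r.no_take))
        pd.DataFrame(rows, columns=["mpa_id", "pixel_id", "fraction",
                                    "implementation_date", "no_take"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MPANetwork":
        df = pd.read_csv(path)
        records = []
        for (mid, date, nt), g in df.groupby(["mpa_id", "implementation_date", "no_take"], sort=True):
            records.append(MPARecord(
                mpa_id=str(mid), implementation_date=_as_date(date), no_take=bool(nt),
                coverage=dict(zip(g["pixel_id"].astype(int), g["fraction"].astype(float))),
            ))
        return cls(records=records)

    @classmethod
    def from_geojson(cls, path) -> "MPANetwork":
        with open(path) as fh:
            gj = json.load(fh)
        records = []
        for feat in gj["features"]:
            props = feat.get("properties", {})
            records.append(MPARecord(
                mpa_id=str(props["mpa_id"]),
                implementation_date=_as_date(props["implementation_date"]),
                no_take=bool(props.get("no_take", True)),
                geometry=shape(feat["geometry"]),
            ))
        return cls(records=records)


def simulate_network(world: ToyWorld, seed: int, n_mpas: int = 16,
                     coverage_target: float = 0.12,
                     midyear_fraction: float = 1.0) -> MPANetwork:
    """Random historical MPA schedule: contiguous blobs implemented in
    staggered cohorts across the simulated years (all but the first and last
    year), some mid-year, mirroring the real world's rolling MPA expansion.

    Blob cores are fully covered; blob edges carry partial fractions so the
    inside/partial/outside region partition is exercised. ``coverage_target``
    is the approximate fraction of ocean area eventually covered.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D7061]).spawn(1)[0])
    years = world.config.years
    impl_years = years[1:-1] if len(years) > 2 else years[1:]
    ocean = list(world.ocean_ids)
    area = world.pixels["area_m2"].values
    ocean_area = area[world.is_ocean].sum()
    target_area = coverage_target * ocean_area

    taken: set[int] = set()
    records = []
    placed_area = 0.0
    for k in range(n_mpas):
        if placed_area >= target_area:
            break
        free = [p for p in ocean if p not in taken]
        if not free:
            break
        blob = {int(rng.choice(free))}
        size = int(rng.integers(2, 6))
        for _ in range(size - 1):
            frontier = set()
            for p in blob:
                for q in world.moore_ring(int(p), 1):
                    q = int(q)
                    if world.is_ocean[q] and q not in blob and q not in taken:
                        frontier.add(q)
            if not frontier:
                break
            blob.add(int(rng.choice(sorted(frontier))))
        # core pixels fully covered, one edge pixel partially covered
        cov = {p: 1.0 for p in blob}
        edge = sorted(
            q for p in blob for q in (int(x) for x in world.moore_ring(int(p), 1))
            if world.is_ocean[q] and q not in blob and q not in taken
        )
        if edge:
            cov[int(rng.choice(edge))] = round(float(rng.uniform(0.2, 0.8)), 3)
        year = int(impl_years[k % len(impl_years)])  # every cohort year represented
        if rng.random() < midyear_fraction:
            day = int(rng.integers(60, 330))
            date = dt.date(year, 1, 1) + dt.timedelta(days=day - 1)
        else:
            date = dt.date(year, 1, 1)
        records.append(MPARecord(mpa_id=f"mpa_{k:02d}", implementation_date=date,
                                 no_take=True, coverage=cov))
        taken |= set(cov)
        placed_area += sum(area[p] * f for p, f in cov.items())

    return MPANetwork(records=records)
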