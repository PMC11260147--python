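"""Hurdle-structured synthetic fishing effort with known behavioral responses.

Effort in a pixel-year is ``occurrence * exp(log-intensity) * area``:
occurrence is Bernoulli with probability driven by a latent attractiveness
(port and seamount proximity, productivity, a pixel random effect), and the
positive intensity is lognormal around an attractiveness- and
environment-driven mean, so the zero fraction and the skewed positive tail
are both structural.

MPAs act through a single expected-hours multiplier ``m`` per pixel-year:

* inside (effective coverage ``c`` after implementation, scaled by the
  in-force fraction of the implementation year): ``m = 1 - delta_inside *
  compliance * c``;
* outside: ``m = 1 + delta_outside * exp(-d / decay_km)`` with ``d`` the
  land-avoiding distance to the nearest implemented MPA (each record's pull
  scaled by its in-force fraction, the strongest record wins);
* the year before implementation, to-be-covered pixels get an anticipation
  bump ``(1 + anticipation)``;
* a fleet whose grounds become covered beyond ``exit_threshold`` departs
  entirely with probability ``p_fleet_exit`` (all-or-nothing per fleet).

``m`` multiplies the conditional intensity, leaving the occurrence margin
untouched except in the limit ``m = 0`` where hours (and hence occurrence)
are forced to zero. Expected hours therefore scale by exactly ``m``, which
keeps the closed-form recovery oracle (:func:`ground_truth_effect`) exact
and keeps the response expressible by a point-predicting hurdle model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator

from .distance import build_ocean_graph
from .grid import ToyWorld
from .network import MPANetwork, fraction_of_year


class BehaviorParams(BaseModel):
    """Generator knobs for the behavioral response to MPA implementation."""

    delta_inside: float = 0.8  # effort multiplier reduction inside, in [0, 1]
    compliance: float = 1.0
    delta_outside: float = -0.3  # signed near-boundary response
    decay_km: float = 1200.0  # e-folding distance of the outside response
    anticipation: float = 0.0  # pre-implementation effort bump
    p_fleet_exit: float = 0.0
    exit_threshold: float = 0.5
    trend: float = 0.02  # per-year multiplicative drift of baseline effort

    model_config = {"frozen": True}

    @field_validator("delta_inside", "compliance")
    @classmethod
    def _unit_interval(cls, v, info):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{info.field_name} must lie in [0, 1]")
        return v

    @field_validator("decay_km")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("decay_km must be > 0")
        return v

    @field_validator("anticipation", "p_fleet_exit")
    @classmethod
    def _non_negative(cls, v, info):
        if v < 0 or (info.field_name == "p_fleet_exit" and v > 1):
            raise ValueError(f"{info.field_name} out of range")
        return v


def ocean_graph(world: ToyWorld):
    """8-connected ocean graph with great-circle edge weights (cached)."""
    g = getattr(world, "_ocean_graph", None)
    if g is None:
        px = world.pixels
        g = build_ocean_graph(px["lat"].values, px["lon"].values, world.is_ocean,
                              world.n_lat, world.n_lon, world.wraps_lon)
        world._ocean_graph = g
    return g


def _outside_pull(world: ToyWorld, network: MPANetwork, year: int) -> np.ndarray:
    """max over records of exp(-d_rec / decay) * frac_of_year, per pixel.

    Returned without the decay applied; callers multiply by delta_outside.
    Distances are land-avoiding shortest paths from each record's covered
    pixels. Zero where no record is implemented.
    """
    from scipy.sparse.csgraph import dijkstra

    n_pix = len(world.pixels)
    pull_dist = np.full(n_pix, np.inf)
    pull_fy = np.zeros(n_pix)
    graph = ocean_graph(world)
    for rec in network.implemented(year):
        fy = fraction_of_year(rec.implementation_date, year)
        if fy <= 0:
            continue
        src = np.array([p for p, f in rec.pixel_fractions(world).items() if f > 1e-12], dtype=int)
        if src.size == 0:
            continue
        d = dijkstra(graph, directed=False, indices=src, min_only=True)
        better = d < pull_dist
        pull_dist[better] = d[better]
        pull_fy[better] = fy
    return pull_dist, pull_fy


def _fleet_exit_state(world: ToyWorld, network: MPANetwork, behavior: BehaviorParams,
                      years, seed: int | None):
    """Per fleet: first year its covered grounds exceed the exit threshold,
    and (when ``seed`` is given) the realized exit draw."""
    px = world.pixels
    fleets = sorted(set(px.loc[world.is_ocean, "fleet"]))
    area = px["area_m2"].values
    first_cross: dict[str, int] = {}
    for y in years:
        cov = network.union_coverage(world, y, effective=True)
        for f in fleets:
            if f in first_cross:
                continue
            mask = (px["fleet"].values == f)
            covered = (cov[mask] * area[mask]).sum() / area[mask].sum()
            if covered > behavior.exit_threshold:
                first_cross[f] = y
    draws = {}
    if seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x657869]).spawn(1)[0])
        for f in fleets:  # one draw per fleet in stable order
            draws[f] = bool(rng.random() < behavior.p_fleet_exit)
    return first_cross, draws


def behavior_multiplier(world: ToyWorld, network: MPANetwork, behavior: BehaviorParams,
                        year: int, expected: bool = True,
                        exit_state=None) -> np.ndarray:
    """Expected-hours multiplier ``m`` per pixel for one year.

    With ``expected=True`` the fleet-exit channel contributes its expectation
    ``(1 - p_fleet_exit)``; otherwise ``exit_state`` (from
    :func:`_fleet_exit_state`) supplies realized exits that zero the fleet.
    """
    n_pix = len(world.pixels)
    m = np.ones(n_pix)
    cov_eff = network.union_coverage(world, year, effective=True)
    inside = cov_eff > 1e-12
    m[inside] = 1.0 - behavior.delta_inside * behavior.compliance * cov_eff[inside]

    if behavior.delta_outside != 0.0:
        dist, fy = _outside_pull(world, network, year)
        outside = (~inside) & np.isfinite(dist) & world.is_ocean
        m[outside] *= 1.0 + behavior.delta_outside * np.exp(
            -dist[outside] / (behavior.decay_km * 1000.0)) * fy[outside]

    if behavior.anticipation > 0.0:
        next_cov = np.zeros(n_pix)
        for rec in network.implemented_in(year + 1):
            for p, f in rec.pixel_fractions(world).items():
                next_cov[p] = max(next_cov[p], f)
        m[next_cov > 1e-12] *= 1.0 + behavior.anticipation

    if behavior.p_fleet_exit > 0.0:
        first_cross = exit_state[0] if exit_state else _fleet_exit_state(
            world, network, behavior, world.config.years, None)[0]
        fleet = world.pixels["fleet"].values
        for f, y0 in first_cross.items():
            if year >= y0:
                mask = fleet == f
                if expected:
                    m[mask] *= 1.0 - behavior.p_fleet_exit
                elif exit_state and exit_state[1].get(f, False):
                    m[mask] = 0.0
    return m


def ground_truth_effect(world: ToyWorld, behavior: BehaviorParams,
                        network: MPANetwork, year: int) -> pd.Series:
    """Closed-form expected percent change in hours per ocean pixel
    (relative to the same world without any MPAs), for ``year``."""
    m = behavior_multiplier(world, network, behavior, year, expected=True)
    return pd.Series(100.0 * (m[world.is_ocean] - 1.0), index=world.ocean_ids,
                     name="pct_change")


def _baseline_latents(world: ToyWorld, rng: np.random.Generator):
    """Year-invariant pieces of the occurrence/intensity model."""
    px = world.pixels
    ocean = world.is_ocean

    def z(x):
        mu, sd = x[ocean].mean(), x[ocean].std()
        return (x - mu) / (sd if sd > 0 else 1.0)

    quality = (-0.5 * z(px["port_distance_m"].fillna(0).values)
               - 0.35 * z(px["seamount_distance_m"].values)
               + 0.3 * z(np.log(px["reception_a"].values))
               + 0.5 * rng.normal(0.0, 1.0, len(px)))
    return quality


def simulate_effort(world: ToyWorld, environment: pd.DataFrame, network: MPANetwork,
                    behavior: BehaviorParams, seed: int = 0,
                    sigma_log: float = 0.5, occ_intercept: float = 0.8,
                    mu_intercept: float = -21.0) -> pd.DataFrame:
    """Simulate the pixel-year effort panel with latent truth attached.

    Returns a long DataFrame with columns ``pixel_id, year, hours,
    occurrence, occurrence_prob, latent_log_intensity, applied_multiplier``;
    latent columns describe the generating process and are absent from real
    data. Deterministic given ``seed``; occurrence uses a fixed uniform draw
    per pixel-year so that re-simulations with different behavior parameters
    share common random numbers.
    """
    years = sorted(environment["year"].unique())
    first = network.earliest_year()
    if first is not None and first > max(years):
        raise ValueError("network implementation dates fall after the simulated years")

    ss = np.random.SeedSequence([seed, 0x666973])
    rng_static, rng_draws = (np.random.default_rng(s) for s in ss.spawn(2))
    quality = _baseline_latents(world, rng_static)

    exit_state = _fleet_exit_state(world, network, behavior, years, seed) \
        if behavior.p_fleet_exit > 0 else None

    ocean = world.is_ocean
    n_oc = int(ocean.sum())
    area = world.pixels["area_m2"].values[ocean]
    q = quality[ocean]
    y0 = years[0]

    env = environment.set_index(["year", "pixel_id"]).sort_index()
    frames = []
    for y in years:
        anom = env.loc[y, "sst_anom_mean"].values[ocean]
        logit_p = occ_intercept + 1.2 * q + 0.3 * anom
        p = 1.0 / (1.0 + np.exp(-logit_p))
        mu = (mu_intercept + 1.0 * q + 0.25 * anom
              + np.log1p(behavior.trend) * (y - y0))

        m = behavior_multiplier(world, network, behavior, y,
                                expected=False, exit_state=exit_state)[ocean]
        u = rng_draws.uniform(size=n_oc)
        eps = rng_draws.normal(0.0, sigma_log, n_oc)
        occurred = ((u < p) & (m > 0)).astype(int)
        log_int = mu + np.log(np.maximum(m, 1e-300)) + eps
        hours = occurred * np.exp(log_int) * area
        p_adj = np.where(m > 0, p, 0.0)

        frames.append(pd.DataFrame({
            "pixel_id": world.ocean_ids,
            "year": y,
            "hours": hours,
            "occurrence": occurred,
            "occurrence_prob": p_adj,
            "latent_log_intensity": mu + np.log(np.maximum(m, 1e-300)),
            "applied_multiplier": m,
        }))
    return pd.concat(frames, ignore_index=True)
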