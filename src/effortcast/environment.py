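"""Synthetic environmental covariates.

Emulates the aggregation of finer-resolution sources to pixel-year means and
standard deviations: sea surface temperature (latitudinal gradient plus an
interannual anomaly loaded on a shared climate index), chlorophyll, wind,
two global annual climate indices, and a global fuel price. All interannual
variation scales with ``interannual_scale`` so a zero value yields fields
that repeat identically across years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import ToyWorld, _smooth_field


def simulate_environment(world: ToyWorld, years=None, seed: int = 0,
                         interannual_scale: float = 1.0) -> pd.DataFrame:
    """One row per (pixel_id, year) with mean/sd environmental features.

    The pixel-mean SST anomaly is ``loading * index`` plus small noise, where
    the first climate index (ENSO-like) is shared across pixels within a
    year; its field mean therefore tracks the index closely.
    """
    years = list(years) if years is not None else list(world.config.years)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x656E76]).spawn(1)[0])
    px = world.pixels
    lats = px["lat"].values
    lons = px["lon"].values
    n_pix = len(px)
    s = float(interannual_scale)

    # static pixel bases
    sst_base = 29.0 - 28.0 * (np.abs(lats) / 90.0) ** 1.5
    sst_seasonal_sd = 1.0 + 3.0 * (np.abs(lats) / 90.0)
    anom_loading = 1.0 + 0.4 * _smooth_field(rng, lats, lons, n_bumps=4)
    chl_base = np.exp(-1.0 + 0.6 * _smooth_field(rng, lats, lons, n_bumps=5)
                      + 0.8 * (np.abs(lats) / 90.0))
    wind_base = 6.0 + 4.0 * (np.abs(lats) / 90.0) + _smooth_field(rng, lats, lons, n_bumps=4)

    # global annual indices (ENSO-like and PDO-like), monthly spread -> mean/sd
    enso = rng.normal(0.0, 1.0, len(years))
    pdo = rng.normal(0.0, 1.0, len(years))
    enso_sd = np.abs(rng.normal(0.25, 0.08, len(years)))
    pdo_sd = np.abs(rng.normal(0.25, 0.08, len(years)))
    fuel_mean = 400.0 + np.cumsum(rng.normal(0.0, 25.0, len(years)))
    fuel_sd = np.abs(rng.normal(30.0, 8.0, len(years)))

    frames = []
    for i, y in enumerate(years):
        anom = s * (anom_loading * enso[i] + rng.normal(0.0, 0.2, n_pix))
        frames.append(pd.DataFrame({
            "pixel_id": np.arange(n_pix),
            "year": y,
            "sst_mean": sst_base + anom,
            "sst_sd": sst_seasonal_sd + s * np.abs(rng.normal(0.0, 0.15, n_pix)),
            "sst_anom_mean": anom,
            "sst_anom_sd": 0.2 + s * np.abs(rng.normal(0.0, 0.1, n_pix)),
            "chl_mean": chl_base * np.exp(s * rng.normal(0.0, 0.1, n_pix)),
            "chl_sd": 0.3 * chl_base * (1.0 + s * np.abs(rng.normal(0.0, 0.2, n_pix))),
            "wind_mean": wind_base + s * rng.normal(0.0, 0.4, n_pix),
            "wind_sd": 1.5 + s * np.abs(rng.normal(0.0, 0.3, n_pix)),
            "enso_mean": s * enso[i],
            "enso_sd": 0.25 if s == 0 else s * enso_sd[i],
            "pdo_mean": s * pdo[i],
            "pdo_sd": 0.25 if s == 0 else s * pdo_sd[i],
            "fuel_price_mean": 400.0 if s == 0 else fuel_mean[i],
            "fuel_price_sd": 30.0 if s == 0 else s * fuel_sd[i],
        }))
    env = pd.concat(frames, ignore_index=True)
    return env
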