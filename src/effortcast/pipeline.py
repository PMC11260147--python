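"""Config-driven end-to-end runs.

A :class:`RunConfig` fully determines a run: toy-world geometry, behavioral
response, feature groups, horizons, learner protocol, and scenario suite.
``run_pipeline`` sequences simulate -> features -> fit -> evaluate ->
scenarios -> shapley, writing a deterministic artifact tree::

    world/  features/  models/  metrics/  scenarios/  shapley/  manifest.json

All randomness descends from the master seed through named substreams, so a
repeated run reproduces every artifact; each stage appends a JSON-lines log
record with its timing and seed.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .effort import BehaviorParams, ground_truth_effect, simulate_effort
from .environment import simulate_environment
from .features import DEFAULT_GROUPS, FeatureSchema, FeatureTable, build_feature_table
from .grid import ToyWorld, WorldConfig, generate_world
from .hurdle import FittedHurdle, HurdleSpec, fit_hurdle
from .network import MPANetwork, simulate_network
from .panel import (audit_no_leakage, make_lead_dataset, make_time_folds,
                    temporal_split)
from .robustness import evaluate_hurdle
from .metrics import reports_to_frame
from .scenarios import (ScenarioSpec, build_networks, compare, distance_to_network,
                        overlap_curve, region_labels, run_bau, run_scenario)
from .shapley import (default_group_map, group_shapley, shapley, stage1_predictor,
                      stage2_predictor)


class ScenarioConfig(BaseModel):
    name: str
    rule: str
    targets: list[float] = [0.03, 0.05, 0.10, 0.16, 0.20, 0.30]
    path: str | None = None


class ShapleyConfig(BaseModel):
    """Sampling sizes for the attribution stage. The library-level defaults
    (1,000 foreground / 100 background observations) are impractical for a
    toy-scale demo with 500-tree forests, so the pipeline defaults are
    smaller; local accuracy is exact at any budget."""

    enabled: bool = True
    n_foreground: int = 100
    n_background: int = 50
    n_samples: int = 1000


class HurdleConfig(BaseModel):
    learner: str = "random_forest"
    n_trees: int = 500
    grid_size: int = 10


class NetworkConfig(BaseModel):
    n_mpas: int = 8
    coverage_target: float = 0.07


class RunConfig(BaseModel):
    """Serializable, hashable description of a full run."""

    world: WorldConfig = Field(default_factory=WorldConfig)
    behavior: BehaviorParams = Field(default_factory=BehaviorParams)
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    feature_groups: list[str] = Field(default_factory=lambda: list(DEFAULT_GROUPS))
    horizons: list[int] = [1, 2, 3]
    hurdle: HurdleConfig = Field(default_factory=HurdleConfig)
    scenarios: list[ScenarioConfig] = Field(default_factory=lambda: [
        ScenarioConfig(name="random", rule="random"),
        ScenarioConfig(name="most_fished", rule="most_fished"),
        ScenarioConfig(name="unfished", rule="unfished"),
    ])
    shapley: ShapleyConfig = Field(default_factory=ShapleyConfig)
    run_fit: bool = True
    run_scenarios: bool = True
    run_shapley: bool = True
    seed: int = 0

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.model_dump(mode="json"),
                                         sort_keys=True).encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def _substream(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class _Log:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)

    def record(self, stage: str, seconds: float, seed: int | None = None, **extra):
        rec = {"stage": stage, "seconds": round(seconds, 3), "seed": seed, **extra}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every enabled stage and return the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run_log.jsonl")
    manifest: dict = {"config_hash": config.hash(), "stages": []}

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    world = generate_world(config.world)
    env = simulate_environment(world, seed=_substream(config.seed, "environment"))
    network = simulate_network(world, seed=_substream(config.seed, "network"),
                               n_mpas=config.network.n_mpas,
                               coverage_target=config.network.coverage_target)
    effort = simulate_effort(world, env, network, config.behavior,
                             seed=_substream(config.seed, "effort"))
    wdir = out / "world"
    wdir.mkdir(exist_ok=True)
    world.export_static_csv(wdir / "static_layers.csv")
    env.to_csv(wdir / "environment.csv", index=False)
    effort.to_csv(wdir / "effort.csv", index=False)
    network.to_csv(wdir / "network.csv", world)
    log.record("simulate", time.perf_counter() - t0, _substream(config.seed, "effort"))
    manifest["stages"].append("simulate")

    # --- features ---------------------------------------------------------
    t0 = time.perf_counter()
    table = build_feature_table(world, env, effort, network,
                                groups=config.feature_groups)
    fdir = out / "features"
    fdir.mkdir(exist_ok=True)
    table.to_csv(fdir / "features.csv", sidecar_path=fdir / "schema.json")
    log.record("features", time.perf_counter() - t0, n_features=len(table.schema.names))
    manifest["stages"].append("features")

    # --- fit + evaluate ---------------------------------------------------
    if not config.run_fit:
        manifest["n_ocean_pixels"] = int(world.is_ocean.sum())
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest

    models: dict[int, FittedHurdle] = {}
    metric_frames = []
    mdir = out / "models"
    for t in config.horizons:
        t0 = time.perf_counter()
        spec = HurdleSpec(learner=config.hurdle.learner, n_trees=config.hurdle.n_trees,
                          grid_size=config.hurdle.grid_size,
                          seed=_substream(config.seed, f"hurdle_t{t}"))
        dataset = make_lead_dataset(table, effort, world, t)
        train, test = temporal_split(dataset)
        assert audit_no_leakage(train, test)
        plan = make_time_folds(train)
        eval_model = fit_hurdle(train, plan, spec, table.schema, horizon=t)
        metric_frames.append(reports_to_frame(evaluate_hurdle(eval_model, test),
                                              horizon=t, split="temporal"))
        # final model for the simulations: refit on every pair-year
        full_plan = make_time_folds(dataset.df)
        final = fit_hurdle(dataset.df, full_plan, spec, table.schema, horizon=t)
        final.save(mdir / f"horizon_{t}")
        models[t] = final
        log.record("fit", time.perf_counter() - t0, spec.seed, horizon=t,
                   tau=final.tau, smear=final.smear)
    manifest["stages"] += ["fit", "evaluate"]
    (out / "metrics").mkdir(exist_ok=True)
    metrics_df = pd.concat(metric_frames, ignore_index=True)
    metrics_df.to_csv(out / "metrics" / "temporal_performance.csv", index=False)

    base_year = max(world.config.years)
    ref_effort = (effort[effort["year"] == base_year]
                  .set_index("pixel_id")["hours"])

    # --- scenarios --------------------------------------------------------
    if config.run_scenarios:
        t0 = time.perf_counter()
        sdir = out / "scenarios"
        sdir.mkdir(exist_ok=True)
        bau = run_bau(models, world, env, effort, network, base_year, table.schema)
        bau.to_csv(sdir / "bau_predictions.csv")
        agg_rows = []
        for sc in config.scenarios:
            seed = _substream(config.seed, f"scenario_{sc.name}")
            if sc.rule == "file":
                nets = {0.0: MPANetwork.from_csv(sc.path)}
            else:
                nets = build_networks(sc.rule, world, ref_effort, sc.targets, seed,
                                      start_date=dt.date(base_year, 1, 1), name=sc.name)
            ov = overlap_curve(nets, world, ref_effort)
            ov.insert(0, "scenario", sc.name)
            ov.to_csv(sdir / f"overlap_{sc.name}.csv", index=False)
            for target, net in nets.items():
                preds = run_scenario(models, world, env, effort, network, net,
                                     base_year, table.schema)
                combined = network.union(net)
                res = compare(preds, bau, region_labels(world, combined, base_year),
                              distance_to_network(world, combined, base_year), world)
                tag = f"{sc.name}_{int(round(100 * target))}pct"
                res.pixel.to_csv(sdir / f"pixels_{tag}.csv", index=False)
                agg = res.aggregates.copy()
                agg.insert(0, "scenario", sc.name)
                agg.insert(1, "target", target)
                agg_rows.append(agg)
        pd.concat(agg_rows, ignore_index=True).to_csv(sdir / "aggregates.csv", index=False)
        log.record("scenarios", time.perf_counter() - t0)
        manifest["stages"].append("scenarios")

    # --- shapley ----------------------------------------------------------
    if config.run_shapley:
        t0 = time.perf_counter()
        hdir = out / "shapley"
        hdir.mkdir(exist_ok=True)
        t = config.horizons[0]
        dataset = make_lead_dataset(table, effort, world, t)
        train, _ = temporal_split(dataset)
        rng = np.random.default_rng(_substream(config.seed, "shapley"))
        names = models[t].feature_names
        n_fg = min(config.shapley.n_foreground, len(train))
        n_bg = min(config.shapley.n_background, len(train))
        fg = train.iloc[rng.choice(len(train), n_fg, replace=False)][names]
        bgi = train.iloc[rng.choice(len(train), n_bg, replace=False)][names]
        gmap = default_group_map(names)
        for stage, fn in (("stage1", stage1_predictor(models[t])),
                          ("stage2", stage2_predictor(models[t]))):
            res = shapley(fn, fg, bgi, n_samples=config.shapley.n_samples,
                          seed=_substream(config.seed, f"shapley_{stage}"))
            res.to_long_frame().to_csv(hdir / f"{stage}_values.csv", index=False)
            res.summary_json(hdir / f"{stage}_summary.json", group_map=gmap)
        log.record("shapley", time.perf_counter() - t0)
        manifest["stages"].append("shapley")

    manifest["base_year"] = base_year
    manifest["n_ocean_pixels"] = int(world.is_ocean.sum())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
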