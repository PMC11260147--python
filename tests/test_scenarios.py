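"""Scenario engine: network construction rules, BAU identities, difference
accounting, and the overlap curve."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import effortcast as ec
from effortcast.network import MPANetwork
from effortcast.panel import make_time_folds
from effortcast.scenarios import DEFAULT_TARGETS, ScenarioSpec


@pytest.fixture(scope="module")
def reference(toy_run):
    eff = toy_run["effort"]
    year = max(toy_run["world"].config.years)
    return eff[eff["year"] == year].set_index("pixel_id")["hours"]


@pytest.fixture(scope="module")
def linear_models(toy_run, feature_table):
    """Fast per-horizon hurdle models (linear learners) on the toy world."""
    models = {}
    for t in (1, 2):
        ds = ec.make_lead_dataset(feature_table, toy_run["effort"], toy_run["world"], t)
        plan = make_time_folds(ds.df)
        models[t] = ec.fit_hurdle(ds.df, plan, ec.HurdleSpec(learner="linear", seed=0),
                                  feature_table.schema, horizon=t)
    return models


def test_ranked_networks_are_nested_across_targets(world, reference):
    year = max(world.config.years)
    for rule in ("random", "most_fished", "unfished"):
        nets = ec.build_networks(rule, world, reference, DEFAULT_TARGETS, seed=3)
        prev = set()
        for target in DEFAULT_TARGETS:
            closed = set(nets[target].records[0].coverage)
            assert prev <= closed
            prev = closed
            area = world.pixels["area_m2"]
            frac = area.loc[sorted(closed)].sum() / area[world.is_ocean].sum()
            one_pixel = area.max() / area[world.is_ocean].sum()
            assert target - 1e-12 <= frac <= target + one_pixel


def test_most_fished_covers_at_least_random_share(world, reference):
    nets_mf = ec.build_networks("most_fished", world, reference, [0.1], seed=5)
    nets_r = ec.build_networks("random", world, reference, [0.1], seed=5)
    curve_mf = ec.overlap_curve(nets_mf, world, reference)
    curve_r = ec.overlap_curve(nets_r, world, reference)
    assert curve_mf["effort_pct"].iloc[0] >= curve_r["effort_pct"].iloc[0]


def test_unfished_network_has_zero_overlap(world, reference):
    nets = ec.build_networks("unfished", world, reference, [0.03, 0.05], seed=2)
    curve = ec.overlap_curve(nets, world, reference)
    assert (curve["effort_pct"] == 0.0).all()


def test_unreachable_target_reports_maximum(world, reference):
    with pytest.raises(ValueError, match="max achievable"):
        ec.build_networks("unfished", world, reference, [0.9], seed=1)


def test_overlap_curve_monotone_and_saturates(world, reference):
    nets = ec.build_networks("most_fished", world, reference, DEFAULT_TARGETS, seed=1)
    curve = ec.overlap_curve(nets, world, reference)
    assert (np.diff(curve["effort_pct"]) >= -1e-9).all()
    # closing every fished pixel captures all effort
    fished = reference[reference > 0].index
    import datetime as dt
    from effortcast.network import MPARecord
    all_net = MPANetwork([MPARecord("all", dt.date(2021, 1, 1),
                                    coverage={int(p): 1.0 for p in fished})])
    full = ec.overlap_curve({1.0: all_net}, world, reference)
    assert full["effort_pct"].iloc[0] == pytest.approx(100.0)


def test_empty_and_identical_scenarios_reproduce_bau_exactly(toy_run, feature_table,
                                                             linear_models):
    world, env, eff, net = (toy_run["world"], toy_run["env"], toy_run["effort"],
                            toy_run["net"])
    base_year = max(world.config.years)
    bau = ec.run_bau(linear_models, world, env, eff, net, base_year,
                     feature_table.schema)
    empty = ec.run_scenario(linear_models, world, env, eff, net, MPANetwork([]),
                            base_year, feature_table.schema)
    pd.testing.assert_frame_equal(bau, empty)
    same = ec.run_scenario(linear_models, world, env, eff, net, net, base_year,
                           feature_table.schema)
    pd.testing.assert_frame_equal(bau, same)


def test_bau_vs_bau_differences_vanish(toy_run, feature_table, linear_models):
    world, env, eff, net = (toy_run["world"], toy_run["env"], toy_run["effort"],
                            toy_run["net"])
    base_year = max(world.config.years)
    bau = ec.run_bau(linear_models, world, env, eff, net, base_year,
                     feature_table.schema)
    res = ec.compare(bau, bau, ec.region_labels(world, net, base_year),
                     ec.distance_to_network(world, net, base_year), world)
    assert (res.aggregates["abs_diff"] == 0).all()
    valid = res.aggregates["pct_diff"].dropna()
    assert np.allclose(valid, 0.0)
    assert np.allclose(res.bins["median_pct_diff"].dropna(), 0.0)


def test_uniform_scaling_gives_linear_percent_difference(toy_run, feature_table,
                                                         linear_models):
    world, env, eff, net = (toy_run["world"], toy_run["env"], toy_run["effort"],
                            toy_run["net"])
    base_year = max(world.config.years)
    bau = ec.run_bau(linear_models, world, env, eff, net, base_year,
                     feature_table.schema)
    scaled = bau * 0.9
    res = ec.compare(scaled, bau, ec.region_labels(world, net, base_year),
                     ec.distance_to_network(world, net, base_year), world)
    assert res.global_percent(1) == pytest.approx(-10.0)


def test_regional_absolute_differences_sum_to_global(toy_run, feature_table,
                                                     linear_models, reference):
    world, env, eff, net = (toy_run["world"], toy_run["env"], toy_run["effort"],
                            toy_run["net"])
    base_year = max(world.config.years)
    snet = ec.build_network("random", world, reference, 0.1, seed=4,
                            start_date=dt.date(base_year, 1, 1))
    bau = ec.run_bau(linear_models, world, env, eff, net, base_year,
                     feature_table.schema)
    preds = ec.run_scenario(linear_models, world, env, eff, net, snet, base_year,
                            feature_table.schema)
    combined = net.union(snet)
    res = ec.compare(preds, bau, ec.region_labels(world, combined, base_year),
                     ec.distance_to_network(world, combined, base_year), world)
    for t in (1, 2):
        agg = res.aggregates[res.aggregates["horizon"] == t].set_index("scope")
        regional = agg.loc[["inside", "partial", "outside"], "abs_diff"].sum()
        assert regional == pytest.approx(agg.loc["global", "abs_diff"], rel=1e-9)
        # pixel-level conservation
        assert res.pixel[f"abs_diff_t{t}"].sum() == pytest.approx(
            agg.loc["global", "abs_diff"], rel=1e-9)


def test_scenario_changes_only_mpa_features(toy_run, feature_table, reference):
    from effortcast.scenarios import scenario_features

    world, env, eff, net = (toy_run["world"], toy_run["env"], toy_run["effort"],
                            toy_run["net"])
    base_year = max(world.config.years)
    snet = ec.build_network("random", world, reference, 0.1, seed=4,
                            start_date=dt.date(base_year, 1, 1))
    f_bau = scenario_features(world, env, eff, net, base_year, feature_table.schema).df
    f_scn = scenario_features(world, env, eff, net.union(snet), base_year,
                              feature_table.schema).df
    changed = [c for c in f_bau.columns if not f_bau[c].equals(f_scn[c])]
    assert changed and all(c.startswith("mpa_") for c in changed)
    # the in-force scenario sets no future-coverage flags
    assert not f_scn[["mpa_lead1_full", "mpa_lead1_partial",
                      "mpa_lead2_full", "mpa_lead2_partial"]].values.any()


def test_mismatched_pixel_sets_rejected(toy_run, feature_table, linear_models):
    world, env, eff, net = (toy_run["world"], toy_run["env"], toy_run["effort"],
                            toy_run["net"])
    base_year = max(world.config.years)
    bau = ec.run_bau(linear_models, world, env, eff, net, base_year,
                     feature_table.schema)
    with pytest.raises(ValueError, match="different pixels"):
        ec.compare(bau.iloc[:-5], bau, ec.region_labels(world, net, base_year),
                   ec.distance_to_network(world, net, base_year), world)


def test_scenario_spec_validation():
    with pytest.raises(ValueError, match="sorted"):
        ScenarioSpec(name="x", rule="random", targets=(0.1, 0.05))
    with pytest.raises(ValueError, match="rule"):
        ScenarioSpec(name="x", rule="bogus")
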