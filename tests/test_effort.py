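"""Hurdle-structured effort generator: behavioral multipliers, the
closed-form recovery oracle, and its stochastic properties."""

import numpy as np
import pandas as pd
import pytest

import effortcast as ec
from effortcast.effort import behavior_multiplier
from effortcast.grid import haversine_m
from effortcast.network import MPANetwork, MPARecord


@pytest.fixture(scope="module")
def one_mpa(small_world):
    p = int(small_world.ocean_ids[len(small_world.ocean_ids) // 2])
    net = MPANetwork([MPARecord("m0", "2018-01-01", coverage={p: 1.0})])
    return p, net


def test_full_suppression_zeroes_hours_inside(small_world, one_mpa):
    p, net = one_mpa
    beh = ec.BehaviorParams(delta_inside=1.0, compliance=1.0, delta_outside=0.0)
    env = ec.simulate_environment(small_world, seed=0)
    eff = ec.simulate_effort(small_world, env, net, beh, seed=0)
    post = eff[(eff["pixel_id"] == p) & (eff["year"] >= 2018)]
    assert (post["hours"] == 0).all()
    assert (post["occurrence"] == 0).all()


def test_zero_outside_response_leaves_outside_effort_unchanged(small_world, one_mpa):
    p, net = one_mpa
    env = ec.simulate_environment(small_world, seed=0)
    beh = ec.BehaviorParams(delta_outside=0.0, anticipation=0.0)
    base = ec.simulate_effort(small_world, env, MPANetwork([]), beh, seed=0)
    with_mpa = ec.simulate_effort(small_world, env, net, beh, seed=0)
    outside = with_mpa["pixel_id"] != p
    # common random numbers: outside pixels are bit-identical
    pd.testing.assert_frame_equal(base[outside].reset_index(drop=True),
                                  with_mpa[outside].reset_index(drop=True))


def test_outside_multiplier_at_one_efold_distance(small_world, one_mpa):
    # a pixel at d = decay_km with delta_outside = -0.5 -> 1 - 0.5/e = 0.8161
    p, net = one_mpa
    px = small_world.pixels
    neigh = [q for q in small_world.moore_ring(p, 1) if small_world.is_ocean[q]
             and abs(q - p) == 1][0]
    d_m = float(haversine_m(px.lat[p], px.lon[p], px.lat[neigh], px.lon[neigh]))
    beh = ec.BehaviorParams(delta_outside=-0.5, decay_km=d_m / 1000.0)
    m = behavior_multiplier(small_world, net, beh, 2020)
    assert m[neigh] == pytest.approx(1.0 - 0.5 * np.exp(-1.0), abs=1e-9)


def test_ground_truth_inside_equals_minus_effect(small_world, one_mpa):
    p, net = one_mpa
    beh = ec.BehaviorParams(delta_inside=0.8, compliance=1.0, delta_outside=0.0)
    gt = ec.ground_truth_effect(small_world, beh, net, 2020)
    assert gt.loc[p] == pytest.approx(-80.0)
    # with no outside response every other pixel is unchanged
    assert np.allclose(gt.drop(p), 0.0)


def test_midyear_implementation_scales_suppression(small_world):
    p = int(small_world.ocean_ids[4])
    # day 183 of 2020 (leap year): in force (366 - 183 + 1)/366 of the year
    net = MPANetwork([MPARecord("mid", "2020-07-01", coverage={p: 1.0})])
    beh = ec.BehaviorParams(delta_inside=0.8, compliance=1.0, delta_outside=0.0)
    fy = (366 - 183 + 1) / 366
    gt = ec.ground_truth_effect(small_world, beh, net, 2020)
    assert gt.loc[p] == pytest.approx(-80.0 * fy, abs=1e-6)
    assert ec.ground_truth_effect(small_world, beh, net, 2021).loc[p] == pytest.approx(-80.0)


def test_anticipation_bumps_year_before_implementation(small_world):
    p = int(small_world.ocean_ids[4])
    net = MPANetwork([MPARecord("m", "2019-01-01", coverage={p: 1.0})])
    beh = ec.BehaviorParams(anticipation=0.3, delta_outside=0.0)
    gt_prev = ec.ground_truth_effect(small_world, beh, net, 2018)
    assert gt_prev.loc[p] == pytest.approx(30.0)


def test_monte_carlo_mean_matches_closed_form(small_world, one_mpa):
    """Replicate means of simulated hours track the closed-form expected
    percent change within two standard errors, inside and near the MPA."""
    p, net = one_mpa
    beh = ec.BehaviorParams(delta_inside=0.8, delta_outside=-0.4, decay_km=1500.0)
    env = ec.simulate_environment(small_world, seed=0)
    gt = ec.ground_truth_effect(small_world, beh, net, 2020)
    near = [q for q in small_world.moore_ring(p, 1) if small_world.is_ocean[q]]

    ratios_inside, ratios_near = [], []
    for rep in range(150):
        base = ec.simulate_effort(small_world, env, MPANetwork([]), beh, seed=1000 + rep)
        trt = ec.simulate_effort(small_world, env, net, beh, seed=1000 + rep)
        b = base[base["year"] == 2020].set_index("pixel_id")["hours"]
        t = trt[trt["year"] == 2020].set_index("pixel_id")["hours"]
        ratios_inside.append(t.loc[p] / max(b.loc[p], 1e-12) if b.loc[p] > 0 else np.nan)
        ratios_near.append(t.loc[near].sum() / b.loc[near].sum() if b.loc[near].sum() > 0 else np.nan)

    for ratios, ids in ((ratios_inside, [p]), (ratios_near, near)):
        r = np.array(ratios)
        r = r[~np.isnan(r)]
        pct = 100.0 * (r.mean() - 1.0)
        se = 100.0 * r.std(ddof=1) / np.sqrt(len(r))
        expected = float(gt.loc[ids].mean())
        assert abs(pct - expected) < 2.0 * se + 1.0


def test_zero_fraction_matches_occurrence_complement(toy_run):
    eff = toy_run["effort"]
    zero_frac = (eff["hours"] == 0).mean()
    expected = 1.0 - eff["occurrence_prob"].mean()
    n = len(eff)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(zero_frac - expected) < 3.0 * se + 0.01


def test_effort_strictly_decreases_with_delta_inside(small_world, one_mpa):
    p, net = one_mpa
    env = ec.simulate_environment(small_world, seed=0)
    means = []
    for delta in (0.2, 0.5, 0.9):
        beh = ec.BehaviorParams(delta_inside=delta, delta_outside=0.0)
        eff = ec.simulate_effort(small_world, env, net, beh, seed=42)
        means.append(eff[(eff["pixel_id"] == p) & (eff["year"] >= 2018)]["hours"].mean())
    assert means[0] > means[1] > means[2]


def test_hours_positive_iff_occurrence(toy_run):
    eff = toy_run["effort"]
    assert ((eff["hours"] > 0) == (eff["occurrence"] == 1)).all()
    assert (eff["hours"] >= 0).all()


def test_simulation_deterministic_given_seed(small_world, one_mpa):
    _, net = one_mpa
    env = ec.simulate_environment(small_world, seed=0)
    beh = ec.BehaviorParams()
    a = ec.simulate_effort(small_world, env, net, beh, seed=7)
    b = ec.simulate_effort(small_world, env, net, beh, seed=7)
    pd.testing.assert_frame_equal(a, b)


def test_fleet_exit_zeroes_whole_fleet(small_world):
    # cover most of one EEZ fleet's grounds so the exit rule must trigger
    px = small_world.pixels
    fleets = px.loc[small_world.is_ocean, "fleet"].value_counts()
    fleet = [f for f in fleets.index if f != "fleet_high_seas"][0]
    members = px.index[(px["fleet"] == fleet) & small_world.is_ocean]
    net = MPANetwork([MPARecord("big", "2018-01-01",
                                coverage={int(p): 1.0 for p in members})])
    beh = ec.BehaviorParams(delta_inside=0.1, delta_outside=0.0,
                            p_fleet_exit=1.0, exit_threshold=0.5)
    env = ec.simulate_environment(small_world, seed=0)
    eff = ec.simulate_effort(small_world, env, net, beh, seed=3)
    post = eff[(eff["year"] >= 2018) & eff["pixel_id"].isin(members)]
    assert (post["hours"] == 0).all()
    # expectation-mode oracle reflects the exit probability
    gt = ec.ground_truth_effect(small_world, beh, net, 2020)
    assert np.allclose(gt.loc[list(members)], -100.0)


def test_invalid_behavior_params_rejected():
    with pytest.raises(Exception, match="delta_inside"):
        ec.BehaviorParams(delta_inside=1.4)
    with pytest.raises(Exception, match="decay_km"):
        ec.BehaviorParams(decay_km=0.0)
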