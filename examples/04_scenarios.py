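"""Counterfactual MPA-expansion scenarios against business as usual.

Closes 10% of the toy ocean under three rules (currently unfished pixels, a
random set, and the most-fished pixels), predicts effort under each network
versus the BAU baseline, and prints the global change, the network's overlap
with current effort, and the recovered inside-MPA effect next to the
generator's closed-form truth.
"""

import datetime as dt

import numpy as np

import effortcast as ec

world = ec.generate_world(ec.WorldConfig())
behavior = ec.BehaviorParams()
env = ec.simulate_environment(world, seed=1)
network = ec.simulate_network(world, seed=1)
effort = ec.simulate_effort(world, env, network, behavior, seed=1)
table = ec.build_feature_table(world, env, effort, network)

dataset = ec.make_lead_dataset(table, effort, world, t=1)
plan = ec.make_time_folds(dataset.df)
# a lighter forest than the 500-tree default keeps this demo under a minute
models = {1: ec.fit_hurdle(dataset.df, plan, ec.HurdleSpec(n_trees=100, seed=0),
                           table.schema, horizon=1)}

base_year = max(world.config.years)
ref = effort[effort["year"] == base_year].set_index("pixel_id")["hours"]
bau = ec.run_bau(models, world, env, effort, network, base_year, table.schema)
base_cov = network.union_coverage(world, base_year)
m_bau = ec.behavior_multiplier(world, network, behavior, base_year)

print("rule         overlap%  global-change%  inside median pred / truth")
for rule in ("unfished", "random", "most_fished"):
    snet = ec.build_network(rule, world, ref, 0.10, seed=1,
                            start_date=dt.date(base_year, 1, 1))
    combined = network.union(snet)
    preds = ec.run_scenario(models, world, env, effort, network, snet,
                            base_year, table.schema)
    res = ec.compare(preds, bau, ec.region_labels(world, combined, base_year),
                     ec.distance_to_network(world, combined, base_year), world)
    overlap = ec.overlap_curve({0.1: snet}, world, ref)["effort_pct"].iloc[0]
    newly = [p for p in snet.records[0].coverage if base_cov[p] == 0]
    px = res.pixel.set_index("pixel_id")
    pred = px.loc[newly, "pct_diff_t1"].dropna().median()
    m_scn = ec.behavior_multiplier(world, combined, behavior, base_year)
    truth = np.median(100 * (m_scn[newly] / m_bau[newly] - 1))
    print(f"{rule:12s} {overlap:7.1f}  {res.global_percent(1):13.1f}  "
          f"{pred:8.1f} / {truth:.1f}")
print("more overlap with current fishing -> deeper global decrease; the")
print("inside medians recover the generator's embedded behavioral response")
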