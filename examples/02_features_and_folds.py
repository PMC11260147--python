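"""Build the model features and the time-based training scaffolding.

Computes the 43-feature table (8 thematic groups), leads the outcome one
year, splits train/test temporally, and prints the fold plan and a leakage
audit — the backbone of honest temporal validation.
"""

import effortcast as ec

world = ec.generate_world(ec.WorldConfig())
env = ec.simulate_environment(world, seed=1)
network = ec.simulate_network(world, seed=1)
effort = ec.simulate_effort(world, env, network, ec.BehaviorParams(), seed=1)

table = ec.build_feature_table(world, env, effort, network)
groups = {}
for g, feats in ec.FEATURE_GROUPS.items():
    groups[g] = len(feats)
print(f"features: {len(table.schema.names)} across groups {groups}")

dataset = ec.make_lead_dataset(table, effort, world, t=1)
train, test = ec.temporal_split(dataset)
plan = ec.make_time_folds(train)
print(f"pair-years {[int(y) for y in dataset.pair_years]}: {len(train)} train rows, "
      f"{len(test)} test rows (outcome year {int(max(dataset.pair_years))})")
print("time-based CV folds (analysis -> assessment):",
      [([int(y) for y in a], int(b)) for a, b in plan.folds])
print("leakage audit passed:", ec.audit_no_leakage(train, test),
      "- no (pixel, outcome-year) pair appears on both sides")
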