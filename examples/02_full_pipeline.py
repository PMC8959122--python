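"""End-to-end synthetic study: simulate, cluster, estimate, compare costs.

A planted rest/easy/hard system (easy and hard tilt the resting-state
distribution toward the same rare states, hard more strongly) is pushed
through the full pipeline: activity simulation, cosine k-means
coarse-graining, kernel estimation, and trajectory-bootstrap bridge costs.
The planted ordering — hard costlier to reach than easy, and easy->hard
costlier than hard->easy — should be recovered with clear separation.
"""

import numpy as np

import statebridge as sb

spec = sb.make_planted_hierarchy(k=4, seed=11, n_subjects=15, frames_per_condition=150)
print("true bridge costs (nats):")
for (a, b), c in sorted(spec.true_costs.items()):
    print(f"  {a:>5s} -> {b:<5s} {c:.4f}")

seqs = sb.simulate_state_sequences(spec)
activity, truth = sb.simulate_activity(seqs, M=spec.channel_dim, seed=1)

model = sb.fit_cosine_kmeans(activity, spec.k, rng=2)
clustered = sb.states_from_assignments(activity, model.assignments, spec.k)
print(f"\nclustered {activity.n_frames} frames into {spec.k} states "
      f"(explained variance {model.explained_variance:.3f})")

ensembles = sb.bootstrap_cost_table(clustered, "rest", n_replicates=100, rng=3)
table = sb.pairwise_costs(ensembles)
print("\nbootstrap mean cost table (nats):")
print(table.to_frame().round(4))

asym = sb.asymmetry_matrix(table, baseline="rest")
print("\nasymmetry Diff(A,B) = cost(A->B) - cost(B->A), ascending from rest:")
print(asym.to_frame().round(4))

report = sb.ordering_consistency(table, "rest")
print(f"\nordering-consistency fraction: {report.fraction:.2f} "
      f"({report.n_consistent}/{report.n_pairs} pairs)")

tt = sb.bootstrap_ttest(
    ensembles[("easy", "hard")].values, ensembles[("hard", "easy")].values
)
print(f"easy->hard vs hard->easy: t = {tt.t:.1f}, df = {tt.df}, one-sided p = {tt.p:.3g}")
# A large positive t confirms the planted asymmetry: switching "up" the
# difficulty hierarchy is costlier than switching down.
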