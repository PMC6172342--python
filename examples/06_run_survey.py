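"""Run a small graph-construction survey end to end.

Simulates a moderately separated cohort, runs 2 clustering presets x 2
edge presets x 2 thresholds through features and leave-one-out surprise,
and prints the per-combination ranking plus the significance scan.
"""

from fcgraph import separable_config
from fcgraph.pipeline import PipelineConfig, run_survey

config = PipelineConfig(
    synthetic=separable_config(
        grid_shape=(8, 8, 4),
        cohort_sizes={"C": 8, "MCI": 6, "AD": 6},
        seed=11,
    ),
    clustering_presets={
        "ward_s": {"method": "ward", "k": 8, "p": 4},
        "atlas_s": {"method": "atlas", "n_regions": 8},
    },
    edge_presets=("BcorrU1", "BMITU1"),
    thresholds=(0.0, 0.2),
    subgraphs=("full",),
)
result = run_survey(config)

print("mean LOO negative surprise per combination (higher is better):")
ranked = result.surprise_table.sort_values("mean_surprise", ascending=False)
for _, row in ranked.iterrows():
    print(f"  {row['clustering']:>8} {row['edge']:>8} w_min={row['w_min']}: "
          f"{row['mean_surprise']: .3f}")
print(f"\nskipped combinations: {len(result.skipped)}")
sig = result.significance
hits = sig[sig["fraction"] > 0]
print(f"significance-scan cells with significant differences: {len(hits)}")
# Each surprise is the mean over 20 leave-one-out subjects of
# ln P(true condition); combinations close to 0 discriminate the planted
# condition differences well, and the scan counts which graph properties
# differ significantly between condition pairs.
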