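"""Alpha diversity of heavy vs light pools.

The 13C-heavy pool contains only the subcommunity that assimilated the
labeled substrate, so its Shannon diversity (SSU rRNA reads, nats) falls
below the 13C-light pool; the 12C contrast reflects only density sorting
of the same community and stays small.
"""
import warnings

warnings.filterwarnings("ignore", message=".*bands extend beyond.*")

from sipscope import RunConfig, heavy_light_diversity, simulate_experiment

cfg = RunConfig(n_taxa=20, n_labeled=5, read_depth=100_000, seed=1)
result = simulate_experiment(cfg)
summaries, diffs = heavy_light_diversity(result.libraries)

print(f"{'pool':<10} {'Shannon (nats)':>14} {'observed':>9} {'Chao1':>7}")
for label, d in summaries.items():
    print(f"{label:<10} {d.shannon:>14.3f} {d.observed_richness:>9} {d.chao1:>7.1f}")
print()
for iso, diff in diffs.items():
    print(f"{iso} heavy - light Shannon difference: {diff:+.3f} nats")
print()
print("The strongly negative 13C contrast is the diversity signature of")
print("labeling: only 5 of 20 genera reach the heavy window. Chao1 close to")
print("observed richness indicates the sequencing depth saturated the pools.")
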