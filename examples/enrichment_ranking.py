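"""Rank taxa by enrichment factor and compare against ground truth.

EF = heavy13C/light13C - heavy12C/light12C on genus-level relative
abundances of SSU rRNA reads. Positive EF indicates isotopic labeling;
the five designated assimilators should top the ranking by orders of
magnitude.
"""
import warnings

warnings.filterwarnings("ignore", message=".*bands extend beyond.*")

from sipscope import call_labeled, simulate_and_rank

ef, result = simulate_and_rank(n_taxa=20, n_labeled=5, alpha=1.0, depth=100_000, seed=1)
truth = result.labeled_genera

print(f"{'genus':<10} {'EF':>12} {'mean abund':>11} {'reads':>7}  {'call':<9} truth")
for row in ef.itertuples():
    called = "labeled" if row.ef > 1.0 else "-"
    is_true = "labeled" if row.feature_id in truth else "-"
    print(
        f"{row.feature_id:<10} {row.ef:>12.2f} {row.mean_rel_abundance:>11.4f} "
        f"{row.total_reads:>7}  {called:<9} {is_true}"
    )
print()
calls = set(call_labeled(ef, threshold=1.0))
print(f"called labeled: {sorted(calls)}")
print(f"ground truth:   {sorted(truth)}")
print(f"exact recovery: {calls == truth}")
print()
print("Labeled genera score EF >> 1 (their rRNA is essentially absent from the")
print("13C-light pool), while unlabeled genera sit near EF = -1: present in")
print("light fractions of both gradients but missing from the 13C-heavy pool.")
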