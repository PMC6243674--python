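"""GC bias of linear amplification on the mRNA portion of a library.

mRNA features are reweighted by w = exp(-kappa (GC - 50)) and resampled;
rRNA is untouched. With the default kappa the count-weighted mean mRNA GC
drops by roughly 2 percentage points, while SSU GC is identical — the
asymmetry used to diagnose amplification skew.
"""
import warnings

warnings.filterwarnings("ignore", message=".*bands extend beyond.*")

from sipscope import RunConfig, mean_gc_by_class, paired_two_tailed_t, simulate_experiment

cfg = RunConfig(n_taxa=20, n_labeled=5, read_depth=100_000, seed=1)
result = simulate_experiment(cfg)

diffs = []
print(f"{'pool':<10} {'mRNA GC unamp':>14} {'mRNA GC amp':>12} {'shift':>7}   SSU shift")
for label in result.libraries:
    unamp, amp = result.libraries[label], result.amplified[label]
    g0 = mean_gc_by_class(unamp, "mRNA")
    g1 = mean_gc_by_class(amp, "mRNA")
    s0 = mean_gc_by_class(amp, "SSU") - mean_gc_by_class(unamp, "SSU")
    diffs.append(g1 - g0)
    print(f"{label:<10} {g0:>14.2f} {g1:>12.2f} {g1 - g0:>7.2f}   {s0:+.3f}")

t, df, p = paired_two_tailed_t(diffs)
print()
print(f"paired two-tailed t-test on the four shifts: t={t:.2f}, df={df}, p={p:.4f}")
print("A consistently negative mRNA GC shift with untouched SSU GC is the")
print("expected signature of GC-selective linear amplification.")
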