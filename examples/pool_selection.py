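"""Pool selection on a hand-written qPCR gradient profile.

Seven fractions per gradient, densest first. The greedy rule grows each
pool from its gradient end inward until the cumulative RNA mass reaches
the 120 ng needed for direct sequencing — the "heaviest/lightest fractions
from which sufficient RNA could be obtained".
"""
from sipscope import GradientFraction, build_profile, select_pools

masses_12c = [5, 20, 60, 200, 400, 300, 15]  # unlabeled: one light band
masses_13c = [500, 400, 30, 10, 5, 5, 150]  # labeled: strong heavy band


def profile(masses, isotope, gid):
    fracs = [
        GradientFraction(gid, i + 1, 1.84 - i * 0.01, float(m))
        for i, m in enumerate(masses)
    ]
    return build_profile(fracs, isotope)


pools = select_pools(
    profile(masses_12c, "12C", "ctrl"),
    profile(masses_13c, "13C", "label"),
    min_mass=120,
)
for label, pool in pools.items():
    idx = [i for _, i in pool.member_fractions]
    lo, hi = pool.density_window
    print(f"{label:<10} fractions {idx} window {lo:.2f}-{hi:.2f} g/ml "
          f"mass {pool.pooled_mass:.0f} ng")
print()
print("12C-heavy pools fractions 1-4: fractions 1-3 alone hold only 85 ng,")
print("so the run extends to fraction 4 (285 ng >= 120). The light pools grow")
print("from fraction 7 upward; pools of one isotope never share a fraction.")
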