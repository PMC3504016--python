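"""Deterministic vs randomizing regions of the relative-fecundity plane.

For a two-state scenario, behavior is summarized by the relative fecundities
r1 = c_a/c_b (state 1, a favored) and r2 = d_a/d_b (state 2, b favored).
Whether the growth-optimal phenotype is deterministic or randomizing depends
only on (p, r1, r2); exact probability matching f* = p occurs on the locus
p (r1 - 1) = (1 - p) (1/r2 - 1).
"""

import numpy as np

from evogrowth import TwoStateScenario, matching_locus_r2, region_map, two_state_solve

p = 0.75
rmap = region_map(p, np.linspace(1.1, 8.0, 40), np.linspace(0.0, 0.95, 40))
df = rmap.to_dataframe()
print(f"p = {p}: region sizes over a 40x40 grid")
print(df["label"].value_counts().to_string())
print()

print("probability-matching locus (f* = p exactly):")
for r1 in (1.5, 2.0, 3.0, 5.0):
    r2 = matching_locus_r2(p, r1)
    res = two_state_solve(TwoStateScenario(p, r1, 1.0, 1.0, 1.0 / r2))
    print(f"  r1 = {r1:4.1f} -> r2 = {r2:.4f}, solver f* = {res.f_star:.6f}")
print()
print("as r1 grows the locus drives r2 toward 0: matching is optimal when")
print("each state is catastrophic for the wrong choice.")
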