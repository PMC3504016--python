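"""Growth-optimal nesting in the sunshine/rain environment.

With probability .75 the day is sunny: valley nests (action a) yield 3
offspring, plateau nests (action b) yield 0.  With probability .25 it rains
and the payoffs flip.  Always nesting in the valley maximizes expected
offspring but dies with the first rain; the growth-optimal phenotype
randomizes, matching the probability of sunshine.
"""

from evogrowth import canonical_model, log_growth_systematic, solve_systematic

model = canonical_model()
res = solve_systematic(model)
print(f"growth-optimal f* = {res.f_star:.4f}  ({res.regime_label.value})")
print(f"log growth at f*  = {res.growth_at_opt:.6f}  "
      f"(per-generation multiplier {2.718281828**res.growth_at_opt:.4f}x)")
print()
print("log growth rate by phenotype (systematic risk):")
for f in (0.2, 0.5, 0.75, 0.9, 1.0):
    a = log_growth_systematic(model, f)
    note = "extinct almost surely" if a == float("-inf") else (
        "grows" if a > 0 else "shrinks")
    print(f"  f = {f:4.2f}: alpha(f) = {a:9.6f}   -> {note}")
print()
print("f* = .75 is exact probability matching: the choice frequency equals")
print("the probability that the valley is the better choice.")
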