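"""How much intelligence does selection sustain when intelligence costs?

Intelligence is correlation rho between the choice indicator and the
fecundity difference Delta = x_a - x_b.  Free perfect correlation gives
growth log E[max(x_a, x_b)] at probability-matching behavior
f = Pr(x_a > x_b).  With a linear reproductive cost c(rho) = kappa * rho the
optimum has three regimes in kappa: matching with maximal correlation,
a tie with a continuum of optima, then mindless deterministic behavior.
"""

from evogrowth import (
    CostModel,
    canonical_model,
    perfect_intelligence_benchmark,
    solve_bounded,
    tie_kappa,
)

model = canonical_model("idiosyncratic")
bench = perfect_intelligence_benchmark(model)
print(f"perfect-intelligence benchmark: f = {bench['f']}, "
      f"growth = {bench['growth']:.6f} (= log 3)")
print()

print("kappa   f*      rho*    growth    regime")
for kappa in (0.0, 0.3, 0.6, 2 / 3, 0.7, 1.0, 5.0):
    res = solve_bounded(model, CostModel.linear(kappa))
    print(f"{kappa:5.3f}  {res.f_star:5.3f}  {res.rho_star:6.3f}  "
          f"{res.growth_at_opt:.6f}  {res.regime_label.value}")
print()

k_star = tie_kappa(model)
print(f"critical cost kappa* = {k_star:.6f}: below it, probability matching")
print("with full correlation is optimal; above it, intelligence is too")
print("expensive and the mindless mean-maximizing phenotype (f = 1) wins.")
print("At kappa* both attain the same growth -- a continuum of optima.")
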