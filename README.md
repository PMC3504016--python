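# evogrowth

Growth-optimal behavior, probability matching, and the evolution of bounded
intelligence in a binary-choice model of natural selection.

## The problem

Individuals in a population face one decision in their lifetime: take action
*a* or action *b*, receiving a random number of offspring *x<sub>a</sub>* or
*x<sub>b</sub>* drawn from a finite-support joint distribution. A phenotype
is the probability *f* of choosing *a*, inherited exactly by offspring.
Lineages compete by long-run geometric growth rate — the evolutionary
analogue of the Kelly criterion — and the phenotype with the highest growth
rate takes over the population exponentially fast.

The character of the optimum depends on how reproductive risk is shared:

* **Systematic risk** (one environmental draw per generation, shared by
  everyone): the growth rate is α(*f*) = E[log(*f x<sub>a</sub>* +
  (1−*f*) *x<sub>b</sub>*)]. The optimum is *f\** = 1 if
  E[*x<sub>b</sub>*/*x<sub>a</sub>*] ≤ 1, *f\** = 0 if
  E[*x<sub>a</sub>*/*x<sub>b</sub>*] ≤ 1, and otherwise the unique interior
  root of E[(*x<sub>a</sub>* − *x<sub>b</sub>*)/ω(*f*)] = 0 with
  ω(*f*) = *f x<sub>a</sub>* + (1−*f*) *x<sub>b</sub>* — randomizing,
  seemingly irrational behavior, including exact probability matching.
* **Idiosyncratic risk** (independent draws per individual): the growth rate
  is log(*f* μ<sub>a</sub> + (1−*f*) μ<sub>b</sub>) and deterministic
  mean-maximizing behavior always wins.

"Intelligence" is modeled as a correlation ρ between the choice indicator
and Δ = *x<sub>a</sub>* − *x<sub>b</sub>*, giving growth
log(*f* μ<sub>a</sub> + (1−*f*) μ<sub>b</sub> + ρ √(*f*(1−*f*)) σ<sub>Δ</sub>).
Free perfect correlation yields growth log E[max(*x<sub>a</sub>*,
*x<sub>b</sub>*)] at *f* = Pr(*x<sub>a</sub>* > *x<sub>b</sub>*); a
reproductive cost *c*(ρ), deducted from the correlation itself, bounds the
intelligence selection can sustain and produces a three-regime solution
(probability matching / tie / deterministic). See `docs/methods.md` for the
full model account, including the attainable-correlation bound
ρ<sub>max</sub>(*f*) from the comonotone coupling.

The package provides exact finite-sum evaluation of all growth functionals,
closed-form and numeric solvers, region maps, an exact-integer stochastic
population simulator, scenario I/O, a fixture generator, and a thin
`evogrowth` command-line interface.

## Worked example

The canonical scenario: sunshine with probability .75 makes valley nests
(action *a*) yield 3 offspring and plateau nests 0; rain flips the payoffs.

```python
from evogrowth import canonical_model, solve_systematic
res = solve_systematic(canonical_model())
print(res.f_star, res.regime_label.value, round(res.growth_at_opt, 6))
```

prints `0.75 randomizing 0.536277`: the growth-optimal phenotype nests in
the valley 75% of the time — exact probability matching — and its lineage
multiplies by e^0.536 ≈ 1.71 per generation. Always choosing the valley
(*f* = 1) maximizes expected offspring (2.25 vs 1.875) yet has growth −∞:
the first rainy generation removes the entire lineage. Running
`python examples/table_experiment.py` simulates five competing phenotypes
for 25 generations from 10 individuals each and summarizes 2000 replicates:

```
  f = 0.20: extinct by gen 25 in  93.75% of runs, modal terminal count 0, largest population in   0.0%
  f = 0.75: extinct by gen 25 in   3.50% of runs, modal terminal count 0, largest population in  70.5%
  f = 1.00: extinct by gen 25 in  99.95% of runs, modal terminal count 0, largest population in   0.1%
```

The other scripts in `examples/` demonstrate the region map of deterministic
vs randomizing behavior (`region_map.py`) and the cost-of-intelligence
analysis (`bounded_rationality.py`), which locates the critical cost
κ\* = 2/3 at which the canonical population abandons probability matching
for mindless determinism.

The CLI mirrors the library:

```
evogrowth solve --config scenario.json
evogrowth simulate --config scenario.json --replicates 2000
evogrowth region --p 0.75 --grid 200 --out region.csv
evogrowth intelligence --config scenario.json --cost linear --kappa 0.3
```

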