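"""Five competing phenotypes, 25 generations, one common weather sequence.

Reproduces the layout of the published simulation table: each column is a
lineage with choice probability f, starting from 10 individuals, all facing
the same random weather each generation.  A second pass over 2000
replicates shows which outcomes are typical rather than lucky.
"""

from evogrowth import SimulationConfig, canonical_model, replicate_summary, simulate

POLICIES = (0.2, 0.5, 0.75, 0.9, 1.0)

cfg = SimulationConfig(canonical_model(), POLICIES, n0=10, generations=25,
                       seed=2012)
traj = simulate(cfg)
print("one realization (state 0 = sunny, 1 = rainy):")
print(traj.to_dataframe().to_string(index=False))
print()

summary = replicate_summary(cfg, 2000)
print("across 2000 replicates:")
for j, f in enumerate(POLICIES):
    print(f"  f = {f:4.2f}: extinct by gen 25 in "
          f"{100 * summary.extinction_frequency[j]:6.2f}% of runs, "
          f"modal terminal count {summary.modal_terminal_count[j]}, "
          f"largest population in {100 * summary.dominance_frequency[j]:5.1f}%")
print()
print("the always-valley type (f = 1) is almost always wiped out by a rainy")
print("generation, while the probability-matching type f* = .75 most often")
print("ends with the largest population.")
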