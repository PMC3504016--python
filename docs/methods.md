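# Methods

## Model

A population of semelparous, asexually reproducing individuals faces a
single binary decision per lifetime. Action *a* yields *x_a* offspring,
action *b* yields *x_b*, with (*x_a*, *x_b*) drawn from a finite-support
joint distribution Φ given as a list of atoms (probability, *x_a*, *x_b*).
A phenotype is the probability *f* ∈ [0, 1] of choosing *a*; the choice is
statistically independent of everything else (no strategic interaction),
and offspring inherit *f* exactly (no mutation). Fitness is the long-run
geometric growth rate of the lineage.

Two risk regimes:

* **Systematic** — one common draw per generation. With population
  *n_{t+1} = n_t · (f x_a + (1−f) x_b)* in distribution (the within-type
  law of large numbers acting on the choice only), the log growth rate
  converges to α(f) = E[log ω(f)], ω(f) = f·x_a + (1−f)·x_b. α is concave
  where finite; log 0 = −∞ is an ordinary value meaning almost-sure
  eventual extinction.
* **Idiosyncratic** — independent draws per individual. The law of large
  numbers acts within each generation, giving μ(f) = log(f·μ_a + (1−f)·μ_b)
  with μ_a = E[x_a], μ_b = E[x_b]; the optimum is always deterministic.

### Solvers

Systematic optimum: *f\** = 1 iff E[x_b/x_a] ≤ 1; *f\** = 0 iff
E[x_a/x_b] ≤ 1 (expected ratios with the convention x/0 = +∞ for x > 0;
the Cauchy–Schwarz inequality E[x_a/x_b]·E[x_b/x_a] ≥ 1 makes the two
conditions mutually exclusive except in the degenerate equality case).
Otherwise the optimum is the unique root of h(f) = E[(x_a − x_b)/ω(f)],
which is continuous and strictly decreasing where finite; it is found by
bisection (200 iterations, |h| < 1e-12). At the root,
E[x_a/ω(f\*)] = E[x_b/ω(f\*)] = 1 via the exact identity
f·E[x_a/ω] + (1−f)·E[x_b/ω] = 1.

Two-state scenarios — state 1 with probability *p* and payoffs (c_a, c_b),
state 2 with (d_a, d_b), constrained so that *a* is strictly favored in
state 1 and *b* in state 2 and neither state kills both actions — admit the
closed interior form

    f* = [p (c_a − c_b) d_b − (1−p)(d_b − d_a) c_b] / [(c_a − c_b)(d_b − d_a)],

obtained by clearing denominators in h(f) = 0 (h is a ratio of polynomials
linear in f for two atoms). Writing r1 = c_a/c_b > 1 and r2 = d_a/d_b < 1,
the optimum depends on the scenario only through (p, r1, r2); setting
f\* = p yields the exact probability-matching locus

    p (r1 − 1) = (1 − p) (1/r2 − 1).

The all-or-nothing family (c, 0)/(0, d) satisfies it in the limit
r1 → ∞, r2 → 0, and has f\* = p identically. Region classification uses
only the boundary ratio tests (E[x_a/x_b] = p·r1 + (1−p)·r2,
E[x_b/x_a] = p/r1 + (1−p)/r2), so r2 = 0 is handled by the infinity
conventions; cells whose deciding ratio is within 1e-10 of 1 carry a
boundary flag.

## Intelligence

Intelligence is a correlation ρ between the Bernoulli(f) choice indicator I
and Δ = x_a − x_b, fixed over generations. Under idiosyncratic risk the
per-individual mean offspring becomes

    E[I x_a + (1 − I) x_b] = f μ_a + (1−f) μ_b + ρ √(f(1−f)) σ_Δ,

using Cov(I, Δ) = ρ σ_I σ_Δ with σ_I = √(f(1−f)); growth is the log of
this mean. It reduces exactly to the mindless rate at ρ = 0 or f ∈ {0, 1},
and is non-decreasing in ρ whenever σ_Δ > 0 — negatively correlated
(counter-productive) types are evaluable but never optimal.

**Attainability.** For fixed marginals, Cov(I, Δ) is maximized by the
comonotone coupling: I = 1 exactly on the upper-f probability mass of Δ,
splitting the boundary atom proportionally. This gives the sharp bound

    rho_max(f) = (E_top_f(Δ) − f E[Δ]) / (√(f(1−f)) σ_Δ) ∈ (0, 1],

where E_top_f(Δ) is the partial expectation of Δ over its upper-f mass — a
piecewise-linear concave function of f with a kink at π = Pr(Δ > 0),
evaluated by interpolation over the cumulative atom masses. The same
construction, mixed with an independent Bernoulli(f) at weight
λ = ρ/ρ_max(f), realizes any requested ρ ≤ ρ_max(f) in simulation while
preserving the Bernoulli(f) marginal. The bound is cross-checked in the
test suite against a linear-program oracle over all couplings.

**Free intelligence.** Along ρ = ρ_max(f) the inner mean collapses to
μ_b + E_top_f(Δ), maximized exactly at the kink f = π with value
E[max(x_a, x_b)]. Hence the zero-cost optimum is probability matching of
the odds that *a* is the better action, with growth log E[max(x_a, x_b)]
— the perfect-intelligence benchmark.

**Cost of intelligence.** A cost c(ρ) with c(0) = 0, non-decreasing on
[0, 1], is deducted from the correlation itself: ρ is replaced by ρ − c(ρ)
in the growth formula. The optimizer maximizes over f ∈ [0, 1] and
ρ ∈ [0, ρ_max(f)] by a dense f-grid (401 points) with bounded local
refinement; the inner ρ-problem (maximize ρ − c(ρ) up to the cap) is
closed-form for the built-in families and grid+refine for custom ones. The
exact matching point f = π is always tried as a candidate and wins ties at
machine precision, since the objective is kinked there. A
boundary/interior growth tie within 1e-10 (absolute, on the log scale) is
labeled `tie_line`; grid resolution dominates finer distinctions.

**Why the default cost family is linear.** With c(ρ) = κρ the constrained
objective along ρ = ρ_max(f) is μ_b + κ f E[Δ] + (1−κ) E_top_f(Δ), still
piecewise linear with its kink at π, so the solution has exactly three
regimes as κ rises: probability matching at full feasible correlation
(small κ), a critical κ\* at which the matching point and the
deterministic boundary tie — and a whole continuum of (f, ρ) pairs along
the constraint is optimal — and the mindless deterministic optimum beyond
(for κ ≥ 1 the net correlation is never positive). For the all-or-nothing
two-state family with state probability p, κ\*(p) = 1/(2p) exactly, which
the cost-region map test verifies by independent bisection. A quadratic
family c(ρ) = κρ² is provided as an alternative, but its marginal cost
vanishes at ρ = 0, so a vanishing amount of correlation always pays: the
optimum then leaves the matching point smoothly instead of jumping to the
boundary, a fourth regime labeled `interior`. Because the quadratic family
cannot produce the clean three-regime structure, the linear family is the
default and is used in all regime-structure analyses.

The critical cost `tie_kappa` is located by bisecting the gap between the
best intelligent (interior) growth and the best mindless boundary growth;
the interior growth is non-increasing and the boundary growth constant in
κ, so the crossing is unique when it exists.

## Simulation

Counts are exact Python integers (arbitrary precision): the canonical
experiment exceeds 1.7 × 10⁸ and intelligent lineages in tests exceed
10²¹. Systematic mode draws one atom per generation from a dedicated
environment RNG stream; each policy column then draws
k ~ Binomial(n, f) choosers of *a* and advances to k·x_a + (n−k)·x_b.
Idiosyncratic mode partitions the column over atoms by a multinomial draw
and applies per-atom binomials. Binomial/multinomial draws on counts
beyond 2⁶² are split into int64-sized chunks (sums of binomials with equal
p are binomial). Intelligence policies condition the choice probability on
the realized atom through the comonotone mixture, so simulated lineages
realize the analytic correlation.

RNG discipline: `SeedSequence(seed)` spawns one child per stream
(environment first, then one per policy), which makes trajectories
bit-reproducible and policy columns independent — removing a column never
changes another column's draws. Replicates derive per-replicate seeds by a
second level of spawning (masked to 31 bits).

Expectation mode propagates log expected counts given the realized state
sequence (numerically stable over thousands of generations); its
per-generation log multipliers are i.i.d. samples of log ω(f), so the time
average estimates α(f) with standard error σ/√T. A lineage extinct before
the final generation yields a truncated, flagged growth estimate.

## Scenario generation

The canonical scenario is fixed by the study conditions: sunshine
probability .75, payoffs 3/0 flipped between states, initial population 10
per phenotype, policies {.20, .50, .75, .90, 1}, 25 generations, 2000
replicates for cross-replicate statistics. The random-fixture generator
draws support sizes 2–6, integer offspring 0–10 (redrawing double-zero
atoms), and Dirichlet(1) state probabilities floored away from zero;
rejection sampling enforces a quota of interior-randomizing models. These
fixtures probe the solvers across boundary and interior regimes; they do
not emulate any empirical fecundity data, so passing tests certify the
mathematics and the simulator, not the realism of any particular Φ.

## Numerical choices and limitations

* Probability sums within 1e-9 of 1 are rescaled (warning); worse sums,
  negative offspring, empty supports and double-zero atoms are hard
  failures.
* Extended-real conventions: log 0 = −∞, x/0 = +∞ (x > 0); −∞ growth
  compares normally.
* Interior-root tolerance |h| < 1e-12; closed-form/numeric agreement
  asserted at 1e-9; boundary flags at 1e-10; tie detection at 1e-10.
* Degenerate models (x_a ≡ x_b, or exactly tied means/boundary ratios) are
  reported as randomizing at f = 0.5 with a degeneracy flag rather than an
  arbitrary silent pick.
* Only finite-support distributions and two actions are supported;
  overlapping generations, mutation, strategic interaction, density
  dependence and time-varying environments are out of scope.
* Problem sizes used in the shipped analyses — 2000 replicates × 25
  generations for the stochastic experiment, 2000 generations for
  expectation-mode growth estimation, 200 random models for solver/oracle
  comparisons, 401-point optimizer grids — were chosen so that every
  statistical check operates at ≥3-standard-error resolution while the
  whole suite runs in seconds.
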