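"""Scenario types and growth-rate functionals for the binary-choice model.

A population of semelparous, asexual individuals faces a single lifetime
decision between two actions, ``a`` and ``b``.  Choosing action ``a`` yields
``x_a`` offspring and choosing ``b`` yields ``x_b``, where ``(x_a, x_b)`` is
drawn from a finite-support joint distribution (a :class:`FecundityModel`).
An individual's behavioral phenotype is the probability ``f`` with which it
chooses action ``a``, independently of everything else in its environment.

The module evaluates the long-run geometric (log) growth rate of a lineage
of ``f``-types exactly, by finite sums, under two risk regimes:

* **systematic** risk — one common environmental draw per generation shared
  by every individual (a single ecological niche):
  ``alpha(f) = E[log(f*x_a + (1-f)*x_b)]``;
* **idiosyncratic** risk — an independent draw per individual, so the law of
  large numbers acts within each generation:
  ``mu(f) = log(f*mu_a + (1-f)*mu_b)``.

It also evaluates the growth rate of "intelligent" phenotypes whose choice
indicator is positively correlated with the fecundity difference
``Delta = x_a - x_b`` (correlation ``rho``), with an optional reproductive
cost of that correlation.

Extended-real conventions are used throughout: ``log 0 = -inf`` and
``x/0 = +inf`` for ``x > 0``; a growth rate of ``-inf`` is an ordinary,
comparable value signalling almost-sure eventual extinction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Action",
    "OutcomeAtom",
    "Regime",
    "FecundityModel",
    "Policy",
    "IntelligencePolicy",
    "CostModel",
    "TwoStateScenario",
    "MomentSet",
    "ValidationReport",
    "validate_model",
    "moments",
    "log_growth_systematic",
    "log_growth_idiosyncratic",
    "log_growth_intelligence",
    "log_growth_net_cost",
]

#: probability sums further than this from 1 are a hard validation failure
PROB_SUM_TOL = 1e-9


class Action(enum.Enum):
    """The two available actions."""

    A = "a"
    B = "b"


class Regime(enum.Enum):
    """How reproductive risk is shared across a generation.

    ``SYSTEMATIC``: one draw of ``(x_a, x_b)`` per generation for everyone.
    ``IDIOSYNCRATIC``: an independent draw per individual.
    """

    SYSTEMATIC = "systematic"
    IDIOSYNCRATIC = "idiosyncratic"

    @classmethod
    def coerce(cls, value: "Regime | str") -> "Regime":
        if isinstance(value, Regime):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class OutcomeAtom:
    """One state of the world: probability and the offspring pair it yields."""

    prob: float
    x_a: float
    x_b: float

    def violations(self) -> list[str]:
        out = []
        if not (0.0 < self.prob <= 1.0):
            out.append(f"atom probability {self.prob!r} not in (0, 1]")
        if self.x_a < 0 or self.x_b < 0:
            out.append(f"negative offspring count in atom ({self.x_a}, {self.x_b})")
        if self.x_a == 0 and self.x_b == 0:
            out.append(
                "atom with x_a = x_b = 0: both actions lead to extinction in "
                "this state, which makes the choice problem degenerate"
            )
        for v in (self.prob, self.x_a, self.x_b):
            if not math.isfinite(v):
                out.append(f"non-finite atom field {v!r}")
                break
        return out


@dataclass(frozen=True)
class MomentSet:
    """Exact finite-sum moments of a fecundity model.

    ``pi`` is ``Pr(x_a > x_b)``, the probability that action ``a`` is the
    better choice ex post — the probability-matching target.
    """

    mu_a: float
    mu_b: float
    mean_delta: float
    sigma_delta: float
    pi: float


@dataclass(frozen=True)
class FecundityModel:
    """Finite-support joint distribution of offspring pairs, plus risk regime."""

    atoms: tuple[OutcomeAtom, ...]
    regime: Regime = Regime.SYSTEMATIC

    def __init__(
        self,
        atoms: Sequence[OutcomeAtom | tuple[float, float, float]],
        regime: Regime | str = Regime.SYSTEMATIC,
    ):
        packed = tuple(
            a if isinstance(a, OutcomeAtom) else OutcomeAtom(*a) for a in atoms
        )
        object.__setattr__(self, "atoms", packed)
        object.__setattr__(self, "regime", Regime.coerce(regime))

    # -- array views (cached; atoms are immutable) --------------------------
    @cached_property
    def probs(self) -> np.ndarray:
        p = np.array([a.prob for a in self.atoms], dtype=float)
        s = p.sum()
        # renormalize float dust so finite sums are exact expectations
        if p.size and abs(s - 1.0) <= PROB_SUM_TOL * (1.0 + 1e-3):
            p = p / s
        return p

    @cached_property
    def xa(self) -> np.ndarray:
        return np.array([a.x_a for a in self.atoms], dtype=float)

    @cached_property
    def xb(self) -> np.ndarray:
        return np.array([a.x_b for a in self.atoms], dtype=float)

    @cached_property
    def delta(self) -> np.ndarray:
        return self.xa - self.xb

    def with_regime(self, regime: Regime | str) -> "FecundityModel":
        return FecundityModel(self.atoms, regime)

    def has_integer_offspring(self) -> bool:
        return all(
            float(a.x_a).is_integer() and float(a.x_b).is_integer()
            for a in self.atoms
        )


@dataclass(frozen=True)
class Policy:
    """Mindless behavioral phenotype: choose action ``a`` with probability f."""

    f: float

    def __post_init__(self):
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"choice probability f={self.f} outside [0, 1]")


@dataclass(frozen=True)
class IntelligencePolicy:
    """Phenotype whose choice indicator has correlation ``rho`` with Delta.

    ``rho`` is the correlation between the Bernoulli(f) choice indicator and
    the fecundity difference ``Delta = x_a - x_b``; it is fixed over
    generations.  Evaluation permits ``rho`` in [-1, 1] (negatively
    correlated, counter-productive types are evaluable, they simply cannot
    survive); optimization restricts to [0, rho_max(f)].
    """

    f: float
    rho: float

    def __post_init__(self):
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"choice probability f={self.f} outside [0, 1]")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError(f"correlation rho={self.rho} outside [-1, 1]")


class CostFamily(enum.Enum):
    LINEAR = "linear"
    QUADRATIC = "quadratic"
    CUSTOM = "custom"


@dataclass(frozen=True)
class CostModel:
    """Reproductive cost of intelligence, ``c(rho)``, parametrized by kappa.

    The cost is deducted from the correlation itself: an intelligent type
    with trait ``rho`` grows as if its correlation were ``rho - c(rho)``.
    Requirements: ``c(0) = 0`` and ``c`` non-decreasing on [0, 1].

    The default family is linear, ``c(rho) = kappa * rho``.  Under a linear
    cost the growth-optimal solution has exactly three regimes as kappa
    rises (probability matching, a tie with a continuum of optima, then a
    deterministic boundary); see ``docs/methods.md``.  A quadratic family
    ``kappa * rho**2`` and arbitrary custom families are also available.
    """

    family: CostFamily = CostFamily.LINEAR
    kappa: float = 0.0
    _eval: Callable[[float], float] | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError(f"kappa={self.kappa} must be non-negative")
        if self.family is CostFamily.CUSTOM and self._eval is None:
            raise ValueError("custom cost family requires an eval callable")

    @classmethod
    def linear(cls, kappa: float) -> "CostModel":
        return cls(CostFamily.LINEAR, kappa)

    @classmethod
    def quadratic(cls, kappa: float) -> "CostModel":
        return cls(CostFamily.QUADRATIC, kappa)

    @classmethod
    def custom(cls, fn: Callable[[float], float], kappa: float = 0.0) -> "CostModel":
        return cls(CostFamily.CUSTOM, kappa, fn)

    @classmethod
    def zero(cls) -> "CostModel":
        return cls(CostFamily.LINEAR, 0.0)

    def eval(self, rho: float) -> float:
        if self.family is CostFamily.LINEAR:
            return self.kappa * rho
        if self.family is CostFamily.QUADRATIC:
            return self.kappa * rho * rho
        return float(self._eval(rho))  # type: ignore[misc]

    def net(self, rho: float) -> float:
        """Net correlation rho - c(rho)."""
        return rho - self.eval(rho)

    def violations(self) -> list[str]:
        out = []
        if abs(self.eval(0.0)) > 1e-12:
            out.append("cost model must satisfy c(0) = 0")
        grid = np.linspace(0.0, 1.0, 101)
        vals = [self.eval(r) for r in grid]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            out.append("cost model must be non-decreasing on [0, 1]")
        return out


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_model`."""

    ok: bool
    violations: tuple[str, ...]
    model: FecundityModel | None
    warnings: tuple[str, ...] = ()

    def raise_on_error(self) -> FecundityModel:
        if not self.ok:
            raise ValueError("invalid fecundity model: " + "; ".join(self.violations))
        assert self.model is not None
        return self.model


def validate_model(model: FecundityModel) -> ValidationReport:
    """Check model invariants; rescale near-unit probability sums.

    Probability sums within ``1e-9`` of 1 are rescaled (with a warning);
    anything farther off is a hard failure, as are empty atom lists,
    negative offspring counts and within-state double-zero atoms (states in
    which both actions lead to extinction).
    """
    violations: list[str] = []
    warnings: list[str] = []
    if not model.atoms:
        return ValidationReport(False, ("empty atom list",), None)
    for i, atom in enumerate(model.atoms):
        violations.extend(f"atoms[{i}]: {v}" for v in atom.violations())
    total = float(sum(a.prob for a in model.atoms))
    # the tiny relative slack keeps sums at exactly the tolerance (up to
    # float representation of the inputs) on the accepted side
    if abs(total - 1.0) > PROB_SUM_TOL * (1.0 + 1e-3):
        violations.append(
            f"atom probabilities sum to {total!r}, off by more than {PROB_SUM_TOL}"
        )
    elif total != 1.0:
        warnings.append(f"probabilities summed to {total!r}; rescaled to 1")
    if violations:
        return ValidationReport(False, tuple(violations), None, tuple(warnings))
    if not model.has_integer_offspring():
        warnings.append(
            "non-integer offspring counts: growth functionals are exact but "
            "sampled-mode simulation requires integers"
        )
    return ValidationReport(True, (), model, tuple(warnings))


def moments(model: FecundityModel) -> MomentSet:
    """Exact moments: means per action, mean/std of Delta, and Pr(x_a > x_b)."""
    validate_model(model).raise_on_error()
    q, xa, xb = model.probs, model.xa, model.xb
    d = xa - xb
    mu_a = float(q @ xa)
    mu_b = float(q @ xb)
    mean_d = float(q @ d)
    var_d = float(q @ (d - mean_d) ** 2)
    return MomentSet(
        mu_a=mu_a,
        mu_b=mu_b,
        mean_delta=mean_d,
        sigma_delta=math.sqrt(max(var_d, 0.0)),
        pi=float(q[d > 0].sum()),
    )


def _check_f(f: float) -> float:
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"choice probability f={f} outside [0, 1]")
    return float(f)


def log_growth_systematic(model: FecundityModel, f: float) -> float:
    """Log growth rate under systematic risk: ``E[log(f x_a + (1-f) x_b)]``.

    Returns ``-inf`` when any positive-probability state gives the lineage
    zero expected offspring (``f x_a + (1-f) x_b = 0``): under a common
    environmental draw that state eventually occurs and the lineage dies.
    """
    f = _check_f(f)
    validate_model(model).raise_on_error()
    omega = f * model.xa + (1.0 - f) * model.xb
    if np.any(omega <= 0.0):
        return float("-inf")
    return float(model.probs @ np.log(omega))


def log_growth_idiosyncratic(model: FecundityModel, f: float) -> float:
    """Log growth rate under idiosyncratic risk: ``log(f mu_a + (1-f) mu_b)``.

    Independent per-individual draws diversify the risk away within each
    generation, so only the mean fecundities matter.
    """
    f = _check_f(f)
    m = moments(model)
    mean = f * m.mu_a + (1.0 - f) * m.mu_b
    if mean <= 0.0:
        return float("-inf")
    return math.log(mean)


def log_growth_intelligence(model: FecundityModel, policy: IntelligencePolicy) -> float:
    """Log growth of a correlated type under idiosyncratic risk.

    The choice indicator I ~ Bernoulli(f) has correlation rho with
    Delta = x_a - x_b, so the per-individual mean offspring picks up a
    covariance term::

        E[I x_a + (1-I) x_b] = f mu_a + (1-f) mu_b
                               + rho * sqrt(f(1-f)) * sigma_Delta

    and the growth rate is the log of that mean.  Reduces exactly to
    :func:`log_growth_idiosyncratic` at rho = 0 or f in {0, 1}.
    """
    m = moments(model)
    f, rho = policy.f, policy.rho
    if math.isnan(rho):
        raise ValueError("rho is NaN")
    mean = (
        f * m.mu_a
        + (1.0 - f) * m.mu_b
        + rho * math.sqrt(f * (1.0 - f)) * m.sigma_delta
    )
    if mean <= 0.0:
        return float("-inf")
    return math.log(mean)


def log_growth_net_cost(
    model: FecundityModel, policy: IntelligencePolicy, cost: CostModel
) -> float:
    """Growth of a costly intelligent type: rho is replaced by rho - c(rho)."""
    bad = cost.violations()
    if bad:
        raise ValueError("invalid cost model: " + "; ".join(bad))
    net = IntelligencePolicy(policy.f, max(-1.0, min(1.0, cost.net(policy.rho))))
    return log_growth_intelligence(model, net)


@dataclass(frozen=True)
class TwoStateScenario:
    """Two environmental states with action ``a`` favored in state 1.

    State 1 occurs with probability ``p`` and yields offspring ``(c_a, c_b)``;
    state 2 yields ``(d_a, d_b)``.  The convention ``c_a > c_b`` and
    ``d_b > d_a`` (action ``a`` strictly better in state 1, ``b`` in state 2)
    plus ``c_a > 0`` and ``d_b > 0`` rules out states in which both actions
    lead to extinction.  Relative fecundities are ``r1 = c_a / c_b`` in (1,
    +inf] and ``r2 = d_a / d_b`` in [0, 1), with ``x / 0 = +inf`` for x > 0.
    """

    p: float
    c_a: float
    c_b: float
    d_a: float
    d_b: float

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"state-1 probability p={self.p} outside (0, 1)")
        for name in ("c_a", "c_b", "d_a", "d_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"offspring count {name} is negative")
        if not (self.c_a > self.c_b):
            raise ValueError("need c_a > c_b: action a must be favored in state 1")
        if not (self.d_b > self.d_a):
            raise ValueError("need d_b > d_a: action b must be favored in state 2")
        if self.c_a == 0 or self.d_b == 0:
            raise ValueError("need c_a > 0 and d_b > 0")

    @property
    def r1(self) -> float:
        return self.c_a / self.c_b if self.c_b > 0 else float("inf")

    @property
    def r2(self) -> float:
        return self.d_a / self.d_b

    def to_model(self, regime: Regime | str = Regime.SYSTEMATIC) -> FecundityModel:
        return FecundityModel(
            [
                OutcomeAtom(self.p, self.c_a, self.c_b),
                OutcomeAtom(1.0 - self.p, self.d_a, self.d_b),
            ],
            regime,
        )


#: The sunshine/rain nesting scenario: with probability 0.75 the day is sunny
#: and nesting in the valley (action a) yields 3 offspring while the plateau
#: (action b) yields 0; with probability 0.25 it rains, the valley floods,
#: and the payoffs flip.  Probability matching f* = 0.75 is growth-optimal.
CANONICAL = TwoStateScenario(p=0.75, c_a=3, c_b=0, d_a=0, d_b=3)


def canonical_model(regime: Regime | str = Regime.SYSTEMATIC) -> FecundityModel:
    """The sunshine/rain model as a :class:`FecundityModel`."""
    return CANONICAL.to_model(regime)
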