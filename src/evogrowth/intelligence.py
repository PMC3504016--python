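"""Intelligence as correlation with reproductive success, and its cost.

"Intelligence" here is any positive correlation ``rho`` between an
individual's choice indicator ``I ~ Bernoulli(f)`` and the fecundity
difference ``Delta = x_a - x_b``.  Under idiosyncratic risk the growth rate
of such a type is ``log(f mu_a + (1-f) mu_b + rho sqrt(f(1-f)) sigma_Delta)``.

Not every (f, rho) pair is attainable: for fixed marginals the covariance of
a Bernoulli indicator with Delta is maximized by the comonotone coupling —
the indicator equals 1 exactly on the upper-f probability mass of Delta
(with proportional splitting of the boundary atom).  This yields the sharp
bound ``rho_max(f)`` and a concrete sampling construction that attains any
requested rho below it.

Free intelligence is unbounded in value: perfect correlation steers every
individual to the ex-post better action, giving growth ``log E[max(x_a,
x_b)]`` at the probability-matching behavior ``f = Pr(x_a > x_b)``.  When
correlation carries a reproductive cost ``c(rho)`` — deducted from the
correlation itself — the growth-optimal solution is bounded.  Under the
default linear cost family it has exactly three regimes as the cost
parameter kappa rises: probability matching with maximal feasible
correlation; a tie at a critical kappa where a continuum of (f, rho) pairs
is optimal; and a deterministic boundary (zero intelligence) beyond it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .optimize import solve_idiosyncratic
from .scenarios import (
    CANONICAL,
    CostFamily,
    CostModel,
    FecundityModel,
    TwoStateScenario,
    moments,
    validate_model,
)

__all__ = [
    "IntelligenceLabel",
    "IntelligenceSolveResult",
    "rho_max",
    "top_partial_expectation",
    "comonotone_choice_probabilities",
    "perfect_intelligence_benchmark",
    "solve_bounded",
    "tie_kappa",
    "CostRegionMap",
    "cost_region_map",
]

TIE_TOL = 1e-10       # absolute growth gap below which two optima tie
MATCH_TOL = 1e-8      # |f* - Pr(x_a > x_b)| for the matching label
_GRID = 401           # dense search grid per axis


class IntelligenceLabel(enum.Enum):
    DETERMINISTIC_BOUNDARY = "deterministic_boundary"
    PROBABILITY_MATCHING = "probability_matching"
    TIE_LINE = "tie_line"
    #: interior optimum away from the matching point; arises only for cost
    #: families (e.g. quadratic) whose marginal cost vanishes at rho = 0
    INTERIOR = "interior"


@dataclass(frozen=True)
class IntelligenceSolveResult:
    """Growth-optimal (f, rho) under a cost of intelligence.

    ``benchmark_gap`` is ``log E[max(x_a, x_b)] - growth_at_opt``, the
    shortfall from the perfect-intelligence benchmark (>= 0).  At a
    boundary optimum f in {0, 1} the correlation is unidentified and is
    canonicalized to ``rho_star = 0``.
    """

    f_star: float
    rho_star: float
    growth_at_opt: float
    regime_label: IntelligenceLabel
    benchmark_gap: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "f_star": self.f_star,
            "rho_star": self.rho_star,
            "growth_at_opt": self.growth_at_opt,
            "regime_label": self.regime_label.value,
            "benchmark_gap": self.benchmark_gap,
            "degenerate": self.degenerate,
        }


class _DeltaProfile:
    """Sorted view of the Delta distribution for partial-expectation queries.

    ``E_top(f)`` — the expectation of Delta restricted to its upper-f
    probability mass, splitting the boundary atom proportionally — is
    piecewise linear in f with knots at the cumulative atom masses, so it is
    evaluated by interpolation.
    """

    def __init__(self, model: FecundityModel):
        m = moments(model)
        self.mean_delta = m.mean_delta
        self.sigma = m.sigma_delta
        self.pi = m.pi
        order = np.argsort(-model.delta, kind="stable")
        self.q = model.probs[order]
        self.delta = model.delta[order]
        self.cum_mass = np.concatenate([[0.0], np.cumsum(self.q)])
        self.cum_mass[-1] = 1.0
        self.cum_sum = np.concatenate([[0.0], np.cumsum(self.q * self.delta)])

    def e_top(self, f):
        return np.interp(f, self.cum_mass, self.cum_sum)

    def max_cov(self, f):
        """Largest attainable Cov(I, Delta) for I ~ Bernoulli(f)."""
        return self.e_top(f) - f * self.mean_delta

    def rho_max(self, f):
        s = np.sqrt(f * (1.0 - f))
        return self.max_cov(f) / (s * self.sigma)


def _profile(model: FecundityModel) -> _DeltaProfile:
    validate_model(model).raise_on_error()
    return _DeltaProfile(model)


def top_partial_expectation(model: FecundityModel, f: float) -> float:
    """E[Delta; upper-f mass]: the comonotone partial expectation of Delta."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"f={f} outside [0, 1]")
    return float(_profile(model).e_top(f))


def rho_max(model: FecundityModel, f: float) -> float:
    """Sharp upper bound on the correlation of a Bernoulli(f) choice with Delta.

    ``rho_max(f) = (E_top_f(Delta) - f E[Delta]) / (sqrt(f(1-f)) sigma_Delta)``,
    attained by the comonotone coupling.  Defined for 0 < f < 1 and
    sigma_Delta > 0; always in (0, 1].
    """
    if not (0.0 < f < 1.0):
        raise ValueError(f"rho_max requires 0 < f < 1, got f={f}")
    prof = _profile(model)
    if prof.sigma == 0.0:
        raise ValueError("rho_max undefined: Delta is degenerate (sigma = 0)")
    return float(min(prof.rho_max(f), 1.0))


def comonotone_choice_probabilities(
    model: FecundityModel, f: float, rho: float
) -> np.ndarray:
    """Per-atom probability of choosing action a that realizes (f, rho).

    Mixture construction: with weight ``lam = rho / rho_max(f)`` the choice
    indicator is the comonotone indicator of the upper-f mass of Delta
    (split proportionally at the boundary atom), and with weight ``1 - lam``
    it is an independent Bernoulli(f).  The marginal stays Bernoulli(f) and
    the correlation is exactly ``lam * rho_max(f) = rho``.  Returns one
    conditional probability per atom, in the model's atom order.
    """
    k = len(model.atoms)
    if f in (0.0, 1.0) or rho == 0.0:
        return np.full(k, float(f))
    cap = rho_max(model, f)
    if not (0.0 <= rho <= cap + 1e-12):
        raise ValueError(f"rho={rho} not attainable at f={f} (rho_max={cap})")
    lam = min(rho / cap, 1.0)
    order = np.argsort(-model.delta, kind="stable")
    q_sorted = model.probs[order]
    upper = np.zeros(k)
    mass = 0.0
    for pos in range(k):
        if mass + q_sorted[pos] <= f:
            upper[pos] = 1.0
            mass += q_sorted[pos]
        else:
            upper[pos] = (f - mass) / q_sorted[pos]
            break
    q_comono = np.empty(k)
    q_comono[order] = upper
    return lam * q_comono + (1.0 - lam) * f


def perfect_intelligence_benchmark(model: FecundityModel) -> dict:
    """Growth-optimal behavior under free, perfect intelligence.

    Every individual takes the ex-post better action, so growth is
    ``log E[max(x_a, x_b)]`` and the realized choice frequency is
    ``f = Pr(x_a > x_b)`` — probability matching of a different kind,
    emerging even under idiosyncratic risk.
    """
    validate_model(model).raise_on_error()
    m = moments(model)
    e_max = float(model.probs @ np.maximum(model.xa, model.xb))
    return {"f": m.pi, "growth": math.log(e_max)}


def _best_net(cost: CostModel, cap: float) -> tuple[float, float]:
    """Maximize the net correlation rho - c(rho) over [0, cap].

    Returns (argmax rho, max net value); the net value is always >= 0
    because rho = 0 is feasible.
    """
    if cap <= 0.0:
        return 0.0, 0.0
    if cost.family is CostFamily.LINEAR:
        if cost.kappa < 1.0:
            return cap, cap * (1.0 - cost.kappa)
        return 0.0, 0.0
    if cost.family is CostFamily.QUADRATIC:
        rho = cap if cost.kappa == 0.0 else min(cap, 0.5 / cost.kappa)
        return rho, cost.net(rho)
    grid = np.linspace(0.0, cap, _GRID)
    vals = np.array([cost.net(r) for r in grid])
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, _GRID - 1)]
    res = minimize_scalar(
        lambda r: -cost.net(r), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    best_r, best_v = float(res.x), float(-res.fun)
    if best_v < 0.0 or vals[i] > best_v:
        best_r, best_v = float(grid[i]), float(vals[i])
    return (best_r, best_v) if best_v > 0.0 else (0.0, 0.0)


def _interior_objective(prof: _DeltaProfile, mu_a: float, mu_b: float,
                        cost: CostModel):
    """Inner expected-offspring mean G(f) on (0,1), maximized over rho."""

    def G(f: float) -> float:
        s = math.sqrt(f * (1.0 - f))
        cap = min(prof.rho_max(f), 1.0)
        _, net = _best_net(cost, cap)
        return f * mu_a + (1.0 - f) * mu_b + net * s * prof.sigma

    return G


def _best_interior(
    model: FecundityModel, cost: CostModel
) -> tuple[float, float, float]:
    """Maximize growth over f in (0, 1), rho in [0, rho_max(f)].

    Dense grid plus bounded local refinement; the exact matching point
    f = Pr(x_a > x_b) is always tried as a candidate and wins any tie
    within machine precision (the zero-cost objective is kinked there).
    Returns (f, rho, growth).
    """
    prof = _profile(model)
    m = moments(model)
    G = _interior_objective(prof, m.mu_a, m.mu_b, cost)
    fs = np.linspace(0.0, 1.0, _GRID + 2)[1:-1]
    vals = np.array([G(f) for f in fs])
    i = int(np.argmax(vals))
    lo = fs[i - 1] if i > 0 else fs[0] / 2.0
    hi = fs[i + 1] if i < fs.size - 1 else (1.0 + fs[-1]) / 2.0
    res = minimize_scalar(
        lambda f: -G(f), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    f_best, g_best = float(res.x), float(-res.fun)
    if vals[i] > g_best:
        f_best, g_best = float(fs[i]), float(vals[i])
    if 0.0 < prof.pi < 1.0 and G(prof.pi) >= g_best - 1e-12:
        f_best, g_best = prof.pi, G(prof.pi)
    rho_best, _ = _best_net(cost, min(prof.rho_max(f_best), 1.0))
    growth = math.log(g_best) if g_best > 0.0 else float("-inf")
    return f_best, float(rho_best), growth


def solve_bounded(
    model: FecundityModel, cost: CostModel | None = None
) -> IntelligenceSolveResult:
    """Growth-optimal behavior and intelligence under a cost of correlation.

    Maximizes ``log(f mu_a + (1-f) mu_b + (rho - c(rho)) sqrt(f(1-f))
    sigma_Delta)`` over f in [0, 1] and attainable rho in [0, rho_max(f)].
    With zero cost this returns the perfect-intelligence benchmark; with a
    prohibitively expensive cost it returns the mindless deterministic
    optimum.  A boundary/interior tie within 1e-10 in growth is labeled
    ``tie_line`` (a continuum of optima).
    """
    cost = cost if cost is not None else CostModel.zero()
    bad = cost.violations()
    if bad:
        raise ValueError("invalid cost model: " + "; ".join(bad))
    m = moments(model)
    bench = perfect_intelligence_benchmark(model)
    if m.sigma_delta == 0.0:
        base = solve_idiosyncratic(model)
        return IntelligenceSolveResult(
            base.f_star, 0.0, base.growth_at_opt,
            IntelligenceLabel.DETERMINISTIC_BOUNDARY,
            bench["growth"] - base.growth_at_opt,
            degenerate=base.degenerate,
        )
    base = solve_idiosyncratic(model)
    boundary_growth = base.growth_at_opt
    f_int, rho_int, growth_int = _best_interior(model, cost)
    if growth_int - boundary_growth > TIE_TOL:
        label = (
            IntelligenceLabel.PROBABILITY_MATCHING
            if abs(f_int - m.pi) <= MATCH_TOL
            else IntelligenceLabel.INTERIOR
        )
        return IntelligenceSolveResult(
            f_int, rho_int, growth_int, label, bench["growth"] - growth_int
        )
    if boundary_growth - growth_int > TIE_TOL:
        return IntelligenceSolveResult(
            base.f_star, 0.0, boundary_growth,
            IntelligenceLabel.DETERMINISTIC_BOUNDARY,
            bench["growth"] - boundary_growth,
            degenerate=base.degenerate,
        )
    growth = max(growth_int, boundary_growth)
    return IntelligenceSolveResult(
        f_int, rho_int, growth, IntelligenceLabel.TIE_LINE,
        bench["growth"] - growth,
    )


def tie_kappa(
    model: FecundityModel,
    family: str | CostFamily = CostFamily.LINEAR,
    kappa_hi: float = 10.0,
    tol: float = 1e-12,
) -> float | None:
    """Critical cost parameter at which intelligence stops paying.

    Bisects kappa for the crossing of the best interior (intelligent)
    growth and the best mindless boundary growth.  Returns None if the two
    never cross on [0, kappa_hi].
    """
    family = CostFamily(family) if not isinstance(family, CostFamily) else family

    def make(k: float) -> CostModel:
        return CostModel(family, k)

    boundary = solve_idiosyncratic(model).growth_at_opt

    def gap(k: float) -> float:
        return _best_interior(model, make(k))[2] - boundary

    lo, hi = 0.0, kappa_hi
    if gap(lo) <= 0.0 or gap(hi) >= 0.0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class CostRegionMap:
    """Regime labels over a (kappa, p) grid for a two-state scenario family."""

    kappa_values: np.ndarray
    p_values: np.ndarray
    labels: np.ndarray            # (len(kappa), len(p)) label strings
    tie_curve: np.ndarray         # rows (p, kappa*) where the regimes tie

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (float(k), float(p), self.labels[i, j])
            for i, k in enumerate(self.kappa_values)
            for j, p in enumerate(self.p_values)
        ]
        return pd.DataFrame(rows, columns=["kappa", "p", "label"])


def cost_region_map(
    kappa_values: "np.ndarray | list[float]",
    p_values: "np.ndarray | list[float]",
    family: str | CostFamily = CostFamily.LINEAR,
    base: TwoStateScenario = CANONICAL,
) -> CostRegionMap:
    """Map optimal-regime labels over cost parameter kappa and probability p.

    For each p the base two-state scenario's state probability is replaced
    by p (regime idiosyncratic) and :func:`solve_bounded` is run per kappa.
    Costly intelligence (large kappa) yields deterministic behavior; cheap
    intelligence yields probability matching; the curve ``kappa*(p)`` where
    they tie is located by bisection and returned separately.
    """
    family = CostFamily(family) if not isinstance(family, CostFamily) else family
    kappa_values = np.asarray(kappa_values, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    labels = np.empty((kappa_values.size, p_values.size), dtype=object)
    ties = []
    for j, p in enumerate(p_values):
        scenario = TwoStateScenario(
            p=float(p), c_a=base.c_a, c_b=base.c_b, d_a=base.d_a, d_b=base.d_b
        )
        model = scenario.to_model("idiosyncratic")
        for i, k in enumerate(kappa_values):
            res = solve_bounded(model, CostModel(family, float(k)))
            labels[i, j] = res.regime_label.value
        k_star = tie_kappa(model, family, kappa_hi=float(kappa_values.max()) + 1.0)
        if k_star is not None:
            ties.append((float(p), k_star))
    return CostRegionMap(kappa_values, p_values, labels, np.array(ties))
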