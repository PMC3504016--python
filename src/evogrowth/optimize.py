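"""Growth-optimal behavior: boundary classification, interior solutions,
two-state closed forms, the probability-matching locus, and region maps.

Under systematic risk the log growth rate ``alpha(f)`` is concave on the set
where it is finite, so the optimum has three parts:

* ``f* = 1`` (always a) when ``E[x_b / x_a] <= 1``;
* ``f* = 0`` (always b) when ``E[x_a / x_b] <= 1``;
* otherwise an interior, randomizing optimum — the unique root of
  ``h(f) = E[(x_a - x_b) / omega(f)]`` with ``omega(f) = f x_a + (1-f) x_b``,
  i.e. the ``f`` at which the expected ratio of each action's offspring to
  the mixed average equals one for both actions.

Under idiosyncratic risk the optimum is always deterministic: whichever
action has the larger mean fecundity.

For two-state scenarios the interior optimum has a closed form, and exact
probability matching ``f* = p`` occurs on the locus
``p (r1 - 1) = (1 - p) (1/r2 - 1)`` in the plane of relative fecundities
``(r1, r2)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenarios import (
    Action,
    FecundityModel,
    TwoStateScenario,
    log_growth_idiosyncratic,
    log_growth_systematic,
    moments,
    validate_model,
)

__all__ = [
    "RegimeLabel",
    "SolveResult",
    "RegionCell",
    "RegionMap",
    "expected_ratio",
    "solve_systematic",
    "solve_idiosyncratic",
    "two_state_solve",
    "probability_matching_condition",
    "MatchingCondition",
    "region_classify",
    "region_map",
]

INTERIOR_TOL = 1e-12       # |h(f)| at the accepted interior root
BOUNDARY_FLAG_TOL = 1e-10  # an E-ratio this close to 1 is flagged "boundary"


class RegimeLabel(enum.Enum):
    ALWAYS_A = "always_a"
    ALWAYS_B = "always_b"
    RANDOMIZING = "randomizing"


@dataclass(frozen=True)
class SolveResult:
    """Growth-optimal behavior plus diagnostics.

    ``degenerate`` marks models for which every ``f`` is optimal (e.g.
    ``x_a`` identically equal to ``x_b``); ``f_star = 0.5`` is then reported
    by convention rather than as a unique optimum.
    """

    f_star: float
    regime_label: RegimeLabel
    growth_at_opt: float
    E_ab: float
    E_ba: float
    interior_residual: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "f_star": self.f_star,
            "regime_label": self.regime_label.value,
            "growth_at_opt": self.growth_at_opt,
            "diagnostics": {
                "E_ab": self.E_ab,
                "E_ba": self.E_ba,
                "interior_residual": self.interior_residual,
            },
            "degenerate": self.degenerate,
        }


def expected_ratio(
    model: FecundityModel, numerator: Action, denominator: Action
) -> float:
    """Finite-sum expected offspring ratio, e.g. ``E[x_a / x_b]``.

    Uses ``x / 0 = +inf`` for x > 0; a single positive-probability infinite
    term makes the expectation ``+inf``.  A 0/0 atom cannot occur in a valid
    model.
    """
    validate_model(model).raise_on_error()
    num = model.xa if numerator is Action.A else model.xb
    den = model.xa if denominator is Action.A else model.xb
    total = 0.0
    for q, n, d in zip(model.probs, num, den):
        if d == 0.0:
            if n > 0.0:
                return float("inf")
            raise ValueError("0/0 atom encountered; model should not validate")
        total += q * n / d
    return float(total)


def _interior_root(model: FecundityModel) -> tuple[float, float]:
    """Bisect h(f) = E[(x_a - x_b)/omega(f)] to |h| < 1e-12 on (0, 1).

    h is continuous and strictly decreasing where finite (alpha is strictly
    concave off degeneracy), positive near 0 and negative near 1 in the
    interior case, so plain bisection is globally convergent.
    """
    q, xa, xb, d = model.probs, model.xa, model.xb, model.delta

    def h(f: float) -> float:
        return float(np.sum(q * d / (f * xa + (1.0 - f) * xb)))

    lo, hi = 0.0, 1.0
    f = 0.5
    for _ in range(200):
        f = 0.5 * (lo + hi)
        val = h(f)
        if abs(val) < INTERIOR_TOL:
            break
        if val > 0.0:
            lo = f
        else:
            hi = f
    return f, h(f)


def solve_systematic(model: FecundityModel) -> SolveResult:
    """Growth-optimal f under systematic risk.

    Boundary cases by the expected-ratio tests; otherwise the interior root
    of ``h`` found by bisection.  A model with ``x_a`` identically ``x_b``
    is degenerate (any f optimal) and is reported as randomizing at 0.5.
    """
    validate_model(model).raise_on_error()
    E_ab = expected_ratio(model, Action.A, Action.B)
    E_ba = expected_ratio(model, Action.B, Action.A)
    if np.all(model.delta == 0.0):
        return SolveResult(
            0.5, RegimeLabel.RANDOMIZING, log_growth_systematic(model, 0.5),
            E_ab, E_ba, degenerate=True,
        )
    if E_ba <= 1.0 and E_ab <= 1.0:
        # only possible with both exactly 1 (Cauchy-Schwarz); any f optimal
        return SolveResult(
            0.5, RegimeLabel.RANDOMIZING, log_growth_systematic(model, 0.5),
            E_ab, E_ba, degenerate=True,
        )
    if E_ba <= 1.0:
        return SolveResult(
            1.0, RegimeLabel.ALWAYS_A, log_growth_systematic(model, 1.0), E_ab, E_ba
        )
    if E_ab <= 1.0:
        return SolveResult(
            0.0, RegimeLabel.ALWAYS_B, log_growth_systematic(model, 0.0), E_ab, E_ba
        )
    f_star, resid = _interior_root(model)
    return SolveResult(
        f_star,
        RegimeLabel.RANDOMIZING,
        log_growth_systematic(model, f_star),
        E_ab,
        E_ba,
        interior_residual=abs(resid),
    )


def solve_idiosyncratic(model: FecundityModel) -> SolveResult:
    """Growth-optimal f under idiosyncratic risk: always deterministic.

    ``mu(f) = log(f mu_a + (1-f) mu_b)`` is monotone in f with the sign of
    ``mu_a - mu_b``, so the optimum sits at a boundary; an exact tie of the
    means makes every f optimal (degenerate, reported at 0.5).
    """
    m = moments(model)
    E_ab = expected_ratio(model, Action.A, Action.B)
    E_ba = expected_ratio(model, Action.B, Action.A)
    if m.mu_a > m.mu_b:
        f, label = 1.0, RegimeLabel.ALWAYS_A
    elif m.mu_a < m.mu_b:
        f, label = 0.0, RegimeLabel.ALWAYS_B
    else:
        return SolveResult(
            0.5, RegimeLabel.RANDOMIZING, log_growth_idiosyncratic(model, 0.5),
            E_ab, E_ba, degenerate=True,
        )
    return SolveResult(f, label, log_growth_idiosyncratic(model, f), E_ab, E_ba)


def two_state_solve(scenario: TwoStateScenario) -> SolveResult:
    """Closed-form growth-optimal behavior for a two-state scenario.

    With state-1 payoffs (c_a, c_b) and state-2 payoffs (d_a, d_b):
    ``f* = 1`` iff ``E[x_b/x_a] = p c_b/c_a + (1-p) d_b/d_a <= 1``;
    ``f* = 0`` iff ``E[x_a/x_b] = p c_a/c_b + (1-p) d_a/d_b <= 1``;
    otherwise the interior first-order condition is linear in f and gives::

        f* = [p (c_a - c_b) d_b - (1-p) (d_b - d_a) c_b]
             / [(c_a - c_b) (d_b - d_a)]
    """
    p = scenario.p
    model = scenario.to_model()
    E_ab = expected_ratio(model, Action.A, Action.B)
    E_ba = expected_ratio(model, Action.B, Action.A)
    if E_ba <= 1.0:
        return SolveResult(
            1.0, RegimeLabel.ALWAYS_A, log_growth_systematic(model, 1.0), E_ab, E_ba
        )
    if E_ab <= 1.0:
        return SolveResult(
            0.0, RegimeLabel.ALWAYS_B, log_growth_systematic(model, 0.0), E_ab, E_ba
        )
    ca, cb, da, db = scenario.c_a, scenario.c_b, scenario.d_a, scenario.d_b
    f_star = (p * (ca - cb) * db - (1.0 - p) * (db - da) * cb) / (
        (ca - cb) * (db - da)
    )
    q, xa, xb = model.probs, model.xa, model.xb
    resid = float(np.sum(q * (xa - xb) / (f_star * xa + (1.0 - f_star) * xb)))
    return SolveResult(
        f_star,
        RegimeLabel.RANDOMIZING,
        log_growth_systematic(model, f_star),
        E_ab,
        E_ba,
        interior_residual=abs(resid),
    )


@dataclass(frozen=True)
class MatchingCondition:
    """Whether a two-state scenario sits on the probability-matching locus."""

    holds: bool
    locus_value: float
    in_limit: bool = False  # r1 = +inf with r2 = 0: matching holds as a limit


def probability_matching_condition(scenario: TwoStateScenario) -> MatchingCondition:
    """Test the exact-matching locus ``p (r1 - 1) = (1-p) (1/r2 - 1)``.

    On this locus the interior optimum is exactly ``f* = p``.  The extreme
    scenario r1 = +inf, r2 = 0 — payoffs (c, 0)/(0, d) — satisfies the
    condition in the limit and indeed has f* = p for every c, d > 0.
    """
    r1, r2 = scenario.r1, scenario.r2
    p = scenario.p
    if math.isinf(r1) and r2 == 0.0:
        return MatchingCondition(True, 0.0, in_limit=True)
    if math.isinf(r1) or r2 == 0.0:
        return MatchingCondition(False, float("inf"))
    value = p * (r1 - 1.0) - (1.0 - p) * (1.0 / r2 - 1.0)
    return MatchingCondition(abs(value) < BOUNDARY_FLAG_TOL, value)


@dataclass(frozen=True)
class RegionCell:
    label: RegimeLabel
    boundary: bool = False


def _representative(p: float, r1: float, r2: float) -> TwoStateScenario:
    # f* depends on a two-state scenario only through (p, r1, r2), so fix
    # c_b = d_a = 1 and scale the favored payoffs
    return TwoStateScenario(p=p, c_a=r1, c_b=1.0, d_a=1.0, d_b=1.0 / r2)


def region_classify(p: float, r1: float, r2: float) -> RegionCell:
    """Classify a point of the (r1, r2) relative-fecundity plane.

    Requires r1 > 1 and 0 <= r2 < 1 (action a favored in state 1, b in
    state 2).  The boundary tests only need the expected ratios
    ``E[x_a/x_b] = p r1 + (1-p) r2`` and ``E[x_b/x_a] = p/r1 + (1-p)/r2``,
    so r2 = 0 is handled by the infinity conventions.
    """
    if not (r1 > 1.0):
        raise ValueError(f"r1={r1} must exceed 1")
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2={r2} must lie in [0, 1)")
    E_ab = p * r1 + (1.0 - p) * r2
    E_ba = p / r1 + ((1.0 - p) / r2 if r2 > 0.0 else float("inf"))
    near = min(abs(E_ab - 1.0), abs(E_ba - 1.0)) < BOUNDARY_FLAG_TOL
    if E_ba <= 1.0:
        return RegionCell(RegimeLabel.ALWAYS_A, near)
    if E_ab <= 1.0:
        return RegionCell(RegimeLabel.ALWAYS_B, near)
    return RegionCell(RegimeLabel.RANDOMIZING, near)


@dataclass(frozen=True)
class RegionMap:
    """Dense regime labels over a (r1, r2) grid plus the matching locus."""

    p: float
    r1_values: np.ndarray
    r2_values: np.ndarray
    labels: np.ndarray           # (len(r1), len(r2)) array of label strings
    boundary: np.ndarray         # same shape, bool
    locus: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns r1, r2, label, boundary."""
        rows = [
            (float(r1), float(r2), self.labels[i, j], bool(self.boundary[i, j]))
            for i, r1 in enumerate(self.r1_values)
            for j, r2 in enumerate(self.r2_values)
        ]
        return pd.DataFrame(rows, columns=["r1", "r2", "label", "boundary"])


def matching_locus_r2(p: float, r1: float) -> float:
    """The r2 at which exact probability matching holds for given p, r1."""
    return 1.0 / (1.0 + p * (r1 - 1.0) / (1.0 - p))


def region_map(
    p: float,
    r1_values: "np.ndarray | list[float]",
    r2_values: "np.ndarray | list[float]",
) -> RegionMap:
    """Label every cell of a rectangular (r1, r2) grid and trace the locus."""
    r1_values = np.asarray(r1_values, dtype=float)
    r2_values = np.asarray(r2_values, dtype=float)
    labels = np.empty((r1_values.size, r2_values.size), dtype=object)
    boundary = np.zeros_like(labels, dtype=bool)
    for i, r1 in enumerate(r1_values):
        for j, r2 in enumerate(r2_values):
            cell = region_classify(p, float(r1), float(r2))
            labels[i, j] = cell.label.value
            boundary[i, j] = cell.boundary
    locus = np.array([[r1, matching_locus_r2(p, float(r1))] for r1 in r1_values])
    return RegionMap(p, r1_values, r2_values, labels, boundary, locus)
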