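"""Attainable correlation, the perfect-intelligence benchmark, and the
cost-constrained (bounded-rationality) optimum."""

import math

import numpy as np
import pytest
from scipy.optimize import linprog

from evogrowth import (
    CostModel,
    FecundityModel,
    IntelligenceLabel,
    comonotone_choice_probabilities,
    cost_region_map,
    log_growth_intelligence,
    matching_family,
    moments,
    perfect_intelligence_benchmark,
    rho_max,
    solve_bounded,
    solve_idiosyncratic,
    tie_kappa,
)
from evogrowth.scenarios import IntelligencePolicy


def lp_max_covariance(model: FecundityModel, f: float) -> float:
    """Independent oracle: maximize Cov(I, Delta) over all couplings of a
    Bernoulli(f) indicator with the atom distribution, by linear program.

    Variables are the conditional probabilities q_i = P(I=1 | atom i); the
    marginal constraint is sum p_i q_i = f.
    """
    p, d = model.probs, model.delta
    res = linprog(
        c=-(p * d),
        A_eq=p.reshape(1, -1),
        b_eq=[f],
        bounds=[(0.0, 1.0)] * len(p),
        method="highs",
    )
    assert res.success
    return float(-res.fun - f * float(p @ d))


# ---------------------------------------------------------------------------
# rho_max
# ---------------------------------------------------------------------------

def test_rho_max_canonical_values(canonical):
    assert rho_max(canonical, 0.75) == pytest.approx(1.0, abs=1e-12)
    expected = (0.5 - 0.5 * 0.75) / (math.sqrt(0.25 * 0.1875))
    # Delta = +-3 cancels between numerator and sigma
    assert rho_max(canonical, 0.5) == pytest.approx(expected, rel=1e-12)
    assert rho_max(canonical, 0.5) == pytest.approx(1 / math.sqrt(3), rel=1e-12)


def test_rho_max_agrees_with_lp_oracle(fixture_models):
    small = [m for m in fixture_models if len(m.atoms) <= 4][:25]
    assert len(small) >= 5
    for model in small:
        m = moments(model)
        if m.sigma_delta == 0:
            continue
        for f in (0.1, 0.37, 0.5, 0.85):
            cov = lp_max_covariance(model, f)
            got = rho_max(model, f)
            want = min(cov / (math.sqrt(f * (1 - f)) * m.sigma_delta), 1.0)
            assert got == pytest.approx(want, abs=1e-10)
            assert 0.0 < got <= 1.0


def test_rho_max_rejects_degenerate_inputs(canonical):
    with pytest.raises(ValueError):
        rho_max(canonical, 0.0)
    with pytest.raises(ValueError):
        rho_max(FecundityModel([(1.0, 2, 2)]), 0.5)


# ---------------------------------------------------------------------------
# comonotone coupling construction
# ---------------------------------------------------------------------------

def test_coupling_preserves_marginal_and_hits_requested_correlation(canonical):
    rng = np.random.default_rng(21)
    n = 100_000
    for f, frac in [(0.5, 1.0), (0.5, 0.6), (0.75, 0.9), (0.3, 0.4)]:
        rho = frac * rho_max(canonical, f)
        p_a = comonotone_choice_probabilities(canonical, f, rho)
        assert float(canonical.probs @ p_a) == pytest.approx(f, abs=1e-12)
        atoms = rng.choice(len(canonical.atoms), size=n, p=canonical.probs)
        choices = rng.random(n) < p_a[atoms]
        deltas = canonical.delta[atoms]
        sample_rho = np.corrcoef(choices, deltas)[0, 1]
        se = (1 - rho**2) / math.sqrt(n)  # Fisher-style large-sample scale
        assert abs(sample_rho - rho) < 3 * max(se, 3 / math.sqrt(n))


def test_no_coupling_exceeds_rho_max(fixture_models):
    # the LP maximum IS the comonotone value, so nothing can beat it
    for model in [m for m in fixture_models if len(m.atoms) <= 4][:10]:
        if moments(model).sigma_delta == 0:
            continue
        for f in (0.25, 0.6):
            cov = lp_max_covariance(model, f)
            bound = rho_max(model, f) * math.sqrt(f * (1 - f)) * \
                moments(model).sigma_delta
            assert cov <= bound + 1e-10


# ---------------------------------------------------------------------------
# perfect intelligence benchmark
# ---------------------------------------------------------------------------

def test_benchmark_examples(canonical):
    b = perfect_intelligence_benchmark(canonical)
    assert b["f"] == 0.75 and b["growth"] == pytest.approx(math.log(3), rel=1e-14)
    b = perfect_intelligence_benchmark(FecundityModel([(1.0, 2, 1)]))
    assert b["f"] == 1.0 and b["growth"] == pytest.approx(math.log(2), rel=1e-14)
    b = perfect_intelligence_benchmark(FecundityModel([(0.5, 4, 1), (0.5, 1, 3)]))
    assert b["f"] == 0.5 and b["growth"] == pytest.approx(math.log(3.5), rel=1e-14)


def test_benchmark_attained_by_maximal_correlation(canonical):
    b = perfect_intelligence_benchmark(canonical)
    got = log_growth_intelligence(
        canonical, IntelligencePolicy(b["f"], rho_max(canonical, b["f"]))
    )
    assert got == pytest.approx(b["growth"], rel=1e-12)


# ---------------------------------------------------------------------------
# bounded-rationality optimum
# ---------------------------------------------------------------------------

def test_zero_cost_returns_benchmark(canonical_idio):
    res = solve_bounded(canonical_idio, CostModel.zero())
    assert res.f_star == pytest.approx(0.75, abs=1e-12)
    assert res.rho_star == pytest.approx(1.0, abs=1e-12)
    assert res.growth_at_opt == pytest.approx(math.log(3), rel=1e-12)
    assert res.regime_label is IntelligenceLabel.PROBABILITY_MATCHING
    assert abs(res.benchmark_gap) < 1e-12


def test_zero_cost_matches_benchmark_on_binary_delta_fixtures():
    rng = np.random.default_rng(23)
    for _ in range(20):
        model = matching_family(rng).to_model("idiosyncratic")
        bench = perfect_intelligence_benchmark(model)
        res = solve_bounded(model, CostModel.zero())
        assert res.f_star == pytest.approx(bench["f"], abs=1e-10)
        assert res.growth_at_opt == pytest.approx(bench["growth"], rel=1e-10)


def test_expensive_intelligence_collapses_to_mindless_optimum(canonical_idio):
    res = solve_bounded(canonical_idio, CostModel.linear(10.0))
    base = solve_idiosyncratic(canonical_idio)
    assert res.f_star == base.f_star == 1.0
    assert res.rho_star == 0.0
    assert res.growth_at_opt == pytest.approx(base.growth_at_opt, rel=1e-14)
    assert res.regime_label is IntelligenceLabel.DETERMINISTIC_BOUNDARY
    # a cost that eats the whole correlation can never help
    res = solve_bounded(canonical_idio, CostModel.custom(lambda r: r))
    assert res.growth_at_opt == pytest.approx(base.growth_at_opt, rel=1e-14)


def test_growth_non_increasing_and_rho_non_increasing_in_kappa(canonical_idio):
    kappas = np.linspace(0.0, 2.0, 21)
    growths, rhos = [], []
    for k in kappas:
        res = solve_bounded(canonical_idio, CostModel.linear(float(k)))
        growths.append(res.growth_at_opt)
        if res.regime_label is IntelligenceLabel.PROBABILITY_MATCHING:
            rhos.append(res.rho_star)
    assert all(b <= a + 1e-12 for a, b in zip(growths, growths[1:]))
    assert all(b <= a + 1e-12 for a, b in zip(rhos, rhos[1:]))


def test_three_regime_structure_with_tie(canonical_idio):
    k_star = tie_kappa(canonical_idio)
    assert k_star == pytest.approx(2 / 3, abs=1e-6)
    below = solve_bounded(canonical_idio, CostModel.linear(k_star - 0.05))
    above = solve_bounded(canonical_idio, CostModel.linear(k_star + 0.05))
    at = solve_bounded(canonical_idio, CostModel.linear(k_star))
    assert below.regime_label is IntelligenceLabel.PROBABILITY_MATCHING
    assert above.regime_label is IntelligenceLabel.DETERMINISTIC_BOUNDARY
    assert at.regime_label is IntelligenceLabel.TIE_LINE
    # multiplicity on the tie: matching point and boundary reach the same
    # growth to within the tie tolerance
    match_growth = at.growth_at_opt
    boundary_growth = solve_idiosyncratic(canonical_idio).growth_at_opt
    assert abs(match_growth - boundary_growth) < 1e-9


def test_negative_correlation_never_optimal(canonical_idio):
    # extend the search grid to rho < 0 by direct evaluation: no (f, rho<0)
    # beats the optimizer's answer
    res = solve_bounded(canonical_idio, CostModel.linear(0.3))
    for f in np.linspace(0.05, 0.95, 19):
        for rho in np.linspace(-1.0, 0.0, 11):
            g = log_growth_intelligence(canonical_idio, IntelligencePolicy(f, rho))
            assert g <= res.growth_at_opt + 1e-12


def test_degenerate_delta_falls_back_to_mindless():
    model = FecundityModel([(1.0, 3, 3)], "idiosyncratic")
    res = solve_bounded(model, CostModel.linear(0.1))
    assert res.rho_star == 0.0 and res.degenerate


# ---------------------------------------------------------------------------
# cost-region map
# ---------------------------------------------------------------------------

def test_cost_region_map_monotone_in_kappa():
    kappas = np.linspace(0.0, 2.0, 9)
    ps = np.linspace(0.55, 0.95, 5)
    cmap = cost_region_map(kappas, ps)
    rank = {
        "probability_matching": 0,
        "tie_line": 1,
        "deterministic_boundary": 2,
        "interior": 0,
    }
    labels = cmap.labels
    assert set(np.unique(labels)) >= {"probability_matching",
                                      "deterministic_boundary"}
    assert all(labels[0, j] == "probability_matching"
               for j in range(ps.size))  # kappa = 0 row
    for j in range(ps.size):
        ranks = [rank[labels[i, j]] for i in range(kappas.size)]
        assert ranks == sorted(ranks)
    # tie curve: kappa*(p) = 1/(2p) for the all-or-nothing payoff family
    for p, k_star in cmap.tie_curve:
        assert k_star == pytest.approx(1.0 / (2.0 * p), abs=1e-6)
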