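"""Stochastic population dynamics: exact steps, trajectories, replicates."""

import math
import subprocess
import sys

import numpy as np
import pytest

from evogrowth import (
    FecundityModel,
    IntelligencePolicy,
    Policy,
    SimulationConfig,
    log_growth_intelligence,
    log_growth_systematic,
    realized_growth,
    replicate_summary,
    rho_max,
    simulate,
    step_idiosyncratic,
    step_systematic,
)


SUNNY, RAINY = 0, 1


# ---------------------------------------------------------------------------
# single steps
# ---------------------------------------------------------------------------

def test_step_systematic_deterministic_policy(canonical):
    rng = np.random.default_rng(0)
    assert step_systematic(10, Policy(1.0), SUNNY, canonical, rng) == 30
    assert step_systematic(10, Policy(1.0), RAINY, canonical, rng) == 0
    assert step_systematic(0, Policy(0.5), SUNNY, canonical, rng) == 0


def test_step_systematic_binomial_expectation(canonical):
    rng = np.random.default_rng(1)
    draws = [step_systematic(10, Policy(0.5), SUNNY, canonical, rng)
             for _ in range(4000)]
    assert all(d % 3 == 0 for d in draws)  # 3 * Binomial(10, .5)
    se = 3 * math.sqrt(10 * 0.25) / math.sqrt(len(draws))
    assert abs(np.mean(draws) - 15.0) < 3 * se


def test_step_idiosyncratic_moment_check(canonical_idio):
    rng = np.random.default_rng(2)
    n = 10_000
    draws = [step_idiosyncratic(n, Policy(1.0), canonical_idio, rng)
             for _ in range(60)]
    # per-individual variance for f=1: E[x_a^2] - mu_a^2 = 6.75 - ... = 1.6875
    se = math.sqrt(n * (0.75 * 9 - 2.25**2)) / math.sqrt(len(draws))
    assert abs(np.mean(draws) - 2.25 * n) < 3 * se
    assert step_idiosyncratic(1, Policy(0.0), FecundityModel(
        [(1.0, 2, 1)], "idiosyncratic"), rng) == 1


def test_sampled_mode_rejects_fractional_offspring():
    model = FecundityModel([(1.0, 2.5, 1)])
    with pytest.raises(ValueError):
        SimulationConfig(model, [0.5], generations=3)


# ---------------------------------------------------------------------------
# full trajectories
# ---------------------------------------------------------------------------

def test_conditioned_deterministic_lineage_matches_exact_powers(canonical):
    # 13 favorable generations triple the f=1 lineage each time; the next
    # unfavorable one wipes it out
    cfg = SimulationConfig(canonical, [1.0], n0=10, generations=14, seed=5,
                           conditioning=[SUNNY] * 13 + [RAINY])
    traj = simulate(cfg)
    assert traj.column(0)[13] == 10 * 3**13 == 15_943_230
    assert traj.column(0)[14] == 0
    assert traj.extinct_at == (14,)


def test_conditioning_rejected_under_idiosyncratic_risk(canonical_idio):
    with pytest.raises(ValueError):
        SimulationConfig(canonical_idio, [1.0], generations=2,
                         conditioning=[0, 0])


def test_seed_determinism_within_and_across_processes(canonical):
    cfg = SimulationConfig(canonical, [0.2, 0.75], n0=10, generations=15,
                           seed=99)
    a, b = simulate(cfg), simulate(cfg)
    assert a.counts == b.counts and a.states == b.states
    code = (
        "import evogrowth as eg;"
        "cfg = eg.SimulationConfig(eg.canonical_model(), [0.2, 0.75], n0=10,"
        " generations=15, seed=99);"
        "print(eg.simulate(cfg).counts)"
    )
    out = subprocess.run([sys.executable, "-c", code], capture_output=True,
                         text=True, check=True).stdout.strip()
    assert out == str(a.counts)


def test_policy_columns_do_not_interact(canonical):
    # per-policy RNG streams: removing a column leaves the others untouched
    full = simulate(SimulationConfig(canonical, [0.2, 0.5, 0.9], n0=10,
                                     generations=20, seed=31))
    fewer = simulate(SimulationConfig(canonical, [0.2, 0.5], n0=10,
                                      generations=20, seed=31))
    assert tuple(r[:2] for r in full.counts) == fewer.counts


def test_extinction_is_absorbing(canonical):
    cfg = SimulationConfig(canonical, [1.0], n0=10, generations=10, seed=5,
                           conditioning=[SUNNY, RAINY] + [SUNNY] * 8)
    traj = simulate(cfg)
    assert all(c == 0 for c in traj.column(0)[2:])
    assert traj.extinct_at == (2,)


def test_generation_one_expectation_identity(canonical):
    # mean generation-1 count over replicates = n0 * E[f x_a + (1-f) x_b]
    f, n0, n_rep = 0.6, 10, 2000
    cfg = SimulationConfig(canonical, [f], n0=n0, generations=1, seed=17)
    summary = replicate_summary(cfg, n_rep)
    counts = np.array(summary.terminal_counts[0], dtype=float)
    expect = n0 * float(canonical.probs @ (f * canonical.xa
                                           + (1 - f) * canonical.xb))
    se = counts.std(ddof=1) / math.sqrt(n_rep)
    assert abs(counts.mean() - expect) < 3 * se


def test_table_layout_dataframe(canonical):
    cfg = SimulationConfig(canonical, [0.2, 0.5, 0.75, 0.9, 1.0], n0=10,
                           generations=25, seed=1)
    df = simulate(cfg).to_dataframe()
    assert list(df.columns) == ["generation", "state", "f=.20", "f=.50",
                                "f=.75", "f=.90", "f=1"]
    assert len(df) == 25


# ---------------------------------------------------------------------------
# realized growth
# ---------------------------------------------------------------------------

def test_realized_growth_recovers_alpha_in_expectation_mode(canonical):
    cfg = SimulationConfig(canonical, [0.75], n0=10, generations=2000,
                           seed=3, mode="expectation")
    est = realized_growth(simulate(cfg), 0)
    assert est.within(log_growth_systematic(canonical, 0.75))


def test_realized_growth_error_shrinks_like_sqrt_T(canonical):
    errors = []
    for T in (100, 400, 1600):
        cfg = SimulationConfig(canonical, [0.75], n0=10, generations=T,
                               seed=29, mode="expectation")
        est = realized_growth(simulate(cfg), 0)
        errors.append(abs(est.time_average
                          - log_growth_systematic(canonical, 0.75)))
    # 16x more generations should shrink the error by roughly 4x; allow a
    # generous factor since a single seed is noisy
    assert errors[2] < errors[0]
    assert errors[2] < 10 / math.sqrt(1600)


def test_realized_growth_deterministic_model():
    model = FecundityModel([(1.0, 2, 1)])
    cfg = SimulationConfig(model, [1.0], n0=1, generations=30, seed=0)
    est = realized_growth(simulate(cfg), 0)
    assert est.time_average == pytest.approx(math.log(2), rel=1e-12)
    assert not est.truncated


def test_realized_growth_flags_truncation(canonical):
    cfg = SimulationConfig(canonical, [1.0], n0=10, generations=5, seed=5,
                           conditioning=[SUNNY, SUNNY, RAINY, SUNNY, SUNNY])
    est = realized_growth(simulate(cfg), 0)
    assert est.truncated and len(est.log_multipliers) == 2


# ---------------------------------------------------------------------------
# replicate summaries
# ---------------------------------------------------------------------------

def test_always_a_extinction_frequency_closed_form(canonical):
    # the f=1 lineage survives 25 generations iff all 25 are sunny
    cfg = SimulationConfig(canonical, [1.0], n0=10, generations=25, seed=41)
    n = 1000
    summary = replicate_summary(cfg, n)
    p_ext = 1 - 0.75**25
    se = math.sqrt(p_ext * (1 - p_ext) / n)
    assert abs(summary.extinction_frequency[0] - p_ext) < 3 * se + 1e-9
    assert summary.modal_terminal_count[0] == 0


def test_single_replicate_degenerate_frequencies(canonical):
    cfg = SimulationConfig(canonical, [0.75, 1.0], n0=10, generations=5,
                           seed=2)
    summary = replicate_summary(cfg, 1)
    assert all(v in (0.0, 1.0) for v in summary.extinction_frequency)
    assert all(v in (0.0, 1.0) for v in summary.dominance_frequency)


# ---------------------------------------------------------------------------
# intelligent phenotypes in simulation
# ---------------------------------------------------------------------------

def test_intelligent_policy_outgrows_mindless_same_f(canonical_idio):
    f = 0.75
    rho = rho_max(canonical_idio, f)
    pol = IntelligencePolicy(f, rho)
    cfg = SimulationConfig(canonical_idio, [Policy(f), pol], n0=200,
                           generations=40, seed=53)
    traj = simulate(cfg)
    est = realized_growth(traj, 1)
    target = log_growth_intelligence(canonical_idio, pol)
    # finite-population noise: just demand agreement at 3 SE and dominance
    assert est.within(target)
    assert traj.terminal()[1] > traj.terminal()[0]
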