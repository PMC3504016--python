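"""Seeded random scenario generation for property tests and experiments.

Models are drawn with finite support (2-6 states by default), integer
offspring counts in 0..10, and Dirichlet state probabilities; atoms in which
both actions yield zero offspring are redrawn, so every generated model
passes validation.  Rejection sampling enforces a quota of
interior-randomizing models (those whose systematic-risk optimum is strictly
between 0 and 1), which are the interesting regime for most properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimize import RegimeLabel, solve_systematic
from .scenarios import (
    FecundityModel,
    OutcomeAtom,
    Regime,
    TwoStateScenario,
    validate_model,
)

__all__ = ["FixtureSpec", "generate_fixtures", "random_two_state", "matching_family"]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_models: int = 200
    support_range: tuple[int, int] = (2, 6)
    max_offspring: int = 10
    regime: Regime | str = Regime.SYSTEMATIC
    min_interior: int = 0
    max_iterations: int = 200_000

    def __post_init__(self):
        lo, hi = self.support_range
        if not (2 <= lo <= hi):
            raise ValueError("support sizes must be at least 2")
        if self.min_interior > self.n_models:
            raise ValueError("interior quota exceeds requested model count")


def _random_model(rng: np.random.Generator, spec: FixtureSpec) -> FecundityModel:
    lo, hi = spec.support_range
    k = int(rng.integers(lo, hi + 1))
    probs = rng.dirichlet(np.ones(k))
    # keep every atom's probability bounded away from 0
    probs = 0.99 * probs + 0.01 / k
    probs = probs / probs.sum()
    atoms = []
    for i in range(k):
        while True:
            xa = int(rng.integers(0, spec.max_offspring + 1))
            xb = int(rng.integers(0, spec.max_offspring + 1))
            if xa > 0 or xb > 0:
                break
        atoms.append(OutcomeAtom(float(probs[i]), float(xa), float(xb)))
    return FecundityModel(atoms, spec.regime)


def generate_fixtures(spec: FixtureSpec) -> list[FecundityModel]:
    """Deterministic batch of valid random models meeting the interior quota."""
    rng = np.random.default_rng(spec.seed)
    interior: list[FecundityModel] = []
    other: list[FecundityModel] = []
    for _ in range(spec.max_iterations):
        if len(interior) >= spec.min_interior and (
            len(interior) + len(other) >= spec.n_models
        ):
            break
        model = _random_model(rng, spec)
        if not validate_model(model).ok:
            continue
        res = solve_systematic(model)
        is_interior = res.regime_label is RegimeLabel.RANDOMIZING and not res.degenerate
        if is_interior:
            interior.append(model)
        elif len(interior) + len(other) < spec.n_models:
            other.append(model)
    if len(interior) < spec.min_interior:
        raise RuntimeError(
            f"could not reach the interior-model quota "
            f"({len(interior)}/{spec.min_interior}) within the iteration cap"
        )
    models = (interior + other)[: spec.n_models]
    if len(models) < spec.n_models:
        raise RuntimeError("could not generate the requested number of models")
    return models


def random_two_state(
    rng: np.random.Generator,
    max_offspring: int = 10,
    integer: bool = True,
) -> TwoStateScenario:
    """Random valid two-state scenario (action a favored in state 1, b in 2)."""
    while True:
        p = float(rng.uniform(0.05, 0.95))
        if integer:
            ca = int(rng.integers(1, max_offspring + 1))
            cb = int(rng.integers(0, ca))
            db = int(rng.integers(1, max_offspring + 1))
            da = int(rng.integers(0, db))
        else:
            ca = float(rng.uniform(0.5, max_offspring))
            cb = float(rng.uniform(0.0, ca * 0.99))
            db = float(rng.uniform(0.5, max_offspring))
            da = float(rng.uniform(0.0, db * 0.99))
        try:
            return TwoStateScenario(p=p, c_a=ca, c_b=cb, d_a=da, d_b=db)
        except ValueError:
            continue


def matching_family(
    rng: np.random.Generator, max_offspring: int = 10
) -> TwoStateScenario:
    """Random scenario from the (c, 0)/(0, d) template: f* = p exactly."""
    return TwoStateScenario(
        p=float(rng.uniform(0.05, 0.95)),
        c_a=int(rng.integers(1, max_offspring + 1)),
        c_b=0,
        d_a=0,
        d_b=int(rng.integers(1, max_offspring + 1)),
    )
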