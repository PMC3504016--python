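import numpy as np
import pytest

from evogrowth import (
    FecundityModel,
    FixtureSpec,
    canonical_model,
    generate_fixtures,
)


@pytest.fixture(scope="session")
def canonical() -> FecundityModel:
    """Sunshine/rain nesting model: (p=.75, 3, 0) / (.25, 0, 3), systematic."""
    return canonical_model()


@pytest.fixture(scope="session")
def canonical_idio() -> FecundityModel:
    return canonical_model("idiosyncratic")


@pytest.fixture(scope="session")
def fixture_models() -> list[FecundityModel]:
    """200 random valid models, at least 80 with interior optima."""
    return generate_fixtures(FixtureSpec(seed=42, n_models=200, min_interior=80))


def grid_argmax_alpha(model: FecundityModel, n: int = 10_001):
    """Independent brute-force oracle: maximize alpha(f) on a dense grid."""
    fs = np.linspace(0.0, 1.0, n)
    q, xa, xb = model.probs, model.xa, model.xb
    omega = np.outer(fs, xa) + np.outer(1.0 - fs, xb)
    with np.errstate(divide="ignore"):
        vals = np.where(
            (omega > 0).all(axis=1),
            np.where(omega > 0, np.log(np.where(omega > 0, omega, 1.0)), 0.0) @ q,
            -np.inf,
        )
    i = int(np.argmax(vals))
    return float(fs[i]), float(vals[i])
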