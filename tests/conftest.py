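import numpy as np
import pytest

from tsopgs.synthdata import SimConfig, simulate_study
from tsopgs.tso import build_spec

# truth used across tests when simulating directly from the latent model
LAM_C = np.array([0.92, 1.02, 1.12, 1.22, 1.02, 0.81, 1.12, 1.22, 1.02, 0.92, 1.32, 1.12])
LAM_S = np.array([1.52, 1.32, 1.22, 1.12, 1.42, 1.52, 1.32, 1.12, 1.52, 1.42, 1.22, 1.32])
RESID_SD = np.full(12, 1.15)


def simulate_indicators(
    n: int,
    rng: np.random.Generator,
    lam_c: np.ndarray = LAM_C,
    lam_s: np.ndarray = LAM_S,
    resid_sd: np.ndarray = RESID_SD,
    b_common: float = 0.0,
    x: np.ndarray | None = None,
    noise: str = "normal",
):
    """Continuous indicators from the 4x3 trait-state-occasion structure.

    When ``b_common`` is non-zero the common factor is ``b x + resid``
    with marginal variance 1 (x standard normal unless supplied).
    ``noise='t3'`` replaces the indicator residual with a scaled t(3).
    """
    if x is None:
        x = rng.standard_normal(n)
    C = b_common * x + np.sqrt(1.0 - b_common**2) * rng.standard_normal(n)
    S = rng.standard_normal((n, 4))
    O = rng.standard_normal((n, 3))
    Y = np.empty((n, 12))
    for k in range(4):
        for t in range(3):
            i = k * 3 + t
            if noise == "t3":
                eps = rng.standard_t(3, n) / np.sqrt(3.0)  # unit variance
            else:
                eps = rng.standard_normal(n)
            Y[:, i] = lam_c[i] * C + lam_s[i] * S[:, k] + O[:, t] + resid_sd[i] * eps
    return Y, {"common": C, "specific": S, "occasion": O, "x": x}


@pytest.fixture(scope="session")
def default_spec():
    return build_spec(4, 3)


@pytest.fixture(scope="session")
def small_study():
    """One simulated study shared by read-only tests."""
    cfg = SimConfig(
        n_individuals=600,
        n_snps=100,
        n_traits=2,
        pgs_effects=[[0.14, 0.0, 0.0, 0.0, 0.0], [0.0, 0.12, 0.0, 0.0, 0.0]],
        missing_rate=0.05,
        seed=42,
    )
    return simulate_study(cfg)
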