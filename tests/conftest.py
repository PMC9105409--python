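import numpy as np
import pytest
from scipy.optimize import brentq

from crabpkin import MMParams, PPIParams


def bisection_unbound(total_ligand: float, total_binder: float, kd: float) -> float:
    """Independent oracle for the free-ligand concentration.

    Solves the mass-balance relation u * (C_t - (A_t - u)) = K_d * (A_t - u)
    by bracketed root-finding on [0, A_t]; monotone in u, so the root is
    unique.
    """
    if total_ligand == 0.0:
        return 0.0
    if kd == 0.0:
        return max(total_ligand - total_binder, 0.0)

    def f(u: float) -> float:
        complex_ = total_ligand - u
        return u * (total_binder - complex_) - kd * complex_

    return brentq(f, 0.0, total_ligand, xtol=1e-14, rtol=1e-15)


@pytest.fixture
def cyp26_mm() -> MMParams:
    """CYP26A1 Michaelis-Menten constants (free-atRA fit)."""
    return MMParams(km=4.7, kcat=1.07)


@pytest.fixture
def crabp1_ppi(cyp26_mm: MMParams) -> PPIParams:
    """Fitted CRABP1-CYP26A1 interaction parameters."""
    return PPIParams(
        ki=0.39, alpha_k=0.99, beta_kcat=0.80, fixed_mm=cyp26_mm, fixed_kd=4.7
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
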