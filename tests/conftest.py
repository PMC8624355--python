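import numpy as np
import pytest

from magaggl import CONSTANTS, Medium, ParticleSpec

#: reference magnetite-like saturation magnetisation, A/m
MS_REF = 4.8e5


@pytest.fixture(scope="session")
def medium():
    """Cell-interior medium used throughout the threshold analysis."""
    return Medium(T=300.0, eta=0.00235)


@pytest.fixture(scope="session")
def constants():
    return CONSTANTS


@pytest.fixture(scope="session")
def particle_22nm():
    """Threshold-sized particle of the intermediate-anisotropy case."""
    return ParticleSpec(d=22e-9, K=11e3, MS=MS_REF)


@pytest.fixture(scope="session")
def sw_particle():
    """d = 20 nm, MS = 480 kA/m reference particle of the T = 0 loop study."""
    return ParticleSpec(d=20e-9, K=10e3, MS=480e3)


def boltzmann_axis_cdf(sigma: float, n_grid: int = 4001):
    """Independent oracle: CDF of the easy-axis projection x = m.n of a
    macrospin in zero field, p(x) ~ exp(sigma x^2) on [-1, 1] (the
    uniform sphere measure is flat in x).  Numerical quadrature only —
    shares nothing with the integrator under test."""
    from scipy.integrate import cumulative_trapezoid

    grid = np.linspace(-1.0, 1.0, n_grid)
    pdf = np.exp(sigma * (grid**2 - 1.0))  # offset avoids overflow
    cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    return lambda x: np.interp(x, grid, cdf)
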