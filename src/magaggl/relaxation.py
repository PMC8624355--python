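"""Closed-form relaxation physics of a single-domain magnetic nanoparticle.

The agglomeration argument compares three characteristic timescales:

* the Néel time ``tau_N`` — thermal activation of the moment over the
  uniaxial anisotropy barrier KV (high-barrier asymptote),
* the translational diffusion time ``tau_diff`` — time to diffuse across
  the distance at which the dipole-dipole energy of two parallel moments
  equals k_B T,
* the Brownian rotation time ``tau_B`` — physical rotation of the whole
  particle in the viscous medium.

A particle whose moment flips internally faster than it can translate or
rotate towards a neighbour (tau_N < tau_diff, tau_B) presents no stable
dipole to bind to, so purely magnetic agglomeration is suppressed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ContactViolationError
from .params import CONSTANTS, Medium, ParticleSpec, PhysicalConstants

__all__ = [
    "dipolar_thermal_ratio",
    "neel_time",
    "diffusion_distance",
    "diffusion_time",
    "brown_rotation_time",
    "blocking_size",
    "relaxation_profile",
    "RelaxationProfile",
]


def dipolar_thermal_ratio(
    particle: ParticleSpec,
    medium: Medium,
    lcc: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Ratio Gamma of the dipolar energy of two parallel-aligned particle
    moments at centre distance ``lcc`` to the thermal energy k_B T.

    Gamma = mu0 (MS V)^2 / (2 pi lcc^3 kB T).  Gamma > 1 conventionally
    signals that magnetostatic attraction beats thermal agitation.
    Independent of the anisotropy constant.
    """
    if lcc < particle.d:
        raise ContactViolationError(
            f"centre distance lcc={lcc} m smaller than particle diameter {particle.d} m"
        )
    return (
        constants.mu0
        * particle.moment**2
        / (2.0 * math.pi * lcc**3 * constants.kB * medium.T)
    )


def neel_time(
    particle: ParticleSpec,
    medium: Medium,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Néel relaxation time, high-barrier uniaxial asymptote.

    tau_N = (sqrt(pi)/2) tau0 exp(sigma) / sqrt(sigma),
    sigma = K V / (kB T).

    For sigma < 1 the asymptote loses validity; the value is still
    returned but a warning is emitted so profiles can span small sizes.
    """
    sigma = particle.K * particle.volume / (constants.kB * medium.T)
    if sigma <= 0:
        raise ValueError(f"anisotropy barrier sigma={sigma} must be positive")
    if sigma < 1.0:
        warnings.warn(
            f"sigma={sigma:.3g} < 1: high-barrier Néel expression is extrapolated",
            stacklevel=2,
        )
    return math.sqrt(math.pi) / 2.0 * constants.tau0 * math.exp(sigma) / math.sqrt(sigma)


def diffusion_distance(
    particle: ParticleSpec,
    medium: Medium,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Distance <x> at which the dipolar energy equals kB T (Gamma = 1).

    <x> = [mu0 (MS V)^2 / (2 pi kB T)]^(1/3).  Evaluating the dipolar
    ratio at lcc = <x> returns exactly 1 by construction.
    """
    return (
        constants.mu0 * particle.moment**2 / (2.0 * math.pi * constants.kB * medium.T)
    ) ** (1.0 / 3.0)


def diffusion_time(
    particle: ParticleSpec,
    medium: Medium,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Time to diffuse across <x>: tau_diff = <x>^2 6 pi eta R_hyd/(kB T).

    This is <x>^2 / D with the Stokes-Einstein diffusion coefficient
    D = kB T/(6 pi eta R_hyd); the hydrodynamic radius includes the
    nonmagnetic coating.
    """
    x = diffusion_distance(particle, medium, constants)
    return x**2 * 6.0 * math.pi * medium.eta * particle.r_hyd / (constants.kB * medium.T)


def brown_rotation_time(
    particle: ParticleSpec,
    medium: Medium,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Brownian (Debye) rotation time tau_B = 3 eta V_hyd / (kB T)."""
    return 3.0 * medium.eta * particle.v_hyd / (constants.kB * medium.T)


def blocking_size(
    K: float,
    TB: float = 300.0,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Sphere diameter whose blocking temperature TB = K V/(25 kB) equals
    the given temperature — the ZFC/FC superparamagnetism criterion.

    d_TB = [6 * 25 kB TB / (pi K)]^(1/3); strictly decreasing in K.
    """
    if K <= 0 or TB <= 0:
        raise ValueError("K and TB must be positive")
    return (6.0 * 25.0 * constants.kB * TB / (math.pi * K)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class RelaxationProfile:
    """Vectorised relaxation quantities over a diameter grid (all SI)."""

    d_grid: np.ndarray
    tau_N: np.ndarray
    tau_B: np.ndarray
    tau_diff: np.ndarray
    gamma_ratio: np.ndarray
    x_diff: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.d_grid)
        for name in ("tau_N", "tau_B", "tau_diff", "gamma_ratio", "x_diff"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
            if not np.all(arr > 0) and not np.all(arr >= 0):
                raise ValueError(f"{name} contains negative entries")

    def to_dataframe(self) -> pd.DataFrame:
        """Profile as a DataFrame in reporting units (nm, s)."""
        return pd.DataFrame(
            {
                "d_nm": self.d_grid * 1e9,
                "tau_N_s": self.tau_N,
                "tau_B_s": self.tau_B,
                "tau_diff_s": self.tau_diff,
                "gamma": self.gamma_ratio,
                "x_diff_nm": self.x_diff * 1e9,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def relaxation_profile(
    K: float,
    MS: float,
    tnm: float,
    medium: Medium,
    constants: PhysicalConstants = CONSTANTS,
    d_grid: np.ndarray | None = None,
) -> RelaxationProfile:
    """Evaluate all characteristic quantities on a diameter grid.

    The Gamma column is evaluated at contact (lcc = d), the convention of
    the touching-particles agglomeration estimate.  Equivalent to mapping
    the scalar operations over the grid, but vectorised.
    """
    if d_grid is None:
        d_grid = np.linspace(5e-9, 50e-9, 451)
    d = np.asarray(d_grid, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("d_grid must be a non-empty 1-D array")
    if np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValueError("d_grid must be positive and strictly increasing")

    kBT = constants.kB * medium.T
    V = np.pi / 6.0 * d**3
    sigma = K * V / kBT
    if np.any(sigma < 1.0):
        warnings.warn(
            "profile extends below sigma = 1 where the Néel asymptote is extrapolated",
            stacklevel=2,
        )
    tau_N = np.sqrt(np.pi) / 2.0 * constants.tau0 * np.exp(sigma) / np.sqrt(sigma)
    r_hyd = d / 2.0 + tnm
    v_hyd = 4.0 * np.pi / 3.0 * r_hyd**3
    tau_B = 3.0 * medium.eta * v_hyd / kBT
    x = (constants.mu0 * (MS * V) ** 2 / (2.0 * np.pi * kBT)) ** (1.0 / 3.0)
    tau_diff = x**2 * 6.0 * np.pi * medium.eta * r_hyd / kBT
    gamma = constants.mu0 * (MS * V) ** 2 / (2.0 * np.pi * d**3 * kBT)
    return RelaxationProfile(
        d_grid=d, tau_N=tau_N, tau_B=tau_B, tau_diff=tau_diff,
        gamma_ratio=gamma, x_diff=x,
    )
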