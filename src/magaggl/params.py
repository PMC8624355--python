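"""Parameter containers: particle geometry/magnetics, embedding medium,
physical constants and AC-field / integrator settings.

All values are SI internally (m, A/m, J/m^3, K, kg/(m s), Hz).  The CLI
layer converts from the customary lab units (nm, kJ/m^3, mT, kHz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the model.

    ``mu0`` is kept at the rounded 1.256e-6 T m/A so that closed-form
    results match the customary arithmetic of the field; ``kB`` is the SI
    exact value.  ``tau0`` is the Néel attempt-time prefactor, which for
    real nanoparticles lies between 1e-12 and 1e-9 s; the default of
    1e-9 s is the value calibrated for magnetite-like parameters (see
    docs/methods.md).
    """

    mu0: float = 1.256e-6  # vacuum permeability, T m/A
    kB: float = 1.380649e-23  # Boltzmann constant, J/K
    tau0: float = 1.0e-9  # Néel attempt time, s
    gamma_e: float = 1.76e11  # electron gyromagnetic ratio, rad/(s T)

    def __post_init__(self) -> None:
        if not (1e-12 <= self.tau0 <= 1e-9):
            raise ValueError(
                f"tau0={self.tau0!r} s outside the physical 1e-12..1e-9 s range"
            )
        if self.mu0 <= 0 or self.kB <= 0 or self.gamma_e <= 0:
            raise ValueError("constants must be positive")


#: Default constants shared by all operations unless overridden.
CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class ParticleSpec:
    """One monodisperse single-domain particle type.

    Parameters
    ----------
    d : float
        Magnetic core diameter, m.
    K : float
        Uniaxial (effective) anisotropy constant, J/m^3.
    MS : float
        Saturation magnetisation, A/m.
    tnm : float, optional
        Nonmagnetic coating thickness, m.  Enters only the hydrodynamic
        radius (drag), never the magnetic volume.
    rho : float, optional
        Mass density used to convert volumetric losses to W/g; the default
        is the bulk magnetite value 5180 kg/m^3.
    """

    d: float
    K: float
    MS: float
    tnm: float = 0.0
    rho: float = 5180.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"diameter must be positive, got {self.d}")
        if self.K <= 0:
            raise ValueError(f"anisotropy constant must be positive, got {self.K}")
        if self.MS < 0:
            raise ValueError(f"saturation magnetisation must be >= 0, got {self.MS}")
        if self.tnm < 0:
            raise ValueError(f"coating thickness must be >= 0, got {self.tnm}")
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")

    @property
    def volume(self) -> float:
        """Magnetic volume V = (pi/6) d^3, m^3."""
        return math.pi / 6.0 * self.d**3

    @property
    def r_hyd(self) -> float:
        """Hydrodynamic radius d/2 + tnm, m."""
        return self.d / 2.0 + self.tnm

    @property
    def v_hyd(self) -> float:
        """Hydrodynamic volume (4 pi/3) R_hyd^3, m^3."""
        return 4.0 * math.pi / 3.0 * self.r_hyd**3

    @property
    def moment(self) -> float:
        """Particle magnetic moment MS * V, A m^2."""
        return self.MS * self.volume

    def anisotropy_field(self, constants: PhysicalConstants = CONSTANTS) -> float:
        """Anisotropy field H_K = 2K/(mu0 MS), A/m."""
        if self.MS == 0:
            raise ValueError("anisotropy field undefined for MS = 0")
        return 2.0 * self.K / (constants.mu0 * self.MS)


@dataclass(frozen=True)
class Medium:
    """Embedding fluid: absolute temperature (K) and dynamic viscosity
    (kg/(m s)).  The default viscosity 0.00235 kg/(m s) is the nm-scale
    effective value for the cell interior; water is 0.001."""

    T: float = 300.0
    eta: float = 0.00235

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.eta <= 0:
            raise ValueError(f"viscosity must be positive, got {self.eta}")


@dataclass(frozen=True)
class FieldProtocol:
    """AC drive: amplitude (A/m), frequency (Hz), waveform and sampling."""

    Hmax: float
    f: float
    waveform: str = "sinusoidal"
    n_cycles: int = 3
    n_steps_per_cycle: int = 1000

    def __post_init__(self) -> None:
        if self.Hmax < 0:
            raise ValueError("Hmax must be >= 0")
        if self.f <= 0:
            raise ValueError("frequency must be positive")
        if self.waveform not in ("sinusoidal", "triangular"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.n_steps_per_cycle < 100:
            raise ValueError("need >= 100 steps per cycle")

    @property
    def period(self) -> float:
        return 1.0 / self.f


@dataclass(frozen=True)
class LLGParams:
    """Stochastic LLG integrator settings.

    ``dt`` of None means "derive from the field protocol",
    dt = 1/(f * n_steps_per_cycle).  ``alpha`` is the Gilbert damping.
    """

    alpha: float = 0.1
    gamma_e: float = 1.76e11
    dt: float | None = None
    T: float = 300.0
    seed: int = 0
    n_particles: int = 100

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("damping alpha must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < 0:
            raise ValueError("temperature must be >= 0")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")


# unit helpers used by the CLI ------------------------------------------------

def mT_to_A_per_m(b_mT: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Convert a field amplitude given as mu0*H in mT to H in A/m."""
    return b_mT * 1e-3 / constants.mu0


def A_per_m_to_mT(h: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Convert H in A/m to mu0*H in mT."""
    return h * constants.mu0 * 1e3
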