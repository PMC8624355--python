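"""Dynamic hysteresis and heating performance of single-domain particles.

Two solvers share one loop container:

* ``sw_quasistatic_loop`` — the T = 0 Stoner-Wohlfarth limit: each
  orientation follows its local energy minimum as the field is swept
  infinitely slowly, switching when the metastable minimum disappears.
  Saturated losses per cycle are 8K for an aligned axis and about 2K for
  a random 3-D axis distribution.
* ``sllg_simulate`` — finite-temperature stochastic Landau-Lifshitz-
  Gilbert dynamics of a fixed-axis macrospin ensemble under an AC field,
  with the thermal field satisfying Brown's fluctuation-dissipation
  relation.

SAR (specific absorption rate) is the loop area times the drive
frequency, converted to W/g with the particle mass density.  Physical
(Brownian) rotation of the particle body is deliberately not simulated:
easy axes stay fixed, so only the internal (Néel) channel heats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss

from ._kernels import _sllg_run, _sllg_sample_axis_projection, _sw_branch, _sw_ensemble
from .exceptions import CycleError, TimestepError
from .params import (
    CONSTANTS,
    FieldProtocol,
    LLGParams,
    ParticleSpec,
    PhysicalConstants,
)

__all__ = [
    "HysteresisLoop",
    "sw_switching_field",
    "sw_quasistatic_loop",
    "sllg_simulate",
    "sllg_equilibrium_sample",
    "loop_area",
    "sar_sweep",
]


def sw_switching_field(psi):
    """Reduced Stoner-Wohlfarth switching field h_sw = H_sw/H_K.

    Astroid formula h_sw = (cos^(2/3) psi + sin^(2/3) psi)^(-3/2) for the
    angle ``psi`` between easy axis and field; angles outside [0, pi/2]
    are folded in by the symmetry of the astroid.  Ranges from 1 at
    psi = 0 or pi/2 down to 1/2 at psi = pi/4.
    """
    p = np.abs(np.asarray(psi, dtype=float))
    p = np.mod(p, np.pi)
    p = np.where(p > np.pi / 2, np.pi - p, p)
    c, s = np.cos(p), np.sin(p)
    out = (c ** (2.0 / 3.0) + s ** (2.0 / 3.0)) ** (-1.5)
    return float(out) if np.isscalar(psi) else out


@dataclass(frozen=True)
class HysteresisLoop:
    """One closed (H, M) cycle with its volumetric loss and SAR.

    ``H`` and ``M`` are the field and the ensemble magnetisation
    projected on the field axis, both in A/m, sampled over one period
    (first and last samples coincide).  ``area`` is the loss per cycle in
    J/m^3 and ``sar`` the specific absorption rate in W/g.
    """

    H: np.ndarray
    M: np.ndarray
    area: float
    sar: float
    f: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"H_A_per_m": self.H, "M_A_per_m": self.M})


def loop_area(H, M, constants: PhysicalConstants = CONSTANTS) -> float:
    """Hysteresis loss per cycle, area = mu0 |closed-loop integral M dH|.

    Trapezoidal quadrature along the sampled trajectory; raises
    ``CycleError`` unless the field trajectory closes on itself.
    """
    H = np.asarray(H, dtype=float)
    M = np.asarray(M, dtype=float)
    if H.shape != M.shape or H.ndim != 1 or H.size < 3:
        raise ValueError("H and M must be equal-length 1-D arrays")
    scale = np.max(np.abs(H)) or 1.0
    if abs(H[0] - H[-1]) > 1e-9 * scale:
        raise CycleError(
            f"field trajectory is not closed: H[0]={H[0]}, H[-1]={H[-1]}"
        )
    return constants.mu0 * abs(np.trapezoid(M, H))


def _quasistatic_path(hmax_red: float, n_steps: int) -> np.ndarray:
    """Two triangular cycles +h -> -h -> +h in reduced field units; the
    first cycle washes out the initial-state transient."""
    n_half = max(n_steps // 2, 50)
    down = np.linspace(hmax_red, -hmax_red, n_half + 1)
    cycle = np.concatenate([down, down[::-1][1:]])
    return np.concatenate([cycle, cycle[1:]])


def _psi_weights(
    psi_or_ensemble: Union[float, str, np.ndarray],
    n_random: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise the orientation argument to (psi angles, weights).

    Accepts a single angle (rad), a 1-D array of angles (equal weights,
    e.g. angles of axes already sampled uniformly on the sphere), an
    (n, 3) array of unit axis vectors, or the string ``"random"`` for a
    deterministic Gauss-Legendre quadrature of the uniform-axis average
    (density sin(psi) d psi, i.e. uniform in cos(psi))."""
    if isinstance(psi_or_ensemble, str):
        if psi_or_ensemble != "random":
            raise ValueError(f"unknown ensemble {psi_or_ensemble!r}")
        u, w = leggauss(n_random)  # nodes on (-1, 1)
        u = 0.5 * (u + 1.0)  # cos(psi) uniform on (0, 1)
        return np.arccos(u), 0.5 * w
    arr = np.asarray(psi_or_ensemble, dtype=float)
    if arr.ndim == 0:
        return arr.reshape(1), np.ones(1)
    if arr.ndim == 2 and arr.shape[1] == 3:
        cospsi = np.abs(arr[:, 2]) / np.linalg.norm(arr, axis=1)
        return np.arccos(np.clip(cospsi, 0.0, 1.0)), np.ones(arr.shape[0])
    if arr.ndim == 1:
        return arr, np.ones(arr.size)
    raise ValueError("psi_or_ensemble must be an angle, angles, (n,3) axes or 'random'")


def sw_quasistatic_loop(
    particle: ParticleSpec,
    psi_or_ensemble: Union[float, str, np.ndarray],
    protocol: FieldProtocol,
    constants: PhysicalConstants = CONSTANTS,
) -> HysteresisLoop:
    """T = 0 quasistatic Stoner-Wohlfarth hysteresis loop.

    The field is swept between +-Hmax; each orientation's moment follows
    the local minimum of the reduced energy
    sin^2(theta - psi) - 2 (H/H_K) cos(theta) and jumps when that
    minimum loses stability.  The returned loop is the weighted
    orientation average of the second sweep cycle (the first absorbs the
    initial-state transient).
    """
    hk = particle.anisotropy_field(constants)
    hmax_red = protocol.Hmax / hk
    path = _quasistatic_path(hmax_red, protocol.n_steps_per_cycle)
    psis, weights = _psi_weights(psi_or_ensemble)
    m = _sw_ensemble(np.ascontiguousarray(psis), np.ascontiguousarray(weights), path)
    n_keep = (path.size + 1) // 2  # second cycle, closed
    H = path[-n_keep:] * hk
    M = m[-n_keep:] * particle.MS
    area = loop_area(H, M, constants)
    sar = area * protocol.f / particle.rho * 1e-3  # W/g
    return HysteresisLoop(H=H, M=M, area=area, sar=sar, f=protocol.f)


def _applied_field(protocol: FieldProtocol, n_steps: int) -> np.ndarray:
    """Applied field at the n_cycles*n_steps + 1 step boundaries."""
    i = np.arange(protocol.n_cycles * n_steps + 1)
    phase = i / n_steps  # cycles
    if protocol.waveform == "sinusoidal":
        return protocol.Hmax * np.sin(2.0 * np.pi * phase)
    # symmetric triangle starting at 0, peaking at quarter period
    frac = np.mod(phase + 0.25, 1.0)
    return protocol.Hmax * (4.0 * np.abs(frac - 0.5) - 1.0)


def sllg_simulate(
    particle: ParticleSpec,
    protocol: FieldProtocol,
    llg: LLGParams,
    axes: np.ndarray | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> HysteresisLoop:
    """Finite-temperature dynamic hysteresis loop from the stochastic LLG
    equation for a fixed-easy-axis macrospin ensemble.

    Integrates dm/dt = -gamma/(1+alpha^2) [m x H_eff
    + alpha m x (m x H_eff)] with H_eff = H_K (m.n) n + H(t) z + H_th by
    the stochastic Heun scheme; the white thermal field has per-component
    variance 2 alpha kB T/(mu0^2 gamma MS V dt).  The first cycle is
    discarded as transient and the remaining cycles are phase-averaged
    into one closed loop.

    ``axes`` defaults to ``llg.n_particles`` unit vectors drawn uniformly
    on the sphere from ``llg.seed``.
    """
    from .scenarios import random_axes  # deferred: scenarios imports params only

    if axes is None:
        axes = random_axes(llg.n_particles, llg.seed)
    axes = np.ascontiguousarray(np.asarray(axes, dtype=float))
    if axes.ndim != 2 or axes.shape[1] != 3:
        raise ValueError("axes must be an (n, 3) array of unit vectors")

    if llg.dt is None:
        dt = protocol.period / protocol.n_steps_per_cycle
        n_steps = protocol.n_steps_per_cycle
    else:
        dt = llg.dt
        n_steps = int(round(protocol.period / dt))
        if n_steps < 100:
            raise TimestepError(
                f"dt={dt} s gives only {n_steps} steps per field cycle"
            )

    hk = particle.anisotropy_field(constants)
    omega_max = llg.gamma_e * constants.mu0 * (hk + protocol.Hmax)
    if omega_max * dt > 0.25:
        raise TimestepError(
            f"dt={dt:.3g} s too coarse: gamma mu0 (H_K+Hmax) dt = "
            f"{omega_max * dt:.3g} > 0.25; refine to < "
            f"{0.25 / omega_max:.3g} s"
        )

    if llg.T == 0.0:
        # Deterministic runs: an axis exactly parallel to the field makes
        # m = n an exact unstable equilibrium (zero torque, no noise to
        # leave it).  A 1e-6 rad tilt about y removes the degeneracy and
        # shifts the switching field by only ~1e-4 relative.
        eps = 1e-6
        ax = axes.copy()
        ax[:, 0], ax[:, 2] = (
            axes[:, 0] * np.cos(eps) + axes[:, 2] * np.sin(eps),
            axes[:, 2] * np.cos(eps) - axes[:, 0] * np.sin(eps),
        )
        axes = ax

    if llg.T > 0:
        sigma_h = np.sqrt(
            2.0 * llg.alpha * constants.kB * llg.T
            / (constants.mu0**2 * llg.gamma_e * particle.MS * particle.volume * dt)
        )
    else:
        sigma_h = 0.0
    gfac = llg.gamma_e * constants.mu0 / (1.0 + llg.alpha**2)

    happ = _applied_field(protocol, n_steps)
    m0 = axes.copy()
    proj = _sllg_run(
        m0, axes, hk, happ, sigma_h, gfac, llg.alpha, dt,
        int(llg.seed) & 0x7FFFFFFF,
    )

    # fold the post-transient cycles onto one period; proj[i] pairs happ[i+1]
    n_avg = protocol.n_cycles - 1
    if n_avg < 1:
        n_avg, first = 1, 0
    else:
        first = n_steps
    folded = proj[first:first + n_avg * n_steps].reshape(n_avg, n_steps).mean(axis=0)
    H_cycle = happ[1:n_steps + 1]
    H = np.concatenate([H_cycle, H_cycle[:1]])
    M = np.concatenate([folded, folded[:1]]) * particle.MS
    area = loop_area(H, M, constants)
    sar = area * protocol.f / particle.rho * 1e-3
    return HysteresisLoop(H=H, M=M, area=area, sar=sar, f=protocol.f)


def sllg_equilibrium_sample(
    particle: ParticleSpec,
    llg: LLGParams,
    n_samples: int,
    stride: int,
    n_burn: int = 50_000,
    axes: np.ndarray | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> np.ndarray:
    """Zero-field equilibrium snapshots of the easy-axis projection m.n.

    Runs the stochastic LLG at H = 0 and temperature ``llg.T``, records
    all particles every ``stride`` steps after ``n_burn`` equilibration
    steps.  At equilibrium m.n is Boltzmann-distributed,
    p(x) proportional to exp(sigma x^2) with sigma = K V/(kB T), which is
    the standard check of the thermal-field calibration.  Returns an
    (n_samples, n_particles) array.
    """
    from .scenarios import random_axes

    if llg.T <= 0:
        raise ValueError("equilibrium sampling needs T > 0")
    if llg.dt is None:
        raise ValueError("equilibrium sampling needs an explicit dt")
    if axes is None:
        axes = random_axes(llg.n_particles, llg.seed)
    axes = np.ascontiguousarray(np.asarray(axes, dtype=float))
    hk = particle.anisotropy_field(constants)
    sigma_h = np.sqrt(
        2.0 * llg.alpha * constants.kB * llg.T
        / (constants.mu0**2 * llg.gamma_e * particle.MS * particle.volume * llg.dt)
    )
    gfac = llg.gamma_e * constants.mu0 / (1.0 + llg.alpha**2)
    m0 = axes.copy()
    return _sllg_sample_axis_projection(
        m0, axes, hk, sigma_h, gfac, llg.alpha, llg.dt,
        n_burn, n_samples, stride, int(llg.seed) & 0x7FFFFFFF,
    )


def sar_sweep(
    particle: ParticleSpec,
    f: float,
    Hmax_list: Sequence[float],
    llg: LLGParams | None = None,
    psi_or_ensemble: Union[float, str, np.ndarray] = "random",
    n_steps_per_cycle: int = 2000,
    n_cycles: int = 3,
    waveform: str = "sinusoidal",
    constants: PhysicalConstants = CONSTANTS,
) -> pd.DataFrame:
    """SAR vs field amplitude, with the anisotropy-normalised columns.

    With ``llg=None`` the loops are the T = 0 quasistatic Stoner-
    Wohlfarth limit; otherwise the stochastic LLG dynamics at ``llg.T``.
    Emits one row per amplitude: Hmax (A/m and mT), loop area (J/m^3),
    SAR (W/g), Hmax/H_K and the normalised loss area/(2K), which equals
    SAR/(2 K f / rho) and is bounded by 1 for aligned axes.
    """
    hlist = np.asarray(Hmax_list, dtype=float)
    if np.any(np.diff(hlist) <= 0):
        raise ValueError("Hmax_list must be strictly increasing")
    hk = particle.anisotropy_field(constants)
    rows = []
    for hmax in hlist:
        if hmax == 0.0:
            area, sar = 0.0, 0.0
        else:
            proto = FieldProtocol(
                Hmax=hmax, f=f, waveform=waveform,
                n_cycles=n_cycles, n_steps_per_cycle=n_steps_per_cycle,
            )
            if llg is None:
                lp = sw_quasistatic_loop(particle, psi_or_ensemble, proto, constants)
            else:
                ax = None if isinstance(psi_or_ensemble, str) else np.asarray(psi_or_ensemble)
                if ax is not None and (ax.ndim != 2 or ax.shape[1] != 3):
                    raise ValueError("sLLG sweep needs (n,3) axes or 'random'")
                lp = sllg_simulate(particle, proto, llg, axes=ax, constants=constants)
            area, sar = lp.area, lp.sar
        rows.append(
            {
                "Hmax_A_per_m": hmax,
                "Hmax_mT": hmax * constants.mu0 * 1e3,
                "area_J_per_m3": area,
                "sar_W_per_g": sar,
                "hmax_over_HK": hmax / hk,
                "sar_over_2Kf": area / (2.0 * particle.K),
            }
        )
    return pd.DataFrame(rows)
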