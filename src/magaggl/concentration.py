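"""Concentration limit of the dilute (non-interacting) assumption.

For a random dispersion of monodisperse spheres at volume fraction c the
mean nearest-neighbour centre distance follows the Tewari-Gokhale
approximation; equating it to the diffusion distance <x> of a particle
at its agglomeration threshold gives the volume fraction c_aggl above
which neighbours already sit inside the dipolar capture radius and the
timescale argument stops applying.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import NoSolutionError
from .params import CONSTANTS, Medium, ParticleSpec, PhysicalConstants
from .relaxation import diffusion_distance
from .thresholds import find_d_aggl

__all__ = ["nearest_neighbor_distance", "find_c_aggl", "concentration_report"]

#: maximum meaningful volume fraction (random close packing of spheres)
C_MAX = 0.74


def nearest_neighbor_distance(particle: ParticleSpec, c: float) -> float:
    """Mean nearest-neighbour centre distance in a random monodisperse
    dispersion at volume fraction ``c``.

    l_NN = (d + 2 tnm) * 0.4465 c^(-1/3) * (1 + 1.02625 c^0.6423);
    linear in the coated diameter and strictly decreasing in c over the
    physical range.
    """
    if not (0.0 < c < 1.0):
        raise ValueError(f"volume fraction must be in (0, 1), got {c}")
    d_out = particle.d + 2.0 * particle.tnm
    return d_out * 0.4465 / c ** (1.0 / 3.0) * (1.0 + 1.02625 * c**0.6423)


def find_c_aggl(
    particle: ParticleSpec,
    medium: Medium,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Threshold volume fraction (in %) at which l_NN equals the dipolar
    capture distance <x> of the particle.

    The particle is expected to sit at its agglomeration threshold size;
    <x> uses the bare magnetic size (the coating enters only through the
    coated diameter in l_NN).  Bracketed root search in c; raises
    ``NoSolutionError`` when <x> is below l_NN even at close packing.
    """
    x = diffusion_distance(particle, medium, constants)

    def g(c: float) -> float:
        return nearest_neighbor_distance(particle, c) - x

    lo, hi = 1e-8, C_MAX
    if g(hi) > 0.0:
        raise NoSolutionError(
            f"<x> = {x * 1e9:.1f} nm below the nearest-neighbour distance "
            f"even at c = {C_MAX} (l_NN = {nearest_neighbor_distance(particle, hi) * 1e9:.1f} nm)"
        )
    if g(lo) < 0.0:
        raise NoSolutionError("<x> exceeds l_NN at the dilute end of the bracket")
    c = brentq(g, lo, hi, rtol=1e-12)
    return c * 100.0


def concentration_report(
    K_list: Sequence[float],
    tnm_list: Sequence[float],
    MS: float,
    medium: Medium,
    constants: PhysicalConstants = CONSTANTS,
) -> pd.DataFrame:
    """c_aggl grid over anisotropy and coating thickness.

    For each K the threshold diameter d_aggl is found for the bare
    particle, then the concentration threshold is evaluated with each
    coating thickness entering the nearest-neighbour distance.  One row
    per (K, tnm): K, tnm_nm, d_aggl_nm, x_nm, c_aggl_percent.
    """
    rows = []
    for K in K_list:
        res = find_d_aggl(K, MS, medium, constants=constants)
        for tnm in tnm_list:
            p = ParticleSpec(d=res.d_aggl, K=K, MS=MS, tnm=tnm)
            x = diffusion_distance(p, medium, constants)
            rows.append(
                {
                    "K_kJ_per_m3": K / 1e3,
                    "tnm_nm": tnm * 1e9,
                    "d_aggl_nm": res.d_aggl_nm,
                    "x_nm": round(x * 1e9, 1),
                    "c_aggl_percent": find_c_aggl(p, medium, constants),
                }
            )
    return pd.DataFrame(rows)
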