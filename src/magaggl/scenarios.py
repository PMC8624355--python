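"""Built-in parameter scenarios and seeded ensembles.

Every analysis in the package runs off physical-parameter scenarios
(magnetite-like particles, cell-interior viscosities, clinical AC-field
protocols) rather than external data.  This module is the single source
of those parameter grids plus the seeded random-orientation ensembles
the hysteresis stage consumes, so the whole pipeline is reproducible
from a (name, seed) pair.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .params import FieldProtocol, LLGParams, Medium, ParticleSpec

__all__ = ["ScenarioSet", "builtin_scenarios", "random_axes", "perturb_grid"]

#: magnetite-like reference values used across the scenario catalogue
MS_REF = 4.8e5  # A/m
ETA_CELL = 0.00235  # kg/(m s), nm-scale effective cell-interior viscosity
ETA_WATER = 0.001
ETA_HELA_MACRO = 0.044

#: threshold diameters (m) of the reference anisotropy cases, used by the
#: dynamic-loop scenarios; regenerate with thresholds.table1_report
_D_AGGL = {8e3: 24.8e-9, 11e3: 22.0e-9, 15e3: 19.5e-9}


@dataclass(frozen=True)
class ScenarioSet:
    """A named, self-contained parameter scenario."""

    name: str
    particles: tuple[ParticleSpec, ...]
    medium: Medium
    protocols: tuple[FieldProtocol, ...] = ()
    llg: LLGParams | None = None
    seed: int = 0
    d_grid: np.ndarray | None = field(default=None, compare=False)
    description: str = ""


def builtin_scenarios(seed: int = 0) -> dict[str, ScenarioSet]:
    """Catalogue of the scenarios behind every figure and table of the
    reference analysis; regeneration from the same seed is bit-identical."""
    medium = Medium(T=300.0, eta=ETA_CELL)
    table1_particles = tuple(
        ParticleSpec(d=_D_AGGL[K], K=K, MS=MS_REF) for K in (8e3, 11e3, 15e3)
    )
    d_grid = np.linspace(5e-9, 50e-9, 451)
    cat = {}

    cat["table1"] = ScenarioSet(
        name="table1",
        particles=table1_particles,
        medium=medium,
        seed=seed,
        description="K = 8/11/15 kJ/m^3 threshold comparison at T = 300 K",
    )
    cat["fig1_profiles"] = ScenarioSet(
        name="fig1_profiles",
        particles=table1_particles,
        medium=medium,
        seed=seed,
        d_grid=d_grid,
        description="relaxation-time profiles vs diameter for the three K",
    )
    cat["fig2_coating"] = ScenarioSet(
        name="fig2_coating",
        particles=tuple(
            ParticleSpec(d=_D_AGGL[11e3], K=11e3, MS=MS_REF, tnm=t)
            for t in (0.0, 5e-9, 20e-9)
        ),
        medium=medium,
        seed=seed,
        d_grid=d_grid,
        description="coating-thickness sensitivity, K = 11 kJ/m^3",
    )
    cat["fig2_viscosity"] = ScenarioSet(
        name="fig2_viscosity",
        particles=(ParticleSpec(d=_D_AGGL[11e3], K=11e3, MS=MS_REF),),
        medium=medium,
        seed=seed,
        d_grid=d_grid,
        description=(
            "viscosity sensitivity, K = 11 kJ/m^3; eta in "
            f"{{{ETA_WATER}, {ETA_CELL}, {ETA_HELA_MACRO}}} kg/(m s)"
        ),
    )
    cat["fig3_sw"] = ScenarioSet(
        name="fig3_sw",
        particles=(
            ParticleSpec(d=20e-9, K=10e3, MS=480e3),
            ParticleSpec(d=20e-9, K=20e3, MS=480e3),
        ),
        medium=medium,
        protocols=(
            FieldProtocol(Hmax=25e-3 / 1.256e-6, f=765e3, n_steps_per_cycle=2000),
        ),
        llg=LLGParams(T=0.0, seed=seed),
        seed=seed,
        description="T = 0 Stoner-Wohlfarth loops and SAR collapse, d = 20 nm",
    )
    cat["fig4_fig5_loops"] = ScenarioSet(
        name="fig4_fig5_loops",
        particles=table1_particles,
        medium=medium,
        protocols=tuple(
            FieldProtocol(Hmax=h_mT * 1e-3 / 1.256e-6, f=f, n_steps_per_cycle=2000)
            for f in (205e3, 765e3)
            for h_mT in (5.0, 15.0, 30.0)
        ),
        llg=LLGParams(T=300.0, seed=seed, n_particles=100),
        seed=seed,
        description="dynamic loops and SAR of the threshold-sized particles",
    )
    cat["fig6_concentration"] = ScenarioSet(
        name="fig6_concentration",
        particles=tuple(
            ParticleSpec(d=_D_AGGL[K], K=K, MS=MS_REF, tnm=t)
            for K in (8e3, 11e3, 15e3)
            for t in (0.0, 5e-9, 10e-9, 20e-9)
        ),
        medium=medium,
        seed=seed,
        description="concentration validity threshold vs coating thickness",
    )
    return cat


def get_scenario(name: str, seed: int = 0) -> ScenarioSet:
    """Look one scenario up by name; raises ``KeyError`` with the list of
    known names otherwise."""
    cat = builtin_scenarios(seed)
    if name not in cat:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(cat)}")
    return cat[name]


def random_axes(n: int, seed: int) -> np.ndarray:
    """``n`` unit vectors uniform on the sphere from a counter-based
    (Philox) generator, so ensembles reproduce across platforms."""
    if n < 1:
        raise ValueError("need at least one axis")
    rng = np.random.Generator(np.random.Philox(seed))
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def perturb_grid(base: ScenarioSet, parameter: str, values) -> list[ScenarioSet]:
    """One scenario per value with a single field path changed.

    ``parameter`` is a dotted path: ``particle.<field>`` applies to every
    particle (e.g. ``particle.tnm``), ``medium.<field>`` to the medium,
    ``llg.<field>`` to the integrator settings.
    """
    try:
        scope, name = parameter.split(".", 1)
    except ValueError:
        raise KeyError(f"parameter path {parameter!r} must look like 'scope.field'")
    out = []
    for v in values:
        if scope == "particle":
            if not any(f.name == name for f in dataclasses.fields(ParticleSpec)):
                raise KeyError(f"ParticleSpec has no field {name!r}")
            repl = dataclasses.replace(
                base,
                particles=tuple(dataclasses.replace(p, **{name: v}) for p in base.particles),
            )
        elif scope == "medium":
            if not any(f.name == name for f in dataclasses.fields(Medium)):
                raise KeyError(f"Medium has no field {name!r}")
            repl = dataclasses.replace(base, medium=dataclasses.replace(base.medium, **{name: v}))
        elif scope == "llg":
            if base.llg is None or not any(f.name == name for f in dataclasses.fields(LLGParams)):
                raise KeyError(f"LLGParams has no field {name!r}")
            repl = dataclasses.replace(base, llg=dataclasses.replace(base.llg, **{name: v}))
        else:
            raise KeyError(f"unknown parameter scope {scope!r}")
        out.append(dataclasses.replace(repl, name=f"{base.name}[{parameter}={v}]"))
    return out
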