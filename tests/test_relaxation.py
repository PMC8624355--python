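"""Closed-form relaxation quantities: frozen values, scaling laws and the
vectorised-profile consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magaggl import (
    CONSTANTS,
    Medium,
    ParticleSpec,
    blocking_size,
    brown_rotation_time,
    diffusion_distance,
    diffusion_time,
    dipolar_thermal_ratio,
    neel_time,
    relaxation_profile,
)
from magaggl.exceptions import ContactViolationError

from .conftest import MS_REF

# frozen expected values, computed by independent high-precision evaluation
# of the closed forms (sympy/mpmath cross-check at 50 digits)
D22 = 22e-9


class TestDipolarRatio:
    def test_touching_22nm_particles(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        gamma = dipolar_thermal_ratio(p, medium, lcc=D22)
        assert gamma == pytest.approx(32.46, rel=1e-3)

    def test_unity_near_7nm(self, medium):
        d = 7e-9
        p = ParticleSpec(d=d, K=11e3, MS=MS_REF)
        assert dipolar_thermal_ratio(p, medium, lcc=d) == pytest.approx(1.0, rel=0.05)

    def test_zero_moment_gives_zero(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=0.0)
        assert dipolar_thermal_ratio(p, medium, lcc=D22) == 0.0

    def test_contact_violation_raises(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        with pytest.raises(ContactViolationError):
            dipolar_thermal_ratio(p, medium, lcc=0.5 * D22)

    def test_cubic_decay_with_distance(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        g1 = dipolar_thermal_ratio(p, medium, lcc=D22)
        g2 = dipolar_thermal_ratio(p, medium, lcc=2 * D22)
        assert g1 / g2 == pytest.approx(8.0, rel=1e-12)


class TestNeelTime:
    def test_sigma_unity_closed_form(self, medium):
        # sigma = 1: tau_N = (sqrt(pi)/2) e tau0
        kBT = CONSTANTS.kB * medium.T
        d = (6.0 * kBT / (math.pi * 11e3)) ** (1 / 3)
        p = ParticleSpec(d=d, K=11e3, MS=MS_REF)
        assert neel_time(p, medium) == pytest.approx(
            math.sqrt(math.pi) / 2 * math.e * CONSTANTS.tau0, rel=1e-12
        )

    def test_22nm_frozen_value(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        # sigma = 14.81, tau_N = 6.2e-4 s at tau0 = 1 ns
        assert neel_time(p, medium) == pytest.approx(6.2e-4, rel=0.02)

    def test_increases_with_anisotropy(self, medium):
        t8 = neel_time(ParticleSpec(d=D22, K=8e3, MS=MS_REF), medium)
        t15 = neel_time(ParticleSpec(d=D22, K=15e3, MS=MS_REF), medium)
        assert t15 > t8

    def test_low_barrier_warns(self, medium):
        p = ParticleSpec(d=8e-9, K=8e3, MS=MS_REF)  # sigma ~ 0.5
        with pytest.warns(UserWarning, match="sigma"):
            neel_time(p, medium)


class TestDiffusionAndRotation:
    def test_diffusion_distance_22nm(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        assert diffusion_distance(p, medium) == pytest.approx(70.18e-9, rel=1e-3)

    def test_diffusion_distance_zero_moment(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=0.0)
        assert diffusion_distance(p, medium) == 0.0

    def test_gamma_at_x_is_unity(self, medium):
        """Definitional identity: the dipolar ratio evaluated at the
        capture distance <x> equals 1 to machine precision."""
        for d, ms in [(15e-9, 3e5), (D22, MS_REF), (40e-9, 6e5)]:
            p = ParticleSpec(d=d, K=11e3, MS=ms)
            x = diffusion_distance(p, medium)
            assert dipolar_thermal_ratio(p, medium, lcc=x) == pytest.approx(1.0, rel=1e-12)

    def test_diffusion_time_22nm(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        assert diffusion_time(p, medium) == pytest.approx(5.8e-4, rel=0.02)

    def test_diffusion_time_linear_in_viscosity(self):
        p = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        t1 = diffusion_time(p, Medium(T=300, eta=0.001))
        t2 = diffusion_time(p, Medium(T=300, eta=0.002))
        assert t2 / t1 == pytest.approx(2.0, rel=1e-12)

    def test_diffusion_time_linear_in_hydrodynamic_radius(self, medium):
        bare = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        coated = ParticleSpec(d=D22, K=11e3, MS=MS_REF, tnm=5e-9)
        assert diffusion_time(coated, medium) / diffusion_time(bare, medium) == pytest.approx(
            16.0 / 11.0, rel=1e-12
        )

    def test_rotation_time_22nm(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        assert brown_rotation_time(p, medium) == pytest.approx(9.5e-6, rel=0.02)

    def test_rotation_time_unit_construction(self):
        med = Medium(T=300, eta=0.001)
        v_hyd = CONSTANTS.kB * med.T / (3 * med.eta)
        r = (v_hyd * 3 / (4 * math.pi)) ** (1 / 3)
        p = ParticleSpec(d=2 * r, K=1e3, MS=MS_REF)
        assert brown_rotation_time(p, med) == pytest.approx(1.0, rel=1e-12)

    def test_rotation_slower_than_diffusion_in_profile_range(self, medium):
        """Across the sizes of interest the particle rotates much faster
        than it translates over the capture distance."""
        for d in np.linspace(10e-9, 40e-9, 16):
            p = ParticleSpec(d=d, K=11e3, MS=MS_REF)
            assert brown_rotation_time(p, medium) < diffusion_time(p, medium)


class TestBlockingSize:
    def test_reference_diameters(self):
        assert blocking_size(11e3, 300.0) * 1e9 == pytest.approx(26.2, abs=0.05)
        assert blocking_size(15e3, 300.0) * 1e9 == pytest.approx(23.6, abs=0.05)

    def test_inverse_cube_root_scaling(self):
        assert blocking_size(8e3, 300.0) / blocking_size(64e3, 300.0) == pytest.approx(
            2.0, rel=1e-12
        )

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            blocking_size(-1.0, 300.0)


class TestProfile:
    def test_single_point_matches_scalar_ops(self, medium):
        p = ParticleSpec(d=D22, K=11e3, MS=MS_REF)
        prof = relaxation_profile(11e3, MS_REF, 0.0, medium, d_grid=np.array([D22]))
        assert prof.tau_N[0] == pytest.approx(neel_time(p, medium), rel=1e-14)
        assert prof.tau_B[0] == pytest.approx(brown_rotation_time(p, medium), rel=1e-14)
        assert prof.tau_diff[0] == pytest.approx(diffusion_time(p, medium), rel=1e-14)
        assert prof.x_diff[0] == pytest.approx(diffusion_distance(p, medium), rel=1e-14)
        assert prof.gamma_ratio[0] == pytest.approx(
            dipolar_thermal_ratio(p, medium, lcc=D22), rel=1e-14
        )

    def test_vectorised_equals_scalar_elementwise(self, medium):
        grid = np.linspace(12e-9, 40e-9, 29)
        prof = relaxation_profile(8e3, MS_REF, 5e-9, medium, d_grid=grid)
        for i, d in enumerate(grid):
            p = ParticleSpec(d=d, K=8e3, MS=MS_REF, tnm=5e-9)
            assert prof.tau_N[i] == pytest.approx(neel_time(p, medium), rel=1e-13)
            assert prof.tau_diff[i] == pytest.approx(diffusion_time(p, medium), rel=1e-13)

    def test_monotonicity_of_timescales(self, medium):
        grid = np.linspace(12e-9, 45e-9, 100)
        prof = relaxation_profile(11e3, MS_REF, 0.0, medium, d_grid=grid)
        assert np.all(np.diff(prof.tau_N) > 0)
        assert np.all(np.diff(prof.tau_B) > 0)
        assert np.all(np.diff(prof.tau_diff) > 0)
        assert np.all(prof.tau_N > 0) and np.all(np.isfinite(prof.tau_N))

    def test_gamma_column_independent_of_K(self, medium):
        grid = np.linspace(10e-9, 40e-9, 31)
        g8 = relaxation_profile(8e3, MS_REF, 0.0, medium, d_grid=grid).gamma_ratio
        g15 = relaxation_profile(15e3, MS_REF, 0.0, medium, d_grid=grid).gamma_ratio
        np.testing.assert_allclose(g8, g15, rtol=1e-15)

    def test_csv_roundtrip(self, medium, tmp_path):
        import pandas as pd

        prof = relaxation_profile(11e3, MS_REF, 0.0, medium,
                                  d_grid=np.linspace(15e-9, 30e-9, 4))
        path = tmp_path / "profile.csv"
        prof.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["d_nm", "tau_N_s", "tau_B_s", "tau_diff_s",
                                    "gamma", "x_diff_nm"]
        np.testing.assert_allclose(df.tau_N_s.to_numpy(), prof.tau_N, rtol=1e-10)

    def test_rejects_unsorted_grid(self, medium):
        with pytest.raises(ValueError):
            relaxation_profile(11e3, MS_REF, 0.0, medium,
                               d_grid=np.array([20e-9, 15e-9]))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    d=st.floats(min_value=10e-9, max_value=50e-9),
    K=st.floats(min_value=5e3, max_value=30e3),
    ms=st.floats(min_value=1e5, max_value=6e5),
    eta=st.floats(min_value=5e-4, max_value=0.05),
)
def test_capture_distance_identity_property(d, K, ms, eta):
    """Gamma(lcc=<x>) = 1 for any physically sensible parameter set."""
    p = ParticleSpec(d=d, K=K, MS=ms)
    med = Medium(T=300.0, eta=eta)
    x = diffusion_distance(p, med)
    if x >= d:  # lcc must respect contact
        assert dipolar_thermal_ratio(p, med, lcc=x) == pytest.approx(1.0, rel=1e-11)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    d=st.floats(min_value=12e-9, max_value=40e-9),
    K=st.floats(min_value=5e3, max_value=30e3),
    scale=st.floats(min_value=1.05, max_value=2.0),
)
def test_neel_time_monotone_in_barrier(d, K, scale):
    med = Medium()
    p1 = ParticleSpec(d=d, K=K, MS=MS_REF)
    p2 = ParticleSpec(d=d * scale**0.34, K=K, MS=MS_REF)  # larger sigma
    assert neel_time(p2, med) > neel_time(p1, med)
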