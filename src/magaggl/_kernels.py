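"""Numba kernels: Stoner-Wohlfarth branch tracking and the stochastic
Heun integrator for the macrospin Landau-Lifshitz-Gilbert equation.

Reduced units in the SW tracker: energy per KV is
eps(theta) = sin^2(theta - psi) - 2 h cos(theta) with h = H/H_K and
theta the moment angle from the field axis.  The LLG kernel works in SI
(fields in A/m).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sw_descend(theta: float, psi: float, h: float) -> float:
    """Follow the local energy minimum reachable downhill from ``theta``.

    Safeguarded Newton on eps'(theta) = 0; when the current stationary
    point is a maximum (branch lost its stability) a small deterministic
    kick restarts the descent into the adjacent basin — that jump is the
    irreversible switching event.
    """
    for _ in range(1000):
        g = np.sin(2.0 * (theta - psi)) + 2.0 * h * np.sin(theta)
        gg = 2.0 * np.cos(2.0 * (theta - psi)) + 2.0 * h * np.cos(theta)
        if abs(g) < 1e-13:
            if gg > 1e-10:
                return theta
            theta += 1e-5  # stationary but unstable: kick off the ridge
            continue
        if gg > 1e-9:
            step = -g / gg
            if step > 0.2:
                step = 0.2
            elif step < -0.2:
                step = -0.2
            theta += step
        else:
            # outside a convex basin: slide downhill with a bounded step
            theta += -0.05 if g > 0.0 else 0.05
    return theta


@njit(cache=True)
def _sw_branch(psi: float, h_path: np.ndarray) -> np.ndarray:
    """Field-projection m_parallel = cos(theta) along a quasistatic field
    path for a single easy-axis angle ``psi``."""
    m = np.empty(h_path.size)
    theta = _sw_descend(1e-8, psi, h_path[0])
    for i in range(h_path.size):
        theta = _sw_descend(theta, psi, h_path[i])
        m[i] = np.cos(theta)
    return m


@njit(cache=True)
def _sw_ensemble(psis: np.ndarray, weights: np.ndarray, h_path: np.ndarray) -> np.ndarray:
    """Weighted orientation average of SW branches."""
    acc = np.zeros(h_path.size)
    wsum = 0.0
    for j in range(psis.size):
        mj = _sw_branch(psis[j], h_path)
        w = weights[j]
        wsum += w
        for i in range(h_path.size):
            acc[i] += w * mj[i]
    return acc / wsum


@njit(cache=True, inline="always")
def _llg_rhs(mx, my, mz, hx, hy, hz, gfac, alpha):
    """dm/dt = -gfac [m x H + alpha m x (m x H)], gfac = gamma mu0/(1+a^2)."""
    cx = my * hz - mz * hy
    cy = mz * hx - mx * hz
    cz = mx * hy - my * hx
    dx = my * cz - mz * cy
    dy = mz * cx - mx * cz
    dz = mx * cy - my * cx
    return (-gfac * (cx + alpha * dx),
            -gfac * (cy + alpha * dy),
            -gfac * (cz + alpha * dz))


@njit(cache=True, fastmath=True)
def _sllg_run(m, axes, hk, happ, sigma_h, gfac, alpha, dt, seed):
    """Integrate the ensemble through the applied-field sequence.

    Parameters: ``m`` (n,3) initial unit moments (updated in place),
    ``axes`` (n,3) unit easy axes, ``hk`` anisotropy field (A/m),
    ``happ`` (nsteps+1,) applied field along z at the step boundaries,
    ``sigma_h`` per-component thermal field std-dev (A/m, already
    includes the 1/sqrt(dt)), ``gfac`` = gamma mu0/(1+alpha^2).

    Returns the ensemble-mean field-axis projection after every step,
    aligned with ``happ[1:]``.  Stochastic Heun (Stratonovich): the
    thermal field is held fixed within a step and enters predictor and
    corrector alike; moments are renormalised after every step.
    """
    n = m.shape[0]
    nsteps = happ.size - 1
    out = np.empty(nsteps)
    np.random.seed(seed)
    for it in range(nsteps):
        h0 = happ[it]
        h1 = happ[it + 1]
        acc = 0.0
        for p in range(n):
            mx = m[p, 0]
            my = m[p, 1]
            mz = m[p, 2]
            nx = axes[p, 0]
            ny = axes[p, 1]
            nz = axes[p, 2]
            tx = ty = tz = 0.0
            if sigma_h > 0.0:
                tx = sigma_h * np.random.standard_normal()
                ty = sigma_h * np.random.standard_normal()
                tz = sigma_h * np.random.standard_normal()
            dot = mx * nx + my * ny + mz * nz
            hx = hk * dot * nx + tx
            hy = hk * dot * ny + ty
            hz = hk * dot * nz + tz + h0
            fx, fy, fz = _llg_rhs(mx, my, mz, hx, hy, hz, gfac, alpha)
            px = mx + fx * dt
            py = my + fy * dt
            pz = mz + fz * dt
            dot = px * nx + py * ny + pz * nz
            hx = hk * dot * nx + tx
            hy = hk * dot * ny + ty
            hz = hk * dot * nz + tz + h1
            qx, qy, qz = _llg_rhs(px, py, pz, hx, hy, hz, gfac, alpha)
            mx += 0.5 * dt * (fx + qx)
            my += 0.5 * dt * (fy + qy)
            mz += 0.5 * dt * (fz + qz)
            inv = 1.0 / np.sqrt(mx * mx + my * my + mz * mz)
            mx *= inv
            my *= inv
            mz *= inv
            m[p, 0] = mx
            m[p, 1] = my
            m[p, 2] = mz
            acc += mz
        out[it] = acc / n
    return out


@njit(cache=True, fastmath=True)
def _sllg_sample_axis_projection(m, axes, hk, sigma_h, gfac, alpha, dt,
                                 n_burn, n_samples, stride, seed):
    """Zero-field equilibrium sampler: returns (n_samples, n) snapshots of
    the easy-axis projection m.n taken every ``stride`` steps after
    ``n_burn`` equilibration steps."""
    n = m.shape[0]
    out = np.empty((n_samples, n))
    np.random.seed(seed)
    total = n_burn + n_samples * stride
    k = 0
    for it in range(total):
        for p in range(n):
            mx = m[p, 0]
            my = m[p, 1]
            mz = m[p, 2]
            nx = axes[p, 0]
            ny = axes[p, 1]
            nz = axes[p, 2]
            tx = sigma_h * np.random.standard_normal()
            ty = sigma_h * np.random.standard_normal()
            tz = sigma_h * np.random.standard_normal()
            dot = mx * nx + my * ny + mz * nz
            hx = hk * dot * nx + tx
            hy = hk * dot * ny + ty
            hz = hk * dot * nz + tz
            fx, fy, fz = _llg_rhs(mx, my, mz, hx, hy, hz, gfac, alpha)
            px = mx + fx * dt
            py = my + fy * dt
            pz = mz + fz * dt
            dot = px * nx + py * ny + pz * nz
            hx = hk * dot * nx + tx
            hy = hk * dot * ny + ty
            hz = hk * dot * nz + tz
            qx, qy, qz = _llg_rhs(px, py, pz, hx, hy, hz, gfac, alpha)
            mx += 0.5 * dt * (fx + qx)
            my += 0.5 * dt * (fy + qy)
            mz += 0.5 * dt * (fz + qz)
            inv = 1.0 / np.sqrt(mx * mx + my * my + mz * mz)
            m[p, 0] = mx * inv
            m[p, 1] = my * inv
            m[p, 2] = mz * inv
        if it >= n_burn and (it - n_burn) % stride == stride - 1:
            for p in range(n):
                out[k, p] = (m[p, 0] * axes[p, 0] + m[p, 1] * axes[p, 1]
                             + m[p, 2] * axes[p, 2])
            k += 1
    return out
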