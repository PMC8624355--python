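# magaggl

Anisotropy-aware size thresholds for the *magnetic* agglomeration of
single-domain nanoparticles, and the hyperthermia performance of
particles at that threshold.

## The problem

Magnetic nanoparticles for biomedical use (hyperthermia, drug release)
should stay dispersed. The usual colloid-physics estimate of
agglomeration likelihood compares the dipole–dipole energy of two
touching, parallel-aligned moments to the thermal energy,

Γ = μ₀(M_S V)² / (2π l_cc³ k_B T),

which for magnetite-like particles (M_S = 4.8×10⁵ A/m) predicts
agglomeration above only ~7 nm. But Γ ignores the magnetic anisotropy
constant K: a particle whose moment flips internally (Néel relaxation)
faster than the particle can translate or rotate towards a neighbour
never presents a stable dipole to bind to. `magaggl` implements the
timescale comparison that repairs this:

- Néel time (high-barrier uniaxial asymptote):
  τ_N = (√π/2) τ₀ e^σ σ^(−1/2), σ = K V / k_B T
- translational diffusion time over the dipolar capture distance:
  τ_diff = ⟨x⟩² 6π η R_hyd / k_B T, with
  ⟨x⟩ = [μ₀(M_S V)²/(2π k_B T)]^(1/3) (the distance where Γ = 1)
- Brownian rotation time: τ_B = 3 η V_hyd / k_B T

The agglomeration threshold d_aggl is the diameter where τ_N overtakes
both mechanical timescales (in practice τ_diff, the slower one). The
package also evaluates the ZFC/FC superparamagnetism criterion
T_B = K V / 25 k_B for comparison, simulates the dynamic hysteresis of
threshold-sized particles — a T = 0 Stoner–Wohlfarth quasistatic solver
and a finite-temperature stochastic Landau–Lifshitz–Gilbert (sLLG)
macrospin integrator — computes SAR = A·f in W/g, and converts the
capture-distance criterion into a sample-concentration limit c_aggl via
the Tewari–Gokhale nearest-neighbour distance for random dispersions.

## Worked example

```python
import magaggl as mg

med = mg.Medium(T=300.0, eta=0.00235)           # nm-scale cell interior
df = mg.table1_report([8e3, 11e3, 15e3], 4.8e5, med)
print(df.to_string(index=False))
print("mean d_TB - d_aggl gap:", df.attrs["mean_gap_nm"], "nm")
print("energy-ratio threshold:", round(mg.find_d_gamma(4.8e5, med)*1e9, 1), "nm")

res = mg.find_d_aggl(11e3, 4.8e5, med)
p = mg.ParticleSpec(d=res.d_aggl, K=11e3, MS=4.8e5)
print("c_aggl (bare, K=11):", round(mg.find_c_aggl(p, med), 2), "%")
```

prints

```
 K_kJ_per_m3  d_aggl_nm  d_TB_nm binding_mechanism
         8.0       24.8     29.1         diffusion
        11.0       22.0     26.2         diffusion
        15.0       19.5     23.6         diffusion
mean d_TB - d_aggl gap: 4.2 nm
energy-ratio threshold: 6.9 nm
c_aggl (bare, K=11): 0.3 %
```

Reading: with usual magnetite anisotropies, purely magnetic clustering
only becomes likely at 20–25 nm — far above the 7 nm the bare energy
ratio suggests, and a few nm below what the blocking-temperature
criterion would indicate. The binding competition is always Néel vs
translational diffusion (rotation is faster than translation for all
these sizes). The dilute-limit arguments hold up to a volume fraction of
only ~0.3% for bare particles; a nonmagnetic coating of a few nm pushes
c_aggl into the 1–10% range (see `mg.concentration_report`).

Hysteresis and heating:

```python
import numpy as np
p = mg.ParticleSpec(d=22e-9, K=11e3, MS=4.8e5)
hk = p.anisotropy_field()
llg = mg.LLGParams(alpha=0.1, T=300.0, seed=42, n_particles=100)
sweep = mg.sar_sweep(p, 765e3, np.array([0.3, 0.6, 1.0]) * hk, llg=llg,
                     n_steps_per_cycle=100_000)
```

yields SAR in the hundreds-to-thousands of W/g once H_max passes about
half the anisotropy field H_K = 2K/μ₀M_S; at T = 0 (`llg=None`) the
normalised curves SAR/(2Kf) vs H_max/H_K for different K collapse onto
a single curve bounded by 1.

A thin CLI mirrors these stages: `magaggl thresholds`,
`magaggl profile`, `magaggl hysteresis`, `magaggl concentration`,
`magaggl scenarios list/dump` (lab units: nm, kJ/m³, mT, kHz).

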