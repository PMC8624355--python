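# Methods

## Model

A monodisperse ensemble of spherical, single-domain, uniaxial
nanoparticles (magnetic core diameter d, anisotropy constant K,
saturation magnetisation M_S) in a Newtonian fluid (temperature T,
viscosity η), optionally carrying a nonmagnetic coating of thickness
t_nm that enters only the hydrodynamic radius R_hyd = d/2 + t_nm.
Magnetisation dynamics are treated in the macrospin approximation: one
rigid moment M_S·V per particle. Particles are non-interacting except
for the pairwise dipole estimate used in the agglomeration criterion.

### Agglomeration criterion

Magnetic binding requires the moment to be stable while two particles
approach and align, so the threshold diameter d_aggl solves

ln τ_N(d) = ln max(τ_diff(d), τ_B(d)),

with the Néel time in the high-barrier asymptote
τ_N = (√π/2) τ₀ e^σ σ^(−1/2) (σ = KV/k_BT), the diffusion time
τ_diff = ⟨x⟩²·6πη R_hyd/k_BT over the capture distance
⟨x⟩ = [μ₀(M_SV)²/(2π k_BT)]^(1/3) (the separation at which the
parallel-dipole energy equals k_BT), and the Brownian rotation time
τ_B = 3η V_hyd/k_BT. The **max** is deliberate: the moment must outlive
*both* mechanical processes for binding, so the slower one — always
translation here, since τ_B < τ_diff for these sizes and viscosities —
is the binding timescale. The root is found on log-ratios (the times
span ~10 orders of magnitude over the bracket) by a dense 512-point
pre-scan for the first sign change followed by Brent's method to
0.01 nm; taking the *first* crossing makes the reported threshold
conservative if multiple crossings ever occur.

Two standard alternatives are computed for comparison: the
anisotropy-blind energy ratio Γ(l_cc = d) = 1, solved in closed form
(d³ = 72 k_BT/π μ₀ M_S²), and the ZFC/FC blocking-size criterion,
inverting T_B = KV/25k_B at T_B = 300 K. The factor 25 (measurement
timescale ~100 s) is taken as given, not re-derived.

### Choice of τ₀ and the formula dialects

The attempt time τ₀ is physically between 10⁻¹² and 10⁻⁹ s and is a
genuine free parameter of the analysis. We fix τ₀ = 10⁻⁹ s, read the
printed Néel factor (KV/k_BT)^(1/2) as σ^(−1/2) (the standard
high-barrier asymptote), and take τ_diff literally as ⟨x⟩²/D with
D = k_BT/6πηR_hyd (no 1/6 mean-square-displacement factor). A
brute-force scan of all combinations (τ₀ decades × exponent sign ×
1/6 factor) against the reference threshold set {24.8, 22.0, 19.5} nm
shows this is the only combination that reproduces all three to
±0.05 nm, so these defaults are calibrated rather than independently
derived; τ₀ is configurable in `PhysicalConstants`.

### Constants

k_B = 1.380649×10⁻²³ J/K (SI exact); μ₀ = 1.256×10⁻⁶ T·m/A (the
rounded value customary in this literature — using the CODATA value
would shift thresholds by ≪0.1 nm); γ = 1.76×10¹¹ rad/(s·T);
ρ = 5180 kg/m³ (bulk magnetite) for the J/m³ → W/g conversion.

## Hysteresis solvers

### T = 0 quasistatic (Stoner–Wohlfarth)

Per easy-axis angle ψ the moment angle θ (from the field axis) tracks a
local minimum of the reduced energy ε(θ) = sin²(θ−ψ) − 2h cosθ,
h = H/H_K, H_K = 2K/μ₀M_S. The tracker is a safeguarded Newton
iteration on ε′ = 0 with a bounded downhill fallback; when the occupied
minimum turns unstable (ε′ = 0, ε″ ≤ 0, e.g. θ = 0 at ψ = 0 beyond
h = −1) a deterministic 10⁻⁵ rad kick restarts the descent into the
adjacent basin — that jump is the irreversible switching event, and its
location reproduces the astroid h_sw = (cos^{2/3}ψ + sin^{2/3}ψ)^{−3/2}.
The field path is two triangular cycles (the first absorbs the
initial-state transient); the loop area is μ₀|∮M dH| by trapezoidal
quadrature. Orientation averages use either user-supplied axes (equal
weights, e.g. seeded uniform-sphere samples) or a deterministic
256-node Gauss–Legendre quadrature uniform in cosψ ("random").
Saturated limits: area = 8K aligned, ≈1.98K for random axes (≈2K).

### Finite temperature (stochastic LLG)

dm/dt = −γμ₀/(1+α²)·[m×H_eff + α m×(m×H_eff)] with
H_eff = H_K(m·n)n + H(t)ẑ + H_th, integrated by the stochastic Heun
scheme (Stratonovich-consistent): the Gaussian thermal field is held
constant within a step, enters predictor and corrector alike, and has
per-component variance 2α k_BT/(μ₀²γ M_S V Δt) with the *bare* γ
(Brown's fluctuation–dissipation relation for this form of the
equation). Moments are renormalised each step (|m| drift ≤ 10⁻¹²).
The variance convention is validated by a Kolmogorov–Smirnov test of
the zero-field stationary distribution p(m·n) ∝ exp(σ(m·n)²) at α = 1,
where a misplaced (1+α²) factor would be a factor-2 error.

Defaults: α = 0.1 (damping is not experimentally pinned for these
particles; loop areas at 300 K change by tens of percent between
α = 0.05 and 1, which is why finite-T SAR values are reported as
orders of magnitude, not point predictions), sinusoidal drive,
n_particles = 100, 3 cycles (1 transient + 2 phase-averaged). The
timestep must satisfy γμ₀(H_K + H_max)Δt ≤ 0.25 (enforced;
~10 ps here). Easy axes are *fixed*: only the internal (Néel) channel
dissipates; physical-rotation (Brownian) heating and field-driven axis
reorientation are outside the model, as is any interparticle
interaction during heating.

Degenerate input: at T = 0 an axis exactly parallel to the field makes
m = n an exact zero-torque ridge that the noiseless integrator can
never leave, so deterministic runs tilt all axes by 10⁻⁶ rad (switching
field shifted by ~10⁻⁴ relative — far below the 2% oracle tolerance).

SAR = area·f/ρ, reported in W/g; the normalised column area/2K equals
SAR/(2Kf/ρ) and collapses T = 0 sweeps of different K when plotted
against H_max/H_K, with 1 as the aligned-ensemble bound.

## Concentration limit

For a random monodisperse dispersion at volume fraction c the mean
nearest-neighbour centre distance is the Tewari–Gokhale approximation
l_NN = (d + 2t_nm)·0.4465 c^(−1/3)·(1 + 1.02625 c^0.6423). Equating
l_NN to ⟨x⟩ of the threshold-sized particle (bare magnetic size in ⟨x⟩;
the coating only widens l_NN) and solving for c by Brent's method on
(10⁻⁸, 0.74) gives c_aggl, the volume fraction above which neighbours
already sit inside the capture radius. For K = 11 kJ/m³, t_nm = 0 this
evaluates to ≈0.30% (values near 0.2% circulate from rounded inputs;
we report the unrounded solution). A few nm of coating raises c_aggl
into the 1–10% range.

## Scenario generator

`scenarios.builtin_scenarios` encodes the study conditions directly:
K ∈ {8, 11, 15} kJ/m³ with M_S = 4.8×10⁵ A/m (deliberately the upper
magnetite value, overestimating the interaction so thresholds are
conservative), η ∈ {0.001 (water), 0.00235 (nm-scale cell interior),
0.044 (macroscopic HeLa)} kg/(m·s), t_nm ∈ {0, 5, 10, 20} nm, T = 300 K,
f ∈ {205, 765} kHz with μ₀H_max up to tens of mT, and the d = 20 nm /
M_S = 480 kA/m / K ∈ {10, 20} kJ/m³ pair for the T = 0 collapse. Random
easy axes come from a counter-based Philox generator (bit-reproducible
across platforms). What the generator does *not* emulate: size or
anisotropy polydispersity, K(T), M_S(d, T), interparticle interactions,
electrostatic/DLVO forces — so passing tests demonstrate internal
consistency of the ideal monodisperse model, not agreement with any
particular experimental sample.

## Problem sizes and numerical tolerances

Threshold roots: 0.01 nm absolute; reported at 0.1 nm. Quasistatic
loops: 2 000–20 000 field steps per cycle (discretisation enters the
area as one field step at the switching point, ≤0.2% at the sizes
used). sLLG checks run with 32–64 particles, 2–3 cycles and ~10 ps
steps; the T = 0 oracle comparisons use 50–100 kHz sweeps where the
dynamic switching delay is below the 2% tolerance. The equilibrium KS
test uses 64 particles × 200 snapshots taken every 20 ns (well beyond
the sub-ns correlation time at σ ≈ 2.4, α = 1). The acceptance script's
random-orientation loss uses 10⁴ sampled axes, where the
orientation-sampling standard error on area/K is ≈0.3%.

## Known limitations

- τ₀ is calibrated, not measured; thresholds shift by ~1–2 nm per
  decade of τ₀.
- The high-barrier Néel asymptote is extrapolated (with a warning)
  below σ = 1, where no accurate closed form exists.
- Finite-temperature SAR magnitudes depend on the unpinned damping α
  and on the waveform; only their scaling behaviour and order of
  magnitude are asserted.
- The blocking-size comparison inherits the fixed "25" of the ZFC/FC
  criterion; field-dependent T_B is not modelled.
- c_aggl treats the dispersion as static and monodisperse; it flags
  where the dilute argument stops applying, not where heating actually
  degrades.
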