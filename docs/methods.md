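# Methods

## Model

A grafted nanoparticle is a rigid spherical core of radius `R` (1–5 nm)
with `N_c` flexible bead–spring chains tethered to uniformly random points
on its surface. Each chain has `L` beads of diameter `σ = 0.65 nm` (one
bead per nucleotide; the ssDNA base-to-base distance), and the model works
at high screening (≥ 0.1 M salt), so there are no explicit charges.

Interactions, in reduced units (`ε_LJ = 1`, lengths in nm, `T* = ε/k_B`):

* **Excluded volume** — shifted-truncated Lennard-Jones
  `U(r) = U_LJ(r − r_s) − U_LJ(r_c − r_s)` for `r < r_c`, else 0.
  Bead–bead pairs use `r_s = 0` and the WCA cutoff `r_c = 2^{1/6}σ`
  (purely repulsive; bonded pairs included, the standard bead–spring
  convention). The core–bead pair uses `r_s = r_s_core` with
  `R = r_s_core + σ/2`; in attractive mode the cutoff extends to
  `r_s + 2.5σ` with well depth `ε_s`, which models a tunable
  chain–surface affinity (`ε_s = 0` recovers the reference system).
* **Bonds** — FENE springs, `U = −(k R₀²/2) ln(1 − r²/R₀²)` with
  `k = 30/σ²`, `R₀ = 1.5σ`, between consecutive beads and between each
  chain's first bead and its fixed anchor point.
* **Stiffness** — `U_lin(θ) = k_lin (1 + cos θ)` at every interior bead,
  `θ` the interior angle (θ = π is straight). `k_lin = 1` is the ssDNA
  setting.

## Sampling

The canonical ensemble at `T* = 1` is sampled with a Langevin thermostat
(BAOAB splitting, friction `γ = 1` in reduced time units), the core held
fixed at the origin. A Langevin scheme was chosen over a deterministic
Nosé–Hoover chain as the package's own design choice: it samples the same
ensemble, is unconditionally ergodic for these small systems, and makes
seeded bit-identical reruns trivial. `γ = 0` switches the thermostat off
and leaves plain velocity Verlet (used by the energy-conservation test).

The bead mass is unity and `dt = 0.0025` reduced time units by default;
with the stiff FENE+WCA bond (vibration period ≈ 0.14) this keeps the
measured kinetic temperature within 1% of `T*` (the run log records it and
flags deviations beyond 2%). Burn-in is 20% of the trajectory. Isolated
chains are integrated as independent replicas in one kernel; the
production runs behind the stiffness/scaling measurements use 16 replicas
× 4×10⁵ steps per chain length with 100 snapshots, chosen so the
bootstrap errors of `l_p` and `ν` are a few per mil and ~0.01
respectively. Seeds flow through `numpy.random.SeedSequence`, and anchor
placement uses one counter-based Philox stream per chain, so enlarging a
system does not perturb earlier draws.

## Hydrodynamic estimators

All solution properties are computed on **sphere unions** (core + beads,
or analytic fixtures).

* **Hydrodynamic radius.** `R_h ≈ C`, the electrostatic capacity of the
  equally shaped conductor (accurate to ≈1%; exact for spheres and, in
  fact, exact for prolate spheroids, where the capacity coincides with the
  Perrin translational radius). `C` is estimated by walk-on-spheres:
  walkers start uniformly on a launch sphere (centroid-centered, 1%
  inflated), step by the exact distance to the union, are absorbed within
  a skin of `10⁻⁴ × b`, and, when they wander outside the launch sphere to
  distance ρ, either escape (probability `1 − b/ρ`) or re-enter through
  the exact first-passage distribution onto the launch sphere (sampled by
  inverse transform; uniform re-placement would bias the capacity and
  fails the sphere fixture). Then `C = b · P(absorbed)` with a binomial
  standard error. The finite-skin bias is first order in the skin and
  below the Monte Carlo error at defaults. Distance queries group spheres
  by equal radius (one square root per group), which covers the two-radius
  bodies that dominate this problem.
* **Polarizability / intrinsic viscosity.** The same walkers estimate the
  orientation-averaged conductor polarizability: with launch direction
  `n̂` and hit position `y` (relative to the launch center), the grounded
  response is `m_ij = 3b² E[n̂_i y_j]`, the induced monopole
  `Q_j = b E[y_j]`, and the neutral-conductor polarizability
  `α_ij = 4π (m_ij − Q_j ⟨y_i⟩)` — an exact multipole projection on the
  launch sphere, normalized so a sphere gives `α = 3V`. The intrinsic
  viscosity follows as `[η] = (5/6) ⟨α⟩ / V` with the union volume `V`
  from rejection sampling (the estimator refuses volumes with > 1%
  relative error). The 5/6 prefactor is fixed by the sphere calibration
  `[η] = 5/2`; for strongly anisotropic bodies the fixed prefactor
  overestimates the true viscosity factor (≈3% at axial ratio 3, ≈6% at
  axial ratio 5 against tabulated Simha values) — this is a known property
  of the polarizability route, quantified in the test suite.
  Errors come from 20-batch means.
* **Radius of gyration.** Deterministic: mass-weighted gyration tensor of
  the union (mass ∝ radius³, each sphere contributing its solid-sphere
  self term `(1/5) r² I`), eigenvalues `Λ₁ ≤ Λ₂ ≤ Λ₃`, `R_g² = ΣΛ`.
  Contrast modes mimic measurement physics: `uniform` (equal density,
  like a chemically homogeneous particle), `core_only` (X-ray-like,
  metal-dominated), `chains_only` (contrast-matched neutron-like). For a
  plain body the largest sphere stands in for the core. The "uniform"
  convention weights by volume; an equal-per-scatterer weighting was
  considered and rejected as the default because the uniform-contrast
  experiment it models is density-weighted.

* **Ellipsoid fixtures** are exact medial-axis transforms: a prolate
  spheroid equals the union of its maximal inscribed spheres, centered on
  the major axis at `|z| ≤ c²/a` with radius `b√(1 − z²/c²)`. A finite
  tessellation (default ≥ 500 spheres) leaves a scalloping error
  quadratic in the spacing, measured in the tests by resolution doubling
  and found below Monte Carlo error at defaults.

## Crossover theory

The capacity of two tangent spheres is Russell's digamma closed form; its
expansion in `s = (r/R)/(1 + r/R)` is `C/R = 1 + 2Σ_{k odd ≥ 3} ζ(k) s^k`.
The single-attached-sphere increment is implemented as the tail-resummed
approximant

    δR_h(r, R)/R = 2 ζ(3) s³ + c0 s⁵,

which is exact to leading order as `r/R → 0` and, with the adopted
`c0 = 2.69678`, gives `δR_h(R, R) = 0.3848 R` — within 0.4% of the exact
capacity increment `(2 ln 2 − 1) R` and 0.2% of the best numerical
hydrodynamic value `0.384 R`; its deviation from the exact Russell curve
is below 0.26% of `R` everywhere in `0 ≤ r/R ≤ 1`. Solving the two
consistency conditions (small-ratio amplitude; exact equal-spheres limit)
on this form yields `c0 = 32(2 ln 2 − 1 − ζ(3)/4) ≈ 2.745`; both values
are exposed, the quoted 2.69678 as the default constant and the solved
2.745 via `c0_from_consistency`. For attached prolate ellipsoids the
constant grows with axial ratio as `c0 = (2π − 1) ln(1 + a_s/e) + 1.041`,
with `a_s = √(2Λ₃/(Λ₁+Λ₂))` estimated from the gyration principal values
of the attached object (unity for an isotropic body, divergent in the rod
limit).

Many attached objects saturate through the hydrodynamic penetration
function `Z/(1+Z)`: `δR_h = δR_h^sat · Z/(1+Z)`, `Z = N δR_h1/δR_h^sat`
(free-draining linear regime → impenetrable-layer limit). Grafted chains
generalize this to `Z^φ/(1+Z^φ)`; the crossover exponent `φ ∈ (0, 1]`
absorbs chain–core and chain–chain interactions, and the `Z^φ` placement
is fixed by the requirement that `φ = 1` reduce exactly to the rigid-
object form. The saturation thickness follows
`δR_h^sat = A (L/l_p)^{ν_h}` with
`ν_h = [1 + 0.43(R/6r_c)]/[1 + 0.70(R/6r_c)]` bounded in (0.614, 1]; the
amplitude `A` is an explicit parameter (fit from data — no printed value
was adopted). The Hill isotherm `N = N_max c^n/(K_D^n + c^n)` supplies
the equilibrium bound-protein count feeding the same crossover for corona
layers; binding kinetics are out of scope.

For the two-sphere dumbbell, `R_g` uses the mass-weighted two-solid-sphere
closed form, and `R_h/R_g` interpolates from `√(5/3) ≈ 1.291` (lone
sphere) to `2 ln 2/√(8/5) ≈ 1.096` (equal spheres) with a shallow maximum
near `r ≈ 0.3 R` (the implementation places it at 0.27 R, 1% above the
sphere value).

## Estimator hygiene in the analysis layer

* Conformational fluctuation `σ_Rh` subtracts the mean squared Monte
  Carlo standard error from the raw per-snapshot variance; on frozen
  snapshots the conformational part is consistent with zero. This
  separation is essential at scaled-down walker counts.
* Persistence length: `C(Δ) = ⟨û(s)·û(s+Δ)⟩` over bond unit vectors,
  averaged over all starting positions and chains; `l_p` is the arc
  length (mean bond length × separation, linearly interpolated) of the
  first 1/e crossing; errors by bootstrap over chains.
* Scaling exponent: `ν` from the log–log regression of the root-mean-
  square `R_g` against bead count; `ρ` is the log–log correlation
  coefficient; errors by bootstrap over chains.
* Crossover fits use `scipy.optimize.curve_fit` with `φ ∈ [0.05, 1.5]`;
  synthetic round trips recover `(φ, δR_h^sat)` to < 2% at 5% noise.
  Purely linear coverage data leave `δR_h^sat` unidentifiable, which is
  reported through a divergent standard error rather than hidden.
* Histograms use Freedman–Diaconis binning, recorded in metadata.

## What the generator emulates — and what it does not

The synthetic study conditions are the model's own: chain lengths
L ∈ {5, 10, 18, 40}, cores R = 1–5 nm, coverages 1–1000, `T* = 1`,
`k_lin = 1`. The coarse-grained chain has no sequence dependence (all
bases are identical "T" beads), no explicit electrostatics (valid at high
salt), no hybridization, and no solvent-mediated hydrodynamic coupling
during sampling (conformations are equilibrium NVT; transport properties
are computed afterwards on rigid snapshots). Passing tests therefore
validate the method stack — force field, sampling, estimators, theory —
under those model assumptions, not sequence- or salt-specific behavior of
real ssDNA.

Two documented model-level tensions surfaced during validation and are
reported, not patched:

* With `k_lin = 1` the 1/e-criterion persistence length measures
  ≈ 0.97 nm (robust to dt, replica count and chain length), while the
  literature ssDNA value the stiffness is meant to reproduce is
  2.0 ± 0.1 nm; the measured Kuhn length
  (`⟨R_e²⟩/L_c`) is ≈ 2.3 nm, and a stiffness of `k_lin ≈ 3.3` would be
  needed to push the 1/e crossing itself to 2.0 nm. The printed
  parameterization is kept.
* The four-length `R_g` scaling fit gives `ν ≈ 0.69 ± 0.01` (the local
  18→40 slope is ≈ 0.655; the global fit is lifted by the stiffness
  crossover at L = 5) against the reference fit value 0.65 ± 0.007.

## Numerical choices and degenerate inputs

Pair energies below the shift `r_s` raise (unphysical configuration);
FENE bonds at `r ≥ R₀` raise with a diagnostic naming the offending bond
(integration aborts rather than silently clamping). Angular cosines are
clamped to [−1, 1] against rounding. The Russell capacity switches to its
series for radius ratios below 10⁻³ where the digamma form loses
precision. Walkers have a 10⁵-step cap; capped walks are counted as
escaped and reported as a bias warning (never observed at default skins).
Capacity requires ≥ 10³ walks and a skin far below the smallest sphere
radius. Over-packed graftings fail with the feasible chain count.

## Known limitations

Single-particle properties only (no virial coefficient `A_2`, no
dimerization or assembly); no bead-level mobility-tensor hydrodynamics
(the capacity analogy carries its documented ≈1% accuracy, and the
polarizability route a few percent more for strongly anisotropic bodies);
`O(N²)` force loops, adequate for ≤ a few thousand beads; the grafted
pipelines at their scaled-down defaults resolve trends (fluctuation peak,
attraction collapse, near-linear `δR_h(L)`) rather than the full
full-scale coverage curves.
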