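# graftnp

Solution properties of polymer-grafted nanoparticles — coarse-grained
molecular dynamics plus path-integration hydrodynamics plus analytic
crossover theory, in one package.

## The problem

Gold nanoparticles functionalized with short single-stranded DNA (and
polymer-grafted nanoparticles generally) are characterized in solution by
their hydrodynamic radius R_h (dynamic light scattering), radius of
gyration R_g (X-ray/neutron scattering) and intrinsic viscosity [η].
These "sizes" disagree with each other because the grafted layer is
diffuse and fluctuating; predicting them from structure (core radius R,
chain length L, grafting density N_c, chain–surface affinity) is what
this package does, for whoever needs to engineer or interpret such
measurements.

Three layers:

1. **`graftnp.forcefield` / `graftnp.engine`** — a bead–spring ssDNA
   model (one bead per base, σ = 0.65 nm; WCA excluded volume, FENE
   bonds k = 30/σ², R₀ = 1.5σ, stiffness U_lin = k_lin(1 + cos θ),
   tunable core–bead attraction ε_s) sampled by Langevin dynamics at
   T* = 1 with the core fixed at the origin.
2. **`graftnp.hydro`** — walk-on-spheres estimators on sphere-union
   bodies: the capacity analogy R_h ≈ C (≈1% accuracy), the
   contrast-weighted gyration tensor, and the polarizability route
   [η] = (5/6)⟨α⟩/V calibrated to the Einstein value 5/2 for a sphere.
3. **`graftnp.theory`** — closed forms: Russell's two-touching-sphere
   capacity C = −(rR/(r+R))[ψ(r/(r+R)) + ψ(R/(r+R)) + 2γ], the
   one-parameter increment approximant
   δR_h/R = 2ζ(3)s³ + c₀s⁵ (s = (r/R)/(1+r/R), c₀ = 2.69678;
   c₀ = (2π−1)ln(1+a_s/e) + 1.041 for attached ellipsoids), the
   hydrodynamic penetration crossover δR_h = δR_h^sat·Z^φ/(1+Z^φ) with
   Z = N_c δR_h1/δR_h^sat, the saturation law δR_h^sat ∝ (L/l_p)^{ν_h},
   the Hill binding isotherm, and dumbbell R_g / R_h/R_g formulas
   (including the Perrin ellipsoid R_h used as accuracy oracle).

`graftnp.analysis` post-processes ensembles (fluctuation statistics with
estimator-noise separation, persistence length, R_g scaling, crossover
fits) and `graftnp.workbench`/the `graftnp` CLI provide fixtures, I/O
(extended-XYZ, HDF5), manifests and scaled-down figure recipes.

## Worked example

```python
import numpy as np
from graftnp import (ForceField, SimSettings, build_grafted_np, run_nvt,
                     capacity, intrinsic_viscosity)
from graftnp.analysis import summarize_ensemble
from graftnp.workbench import make_fixture
from graftnp import theory

# --- rigid benchmark: two equal touching spheres -----------------------
body = make_fixture("tangent_dumbbell", {"R": 1.0, "r": 1.0}).obj
est = capacity(body, n_walks=100_000, seed=7)
print(f"C/R = {est.value:.4f} ± {est.std_error:.4f}")
print(f"exact 2 ln 2 = {theory.capacity_two_touching_spheres(1, 1):.4f}")

# --- a 3 nm core with 8 grafted 6-base chains --------------------------
ff = ForceField(r_s_core=3.0 - 0.325)          # core radius R = 3 nm
cfg = build_grafted_np(R=3.0, N_c=8, L=6, ff=ff, seed=1)
traj = run_nvt(cfg, ff, SimSettings(n_steps=60_000, n_samples=40, seed=1))
summ = summarize_ensemble(traj, n_walks=10_000, seed=1)
print(f"mean R_h = {summ.mean_rh:.3f} nm   delta R_h = {summ.delta_rh:.3f} nm")
print(f"sigma_Rh (conformational) = {summ.sigma_rh:.3f} nm")
print(f"R_g (uniform contrast) = {summ.mean_rg['uniform']:.3f} nm")
```

prints (seeds as shown):

```
C/R = 1.3889 ± 0.0030
exact 2 ln 2 = 1.3863
mean R_h = 3.546 nm   delta R_h = 0.546 nm
sigma_Rh (conformational) = 0.041 nm
R_g (uniform contrast) = 2.466 nm
```

So eight 6-base strands thicken the hydrodynamic size of a 3 nm core by
≈ 0.5 nm, the layer's conformational fluctuations put ≈ 0.04 nm of width
on R_h, and R_h/R_g ≈ 1.44 already exceeds the hard-sphere value 1.29 —
the diffuse-layer signature the method stack is built to quantify.

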