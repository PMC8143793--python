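# fibrosim

In-silico assessment of fibrotic left-atrial substrates: can rapid pacing
induce self-sustaining reentrant drivers (RDs, "rotors"), and how does that
propensity relate to the amount and spatial pattern of fibrosis?

`fibrosim` is a research pipeline for computational cardiac
electrophysiologists.  It bundles, as one tested package:

* the standard 21-variable **human atrial action-potential model** with two
  remodeled parameterizations — chronic-AFib (I_Kur, I_to -50%, I_CaL -70%)
  and fibrotic/TGF-beta1 (additionally I_CaL -50%, I_Na -40%, I_K1 -50%) —
  integrated by Rush-Larsen with an RK4 reference oracle;
* a **monodomain reaction-diffusion solver** (linear FEM, lumped mass,
  operator splitting, numba kernels) on triangulated sheets and bilayer
  surfaces with anisotropic, fibrosis-dependent conductivities
  (beta C_m dV/dt = div(sigma grad V) - beta (I_ion - I_stim));
* a **synthetic substrate generator**: LA-like ellipsoidal bilayer shells
  with PV ostia, appendage and mitral rim, five-region partition, 15 pacing
  sites, rule-based fibers, and seeded binary fibrosis patterns with exact
  burden control and tunable texture;
* the **clinical rapid-pacing induction protocol** (12 stimuli, 300 ms
  coupling ramping to 200 ms) with phase-based rotor detection
  (Hilbert-transform phase, +-2pi element winding, trajectory tracking),
  macroscopic-reentry exclusion, unique-morphology counting and region-wise
  inducibility scores (IdS);
* **fibrosis pattern metrics**: local fibrosis density and entropy and the
  published pro-RD classification polynomial
  0.4096 FD^2 + 3.28 FD FE - 0.1036 FE^2 - 0.7112 FD - FE + 0.0429;
* a **virtual-cohort pipeline** with the accompanying statistics (quartile
  grouping, Wilcoxon rank-sum with Hodges-Lehmann CI, chi-squared,
  burden-count correlation and logistic fits).

Patient LGE-MRI meshes are not public; everything here runs on synthetic
substrates that emulate the features the analysis consumes.  See
`docs/methods.md` for the model details, calibrations, reduced-scale
conditions, and known limitations.

## Worked example

Pace the two remodeled cell models to their limit cycles and compare them:

```python
from fibrosim import make_model, pace_to_limit_cycle

metrics = {}
for variant in ("afib", "fibrotic"):
    state, (t, v), info = pace_to_limit_cycle(make_model(variant), bcl=500.0)
    m = metrics[variant] = info["metrics"]
    print(f"{variant}: APD90 {m.apd:.1f} ms, dV/dt_max {m.dvdt_max:.1f} "
          f"mV/ms, rest {m.v_rest:.1f} mV")

a, f = metrics["afib"], metrics["fibrotic"]
print(f"APD90 prolongation: {100 * (f.apd / a.apd - 1):+.1f}%")
print(f"upstroke change:    {-100 * (1 - f.dvdt_max / a.dvdt_max):+.1f}%")
```

prints

```
afib: APD90 181.2 ms, dV/dt_max 197.2 mV/ms, rest -80.6 mV
fibrotic: APD90 209.1 ms, dV/dt_max 105.8 mV/ms, rest -74.6 mV
APD90 prolongation: +15.4%
upstroke change:    -46.4%
```

i.e. the fibrotic remodeling prolongs the action potential by ~15%, slows
the upstroke by ~46%, and depolarizes the resting membrane by ~6 mV — the
cellular substrate for slow conduction and unidirectional block in fibrotic
tissue.  A tissue-scale example (healthy-strip conduction velocity):

```python
from fibrosim.reproduce import strip_cv
print(strip_cv("longitudinal"))   # ~71.4 cm/s at 200 um resolution
```

The command-line interface exposes the same pipeline
(`fibrosim membrane --variant fibrotic`, `fibrosim substrate`,
`fibrosim cohort`, `fibrosim reproduce`, ...).

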