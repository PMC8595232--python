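# tevarsim

A reduced-order, desk-scale simulator of stent-graft (SG) deployment in
**type B aortic dissection** (TEVAR — thoracic endovascular aortic repair).
It is aimed at cardiovascular-biomechanics researchers who want the
mechanical skeleton of a patient-specific virtual-deployment pipeline —
constitutive fitting, arterial pre-stress, superelastic device mechanics,
configuration metrics — without a 3D finite-element solver: every vessel
cross-section is a thin ring in radial equilibrium with a superelastic stent
ring.

## What it computes

**Wall constitutive model.** The dissected aortic wall is incompressible
Yeoh hyperelastic,

    W = c10 (Ī₁ − 3) + c20 (Ī₁ − 3)² + c30 (Ī₁ − 3)³,

with coefficients fitted per uniaxial strip test (Cauchy stress
σ = F·λ/A₀ from the incompressible area reduction, stretch referenced at the
0.05 N preconditioning load, fitted from zero stretch to the yield point)
and then averaged across samples. The intimal flap is linear elastic
(277 kPa, ν = 0.49).

**Stent wire.** A 1D flag-shaped superelastic Nitinol law with martensite
fraction ξ ∈ [0, 1]: austenite slope E_A to the loading plateau
(600 → 670 MPa, transformation strain 0.063), martensite slope E_M beyond,
reverse plateau 288 → 254 MPa on unloading, full strain recovery — so the
crimped device pushes with its *chronic outward force* (unloading branch),
not its radial resistive force.

**Pre-stress.** The imaged (diastolic, 80 mmHg) geometry is not stress-free.
A per-station hoop pre-stress σ₀ is found by fixed-point iteration:
pressurise, feed the equilibrium hoop stress back as σ₀, repeat until the
worst radial deviation from the imaged radii is below 0.5 mm.

**Deployment variants.** Crimp 28 → 7 mm, pre-dilate the narrowed true
lumen 6 → 8 mm, release each strut-end ring and solve
P_stent(r) + P_graft = P_wall(r):
*A* — no pre-stress, no pressure; *B* — pre-stress, luminal pressure removed;
*C* — pre-stress plus 80 mmHg inside the graft (bare proximal ring P1
excluded).

**Metrics.** Local open area (LOA: area of a periodic cubic spline through
each strut end's apex points, projected on its least-squares plane),
strut-centre deviation e_c, and mean ± SD / [min, max] summaries per landing
section (healthy aorta / entry tear / dissection).

No CT data is consumed: a synthetic-patient generator builds the dissected
vessel (healthy 26 mm, aneurysmal entry tear 30 mm, true lumen narrowed to a
6.5 mm minimum diameter, 1.5 mm wall, 0.6–1.6 mm flap) and synthetic tensile
records.

## Worked example

```bash
tevarsim run -o demo --seed 1
```

runs fit-tissue → synth → prestress → deploy (A, B, C) → validate and prints
a summary; with seed 1 it reports (abridged):

```
fitted_params_kpa: c10 17.64, c20 56.96, c30 121.18, mean R² 0.9993
prestress: converged true, 6 iterations, max deviation 0.237 mm
variants:
  A: mean e_LOA +9.98 %
  B: mean e_LOA −2.95 %
  C: mean e_LOA +0.01 %
```

Reading this: twelve synthetic strip tests with 2 % noise fit back close to
the generating wall parameters (17.5 / 58.9 / 116.1 kPa); the pre-stress
iteration meets the 0.5 mm imaging criterion in 6 sweeps; and against a
reference configuration the stress-free model **A over-opens** the stent
(worst in the narrowed dissection section), pre-stress without graft
pressure (**B**) lets the wall recoil and under-opens it, while the full
model **C** sits in between and closest — the reason both pre-stress and
graft pressure must be modelled. Per-end tables, apex point clouds, wall
hoop-stress tables (entry tear shielded, dissection loaded post-TEVAR) and
the section summaries land in `demo/`.

The same stages are available individually (`tevarsim synth`,
`tevarsim prestress`, `tevarsim deploy --variant C`, `tevarsim validate`,
`tevarsim fit-tissue`) and as library functions.

## Layout

| module | contents |
|---|---|
| `tevarsim.materials` | Yeoh, linear-elastic and superelastic Nitinol laws |
| `tevarsim.tensile` | strip-test processing, yield detection, Yeoh fitting |
| `tevarsim.synthetic` | vessel / tensile-data / reference-configuration generators |
| `tevarsim.prestress` | ring pressurisation and the fixed-point algorithm |
| `tevarsim.deployment` | crimp / pre-dilation / release, variants A/B/C |
| `tevarsim.metrics` | LOA, e_c, section summaries, validation report |
| `tevarsim.pipeline`, `tevarsim.cli` | end-to-end runs and the `tevarsim` CLI |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
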