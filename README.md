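# fastpet

Analytical PET simulation and reconstruction toolkit.

Monte Carlo PET simulators are accurate but take CPU-core-days per
clinical frame; naive analytical simulators are fast but do not match
real scanner geometry or counting statistics.  `fastpet` implements
the middle path: given a 3D activity map (Bq/ml) and a 3D attenuation
map (cm⁻¹), it produces realistic noisy sinograms and reconstructed
images against a configurable cylindrical-scanner geometry — including
the Siemens Biograph Vision-600 data format (520 projections × 50
views × 815 planes × 33 TOF bins, span 19, 72.6 × 72.6 × 26.2 cm³
FOV) — together with the full evaluation stack used to validate such
simulators: NEMA IQ recovery/noise analysis, intensity and GLCM
texture features, and segmentation-concordance metrics.

It is aimed at researchers who need large numbers of ground-truthed
PET images: virtual imaging trials, development and validation of
quantification, denoising, or segmentation pipelines, and training
data for learned reconstruction.

## Model

The simulation chain, for activity map `a` (Bq/ml), attenuation map
`μ` (cm⁻¹), acquisition time `T` (s):

1. `ã = G_fwhm ∗ a` — isotropic Gaussian pre-smoothing (default FWHM
   3 mm) modelling positron range, photon non-collinearity and
   intrinsic detector resolution;
2. decays per voxel `d = ã · v_ml · T`;
3. trues: `t = (S/1000) · A d · exp(−∫μ dl)` where `A` is a Joseph
   ray-driven projector in sinogram coordinates, globally normalized so
   that `Σ A x = Σ x` (counts-preserving), and `S` is the scanner
   sensitivity in cps/kBq (default 38, so a non-attenuated source gives
   exactly `S·T` counts per kBq);
4. randoms: uniform sinogram with `Σ r = 0.20 · Σ t` (default random
   rate 20%);
5. scatter: 2D single-scatter simulation (Klein–Nishina cross-section,
   energy-window acceptance, two-leg attenuation) per slice, expanded
   axially by inverse single-slice rebinning and scaled to a
   configurable scatter fraction (default 30%);
6. prompts `p ~ Poisson(t + s + r)` element-wise, plus an independent
   delayed-window sinogram `~ Poisson(r)`;
7. reconstruction by ordinary-Poisson OSEM,
   `x ← (x/s_u) · Aᵀ_u( p_u / (A_u x + r̄_u + s̄_u) )`,
   with view-interleaved subsets, optional image-space PSF and TOF.

The back projector is the exact matrix transpose of the forward
projector, so EM monotonicity holds to numerical precision and is used
as a correctness oracle in the tests.

## Worked example

Simulate the NEMA image-quality phantom (six spheres of 10–37 mm inner
diameter at 27 369 Bq/ml in a 9575 ml background at 2930 Bq/ml, a
9.34:1 ratio) at quarter scale, reconstruct, and measure recovery
coefficients:

```python
import fastpet as fp

g, grid = fp.make_scaled_geometry(0.25)          # 130×13×204 sinogram, 110×110×40 grid
act, mu, spec = fp.make_nema_iq(grid)

cfg = fp.SimulationConfig(acquisition_time_s=120.0, scatter=fp.ScatterConfig(), seed=1)
sset = fp.simulate(act, mu, g, cfg)              # trues/scatter/randoms + noisy prompts
print({k: round(v) for k, v in sset.counts.items() if k != "prompts_noisy"})
# {'trues': 19590618, 'scatter': 8395979, 'randoms': 3918124}

attn = fp.attenuation_factors(mu, g)
rcfg = fp.ReconConfig(n_iterations=8, n_subsets=5, grid=grid)
img = fp.op_osem(fp.Sinogram(sset.prompts_noisy[0], g),
                 fp.Sinogram(sset.delayed_noisy[0], g),
                 sset.scatter, attn, g, rcfg)
img = fp.counts_to_activity(img, cfg)            # back to Bq/ml

rois = fp.nema_rois(grid, spec)
for d, m in rois.spheres.items():
    print(f"{d:g} mm sphere: RC = {fp.recovery_coefficient(img, m, 27369):.3f}")
# 10 mm sphere: RC = 0.268     (strong partial-volume loss)
# 13 mm sphere: RC = 0.527
# 17 mm sphere: RC = 0.584
# 22 mm sphere: RC = 0.734
# 28 mm sphere: RC = 0.759
# 37 mm sphere: RC = 0.817     (recovery approaches 1 with size)
```

The recovery coefficient (mean reconstructed / true activity) rises
with sphere diameter because small objects lose apparent activity to
the system resolution; the background COV falls as the acquisition
time (count level) grows.  Both trends are asserted end-to-end in the
test suite.

A `fastpet` command-line tool wraps the same library:
`fastpet phantom | simulate | recon | nema | features | segcompare |
concordance | config`; every run writes a JSON manifest (config,
seeds, count totals) that reproduces it exactly.

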