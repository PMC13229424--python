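# vaviq

Quantification of flow-induced high-frequency vascular wall vibrations in
arteriovenous fistulas (AVFs).

An AVF — the surgical artery-to-vein connection used for hemodialysis
access — exposes the juxta-anastomotic vein to transitional, high-velocity
flow.  The resulting wall vibrations (tens of µm, tens to hundreds of Hz)
are a candidate mechanical driver of adverse remodeling: stenosis by
intimal hyperplasia, or excessive dilatation.  `vaviq` is the
post-processing half of a fluid–structure-interaction (FSI) workflow: it
takes time-resolved wall displacement and traction fields on a triangulated
vessel surface (as an FSI solver exports them) and turns them into the
quantities that discriminate those fates.  It is written for biomedical
engineers and computational hemodynamics groups who have solver output (or
want a controlled synthetic stand-in) and need reproducible vibration
metrics and statistics.

## What it computes

- **High-pass vibration amplitude** — wall displacement filtered above
  25 Hz (zero-phase Butterworth); per-node time-averaged magnitude in µm,
  and the 99th spatial percentile trace with its peak and cycle-average.
- **High-pass strain** — in-plane Green–Lagrange strain of the filtered
  displacement; scalar = largest-magnitude principal value.
- **Spectrograms and band detection** — Hann short-time spectra of the
  juxta-anastomotic mean displacement; narrowband modes detected as
  supra-threshold runs with power-weighted centroids.  The three regimes
  of interest: no band (patency), two bands in 45–100 Hz (stenosis), one
  band near 50 Hz (dilatation).
- **Wall-shear indices** — TAWSS, OSI ∈ [0, 0.5], and the spectral power
  index SPI (supra-cutoff fraction of mean-removed power, a turbulence
  proxy), plus the Q-criterion ½(‖Ω‖² − ‖S‖²) from velocity gradients.
- **Slice statistics** — metrics averaged over 25 × 1 mm cross-sectional
  slices of the first 2.5 cm of the juxta-anastomotic vein.
- **Mixed-effects comparison** — `GroupComparisonModel(...).fit()` returns
  a results object (estimates, SEs, p-values, variance components,
  `summary()`): random-intercept model per patient, Gaussian (REML) with
  an automatic Gamma/log-link refit when residual normality fails, plus
  mixed-model correlations between shear indices and vibration metrics.

A synthetic generator produces tube vessels with calibrated wall motion for
each regime, so the entire pipeline is testable without patient data.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from vaviq import (GROUP_PRESETS, make_tube, generate_wall_motion,
                   summarize_vibration, assign_nodes_to_slices, slice_means,
                   highpass_filter, detect_bands, fit_lmm, simulate_slice_table)
from vaviq.spectral import detection_spectrum

mesh, cl = make_tube()                       # r=3.5 mm, L=30 mm tube
series = generate_wall_motion(mesh, cl, GROUP_PRESETS["dilatation"], seed=42)
vib = summarize_vibration(mesh, series)      # 25 Hz high-pass
print(f"peak amplitude      : {vib.peak_amp_um:.1f} um")
print(f"cycle-average       : {vib.cycleavg_amp_um:.1f} um")

slices = assign_nodes_to_slices(mesh, cl)    # 25 x 1 mm slabs
table = slice_means({"amp_um": vib.amp_map, "strain_e3": vib.strain_map * 1e3},
                    slices, patient_id="D1", group_label="dilatation")
print(f"slice-mean amplitude: {table[table.metric_name=='amp_um']['mean_value'].mean():.1f} um")
print(f"slice-mean strain   : {table[table.metric_name=='strain_e3']['mean_value'].mean():.2f} x1e-3")

hp = highpass_filter(series)
trace = hp.values[:, slices >= 0, :].mean(axis=1)
bands = detect_bands(detection_spectrum(trace, hp.dt))
print(f"detected bands      : {[(round(b.f_center_hz,1), round(b.peak_db,1)) for b in bands.bands]}")

res = fit_lmm(simulate_slice_table(seed=0), "amp_um", "two_group")
print(res.summary())
```

prints

```
peak amplitude      : 66.5 um
cycle-average       : 25.1 um
slice-mean amplitude: 15.8 um
slice-mean strain   : 1.01 x1e-3
detected bands      : [(50.1, -40.1)]
Mixed-effects group comparison: response='amp_um', design=two_group
family=gamma_log  n_obs=150  n_patients=6  contrast df=5
random-intercept var=0.04935  residual var/dispersion=0.06945
residual Shapiro-Wilk p=0.000113   conditional R=0.864
adjusted alpha=0.05

term                            estimate          SE           p
intercept                           2.03      0.1614
adverse_vs_patency                0.9638      0.1977     0.00458
```

Reading it: the dilatation-regime vessel vibrates with a single narrowband
mode centered at 50.1 Hz, a slice-mean time-averaged amplitude of ~16 µm
and strain ~1.0×10⁻³; the percentile trace peaks at 66 µm.  On a simulated
six-patient cohort the residuals fail normality, the model falls back to
the Gamma/log family, and patients with adverse remodeling show
e^0.96 ≈ 2.6× the patency amplitude (p ≈ 0.005, t with 5 df).

The same stages are scriptable from the shell:

```
vaviq synth --preset cohort --seed 1 --out data/
vaviq run --seed 1 --out report/       # synth -> metrics -> slices -> stats
vaviq vibration data/D1.obj data/D1_displacement.h5 --out vib/
vaviq stats report/slices.csv --response amp_um --design three_group
```

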