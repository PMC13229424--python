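# Methods

`vaviq` quantifies flow-induced high-frequency vibrations of the vascular
wall in arteriovenous fistulas (AVFs) from time-resolved surface fields —
the post-solver half of a fluid–structure-interaction (FSI) workflow.  This
note records the models, conventions and numerical choices the package
commits to, and what its synthetic verification does and does not show.

## Signal model

Wall displacement on the vessel surface is treated as the sum of a
quasi-static cardiac pulsation (harmonics of the heart rate, ≲10 Hz) and
flow-induced vibration (≳25 Hz).  The separation is a zero-phase 4th-order
Butterworth high-pass (`scipy.signal.sosfiltfilt`, reflection padding) at a
configurable cutoff, default **25 Hz**.  Two passes give ≈48 dB attenuation
one octave below the cutoff and <1% passband droop above twice the cutoff;
zero phase matters because the vibration metrics are time averages of the
filtered signal itself, not of an envelope.

From the filtered field the package derives:

- **Vibration amplitude** — per node, the time average of the Euclidean
  displacement magnitude over a whole number of cardiac cycles, reported in
  µm (geometry is in mm; amplitudes are three orders of magnitude smaller).
  Time-averaged magnitude was chosen over RMS or envelope because the
  downstream slice statistics are means of exactly this quantity.
- **Percentile trace** — per timestep, the 99th spatial percentile of the
  amplitude: a robust "loudest point on the wall" trace through the cycle,
  with peak and cycle-average scalars.  Percentiles use exclusive (type-6)
  plotting positions, `position = q/100·(n+1)`, linearly interpolated and
  clipped to the sample range; `q = 100` returns the maximum.  The
  convention is fixed for reproducibility and documented because different
  software defaults disagree at these sample sizes.
- **High-pass strain** — per triangle and timestep, the in-plane
  Green–Lagrange tensor of the filtered displacement restricted to the
  element plane, `E = (AᵀCA⁻¹-like edge-metric form − I)/2`; the scalar is
  the largest-magnitude principal value (a config-level choice; a
  tensor-norm scalar would be equally defensible).  Node values are
  area-weighted averages of incident triangles; the uniform-inflation case
  reproduces the closed-form hoop strain `(λ²−1)/2` to machine precision,
  and rigid motions produce exactly zero strain by construction.
  Filtering precedes differentiation; the two commute for the linear part
  of the strain.

## Spectral analysis

Spectrograms are Hann-window short-time power spectra of the analysis-region
trace: the spatial mean of the filtered displacement **vector** over the
juxta-anastomotic nodes, with component power spectra summed.  Taking the
magnitude before the transform would rectify the signal and alias band power
to twice the frequency, so the vector convention is used; it is also
rotation invariant.  Power is integrated per bin and expressed in dB re
1 mm² (1 (mm/s)² for velocity), floored at −120 dB, so a tone of amplitude
*a* reads `10·log₁₀(a²/2)` independent of resolution.

Display spectrograms default to a 0.1 s window with 90% overlap (10 Hz
resolution).  **Band detection runs on a separate time-averaged spectrum at
a 0.4 s window (2.5 Hz resolution)**: at 10 Hz resolution the Hann main
lobe bridges the ~20 Hz gap between the two stenotic bands and merges them.
Detection thresholds supra-threshold runs above the high-pass cutoff
(default **−48 dB**), merges runs closer than 12 Hz, drops runs narrower
than 5 Hz, and reports power-weighted centroids.  The −48 dB default is
derived from the amplitude scale of the synthetic regimes: a patent vessel
(≈6.6 µm spread over ≈125 Hz) sits near −56 dB per 2.5 Hz bin, while the
narrowband regimes (≈16–32 µm concentrated in ≈10 Hz) sit near −35 to
−40 dB, leaving ~8 dB margin on both sides.

The **spectral power index (SPI)** is the fraction of a mean-removed
signal's periodogram power strictly above the cutoff, in [0, 1], defined as
0 for constant signals; the same 25 Hz cutoff is used pipeline-wide for
consistency.  Applied to wall-traction magnitude it is the package's
turbulence proxy.

## Hemodynamic indices

The pipeline consumes wall-traction vectors exported by the solver rather
than recomputing them from volumetric velocity (no finite-element gradient
recovery is attempted), and Q-criterion consumes supplied velocity-gradient
tensors:

- `TAWSS = (1/T)∫‖τ‖dt` (Pa),
- `OSI = ½(1 − ‖∫τ dt‖ / ∫‖τ‖dt)` ∈ [0, 0.5], defined as 0 for zero shear,
- `SPI` of the traction magnitude as above,
- `Q = ½(‖Ω‖² − ‖S‖²)` with S/Ω the symmetric/antisymmetric velocity-
  gradient parts (Frobenius norms): positive where rotation dominates.

## Slice aggregation

Statistics operate on cross-sectional slices of the juxta-anastomotic vein
(JAV): each node is projected to the nearest centerline point and binned by
projected arclength into half-open 1 mm slabs over the first 25 mm
(→ 25 values per vessel per metric); arclength 0 is the anastomosis and
must be supplied as the centerline origin.  Projection-binning was chosen
over exact perpendicular-plane cutting for robustness on coarse meshes; on
a curved test vessel (curvature radius ≥ 5× lumen radius) it agrees with
plane cutting on ≥95% of nodes.  Slice means are unweighted by default
(area weighting is a flag).  Arclengths within 10⁻⁹ of a slab boundary are
snapped upward so boundary nodes bin deterministically under rigid
transforms.  A 0.1 mm spacing is available via configuration; the 1 mm
default matches the 25-values-per-vessel analysis unit.

## Group statistics

The slice is the unit of analysis, with repeated measures per patient.  The
comparison model is a random-intercept mixed model, fitted in two stages:

1. Gaussian linear mixed model (statsmodels `MixedLM`), **REML by default**
   (`reml=False` for ML) — with six patients the ML variance components are
   biased low enough to visibly inflate test size.  The default gradient
   optimizer occasionally diverges on boundary-variance problems, so
   derivative-free optimizers are tried and the first sane fit
   (finite likelihood, finite positive SEs) is used.
2. Shapiro–Wilk on the conditional residuals; if p < 0.05 the model is
   refitted as a **Gamma GLMM with log link**, implemented in-package with
   a Laplace approximation (the random intercept makes the integral
   one-dimensional and log-concave, so a damped Newton inner loop is
   exact enough); outer ML over (β, log shape, log σ_b) with L-BFGS-B, SEs
   from the numerical Hessian.  On a simulated slice table the estimates,
   SEs and variance components agree with `glmmTMB` to ~6 decimals.

Contrasts are Patency vs Adverse (stenosis + dilatation pooled) or each
complication group vs Patency with Bonferroni α/3 (reported at 4 decimals,
0.0167 for three comparisons).  **Degrees of freedom:** group contrasts are
between-patient effects; their Wald statistics are referred to a t
distribution with `n_patients − 1` degrees of freedom (the cluster-robust
convention).  A normal reference with six patients rejects a true null
~12% of the time at nominal 5%; with REML + t(G−1) the simulated size is
≈6% and the headline contrast retains its sensitivity.  Slopes of
within-patient covariates (the WSS-index correlations) use the normal
reference, as their information is slice-level.  The **conditional
correlation coefficient R** is the Pearson correlation between observations
and the conditional (fixed + random) fitted values.  A patient-level
permutation test (difference of group means of patient means, exact
enumeration; the 2-vs-4 design bottoms out at p = 1/15) is provided as a
distribution-free cross-check.

## Synthetic data: what it emulates

The generator builds tube meshes (default radius 3.5 mm, length 30 mm,
50×32 nodes) with axial centerlines and displacement series

    pulsation + sway + breathing + noise

- **Pulsation**: radial, harmonics at 1–3× the cardiac frequency (default
  period 1 s), 50 µm base amplitude — entirely below the cutoff.
- **Sway**: a near-rigid lateral motion of the vessel, band-limited to the
  preset bands, axially coherent over ~15 mm.  It carries displacement
  amplitude while contributing only quadratically to membrane strain.
- **Breathing**: radial ring motion, band-limited, coherent over ~5 mm;
  its hoop strain is amplitude/radius pointwise.
- **Noise**: white, 0.02 µm, a numerical floor.

Band-limited processes are synthesized in the frequency domain (raised-
cosine edges, 20% of the bandwidth), so band power is strictly confined;
axial coherence comes from Gaussian smoothing of independent per-millimetre
processes.  Vibration is localized along the vessel by a smooth quadratic
envelope and a frozen axially-correlated modulation (±20%), which together
produce the across-slice spread.

The two-component split exists because a purely wall-normal vibration on a
cylinder has an inescapable strain floor of amplitude/radius, which for a
realistic vein radius is several times larger than the strain levels the
regimes require; lateral sway decouples the two targets.  Both scales are
**self-calibrated per vessel through the actual measurement pipeline**
(filter → amplitude → strain → slices): component responses are measured
once, combined by quadrature (time-averaged magnitudes of independent
Gaussian components add in RMS), then refined by up to six corrective
iterations to within 2% of the targets; a residual above 5% raises an
error.

Group presets encode the three regimes:

| group      | bands (center, width, power)        | amp (µm)   | strain (×10⁻³) |
|------------|-------------------------------------|------------|-----------------|
| patency    | broadband 25–155 Hz                 | 6.6 ± 2.0  | 0.30 ± 0.10     |
| stenosis   | (55, 12, 0.65), (85, 12, 0.35)      | 31.7 ± 9.7 | 1.68 ± 0.58     |
| dilatation | (50, 10, 1.0)                       | 15.9 ± 4.8 | 1.00 ± 0.35     |

The lower stenotic band carries more power than the upper one; the exact
ratio is a free parameter fixed at 65/35.  A patent vessel still carries
µm-scale broadband motion — its defining feature is the absence of any
supra-threshold narrow band, not silence.  Cohorts draw each patient's
amplitude/strain targets from the group mean ± between-patient SD
(truncated normal at 0), with the printed pooled SD split evenly between
between-patient and across-slice variance (an unspecified partition; the
even split is a design choice held fixed).  `simulate_slice_table`
reproduces the same patient/slice statistical model directly, without field
synthesis, for simulation studies that need hundreds of cohorts.

Traction stand-ins (`steady`, `oscillatory`, `turbulent_like`) and constant
velocity-gradient tensors (`solid_rotation`, `simple_shear`,
`pure_extension`) have closed-form index values and exist to pin the shear
and Q-criterion implementations.

## Problem sizes

Default verification sizes: fields at 2 kHz for 3 cardiac cycles on
50×32-node tubes; a six-patient cohort (2 patency / 2 stenosis /
2 dilatation); 100-cohort power and 400-cohort type-I simulations at the
slice-table level; all single-core.

## What passing tests do not show

The synthetic regimes are calibrated emulations, not hemodynamics: no
Navier–Stokes or FSI physics, no Womersley profiles, no patient geometry
(straight tubes stand in for anastomosed vessels), no measurement noise
model for imaging-derived displacement.  Passing tests demonstrate that
the *pipeline* — filtering, strain, spectra, detection, slicing, mixed
models — measures what it claims on fields with known structure; claims
about real AVFs require solver outputs.  Per-patient published quantities
that depend on those fields (individual dB levels, patient R values) are
out of scope by construction.

## Known limitations

- Surface membrane strain only; no through-thickness strain.
- Band detection assumes bands separated by more than the detection
  resolution plus the main-lobe width; overlapping bands merge.
- The Gamma GLMM supports a single random intercept (the design used
  here), not general random-effect structures.
- OBJ + HDF5 are the only on-disk formats; other mesh/series formats need
  conversion upstream.
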