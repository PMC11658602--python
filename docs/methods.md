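# Methods

`depotkit` quantifies percutaneously injected, imageable hydrogel depots —
poloxamer-type gels carrying an iodinated CT contrast agent, microbubbles
for ultrasound visibility, and optionally a drug payload — from CT/CBCT-like
volumes, B-mode-like frames, and plasma concentration–time data. Because no
raw in vivo scans are available to a desk user, every stage is exercised on
synthetic phantoms whose ground truth is known by construction; this note
records the models, the defaults, and what they do and do not emulate.

## Depot phantoms

A depot is rendered on an isotropic voxel grid (default spacing
`min(semi_axes)/20`, so ≥ 20 voxels span the smallest semi-axis) as one of
three geometries:

* **ellipsoid** — the well-localized single-end-hole injection; default
  semi-axes 11.5 × 7.5 × 7.5 mm (≈ 2.7 mL, the ~4 mL-injection scale once
  partial intravasation is accounted for);
* **lobed** — two deterministic lobes budding off the main body, emulating
  multi-hole/multi-prong spread;
* **branched-leak** — thin tubes (default 3, radius 1.2 mm) radiating from
  the body, emulating gel intravasation into vessels. Tube directions are
  drawn from the spec's seed; everything else is deterministic.

Iodine concentration ≤ 40 mg/mL follows a uniform, radial-linear or
radial-Gaussian profile and is encoded linearly in attenuation:
`HU = hu_background + hu_per_mg_ml · c + N(0, noise_sd)`. Only the
*linearity* of the HU–iodine relation is part of the emulated physics; the
absolute attenuation of gel is not identifiable from such data, so
`hu_per_mg_ml` is an explicit parameter, defaulted to 25 HU/(mg/mL) so the
40 mg/mL ceiling sits ~1000 HU above background (strongly contrast-enhanced
but within CT range). No beam hardening, scatter, or reconstruction physics
is modeled; passing tests show the *analysis* is correct, not that a scanner
would produce these values.

Ground truth carried with each phantom: the analytic mask, the analytic
volume (4π/3·abc for the ellipsoid; the voxelized analytic mask for
composite shapes), the Knud Thomsen surface-area approximation for the
ellipsoid, and the concentration field.

## Segmentation and serial differencing

Depots are segmented by inclusive HU-range thresholding with 26-connected
component labeling (6/18 available). Serial per-mL analysis consumes an
ordered mask series plus optional rigid alignment transforms — alignment is
an input, never estimated here, matching how serially acquired scans are
registered interactively against the needle — and reports set-difference
increments. A step that shrinks by more than 5% of the previous mask raises
a warning but is reported as-is (negative growth is real data, not an
error).

## Surface meshing and 3D morphometrics

Surfaces are 0.5-level marching-cubes iso-surfaces of the binary mask in
physical mm. The raw staircase iso-surface of a voxel mask overestimates
area by ~8%, which would bias sphericity well below its analytic value, so
the indicator is smoothed with a Gaussian of σ = 0.8 voxel before
iso-surfacing; σ = 0.8 was chosen on the analytic ball as the point where
the area error (~0.05%) and the curvature-induced volume shrink (~0.9%)
are both small. Two fallbacks guard thin structures: if the smoothed field
never reaches the 0.5 level, or if the smoothed mesh encloses less than 85%
of the voxel volume (smoothing erases features thinner than ~σ), the raw
indicator is meshed instead.

Descriptors:

* volume `V` — exact voxel count × voxel volume (the oracle used
  throughout);
* surface area `SA` — mesh area;
* sphericity `π^{1/3}(6V)^{2/3}/SA` — 1 for a ball;
* solidity `V / V_hull` with the hull taken over mesh vertices; for
  multi-component masks a single joint hull is used (per-component analysis
  is available by segmenting with `select="all"`);
* SA/V in cm⁻¹ and mean ± SD HU within the mask.

A documented discretization slack ε_mesh = 0.03 is allowed on the ≤ 1
bounds: voxelized surfaces can overshoot slightly in either direction.
Internal units are mm/mm²/mm³; reported units cm/cm²/mL.

## 2D morphometrics

On a slice mask: area = pixel count × pixel area; major/minor axes from the
ellipse with matching second central moments; perimeter from
marching-squares boundary tracing with the same σ = 0.8 smoothing rationale;
circularity `4πA/P²` (the de-facto image-analysis definition — the quantity
is conventionally named but rarely defined); 2D solidity = pixel count /
convex-hull pixel count. Disconnected foreground is treated as one object.

## Iodine mapping

`c = c_max (HU − hu_baseline)/(hu_at_cmax − hu_baseline)`, clipped to
[0, 40] mg/mL. The baseline defaults to the median HU of a user-supplied
background region; nothing in the data pins it otherwise. Range areas use
the 7 / 13.4 / 27 / 40 mg/mL boundaries (half-open at the low edge, ceiling
included in the top range; configurable). Line profiles sample bilinearly
(default 100 samples) along a segment whose length is rescaled to one unit,
with trapezoidal AUC over normalized distance; temporal AUC of range areas
is trapezoidal over minutes.

## Ultrasound emulation and texture

B-mode-like frames resample the phantom on rigidly posed planes
(pixel (row, col) → world via an orthonormal frame and translation), map the
HU window linearly from a background gray of 60 to a hyperechoic depot level
of 200, and optionally multiply unit-mean Rayleigh speckle before 8-bit
quantization. This reproduces the *statistical* appearance B-mode texture
metrics respond to — it is not a wave-propagation model: no attenuation,
shadowing, point-spread anisotropy, or probe compression. The reported
tendency of ultrasound volumes to read larger than CT is therefore outside
what these phantoms can test.

Texture metrics within a supplied ROI mask: mean gray (acoustic intensity),
population-SD gray (acoustic heterogeneity; at realistic ROI sizes the
sample/population distinction is negligible), and 256-bin histogram Shannon
entropy in bits (bounded by 8 for 8-bit frames; the speckled depot sits in
the 6–8 bit band). Entropy is computed over the ROI only.

## Freehand 3D reconstruction

Tracked frames are splatted into an isotropic output grid: each pixel
sample distributes onto voxels within a 1-voxel kernel radius with
inverse-distance weights, and each voxel becomes the weighted mean of its
contributions; voxels no sample reached are flagged missing (no hole
filling). Consequences verified on ball phantoms: dense sweeps (step ≤ the
output spacing) recover volume within ~1%, a 30°-rotated sweep agrees with
the axis-aligned one within sampling error, and coarse sweeps leave
unvisited gaps that systematically *underestimate* volume — so
reconstruction error decreases with sweep density.

## Pharmacokinetics

**Simulator.** A two-compartment disposition model driven by a zero-order
infusion (default 24 min) is the minimal structure producing the observed
biexponential post-administration decay. With micro-constants k10, k12, k21
(1/min), the hybrid rates α > β are the negated eigenvalues of the 2×2
system; concentrations are evaluated in closed form (each mode charges as
`1 − e^{−rt}` during the infusion and decays afterwards) and cross-checked
in tests against numerical ODE integration. Defaults place the model in the
gel-depot cohort regime: dose 40 mg (4 mL × 10 mg/mL), t½α ≈ 5.4 min,
t½β ≈ 103 min (k21 = 0.03/min fixed, k10 and k12 derived), and
V_central = 8200 mL so the noiseless Cmax ≈ 2084 ng/mL at the end of
infusion. Sampling follows the study schedule: 0.5–24 min during and
26–264 min after administration (16 samples). Noise is multiplicative
lognormal with a given CV (mean-preserving). Note the simulator delivers
the full dose to the central compartment (F = 1); it emulates disposition
shape for parameter-recovery testing, not the depot's reduced systemic
availability.

**NCA.** Linear trapezoid AUCs over [0, t_adm] and [t_adm, t_end], divided
by 60 so AUCs are in ng/mL·h while times stay in minutes; a C(0) = 0 anchor
is prepended by default when sampling starts after 0 (the infusion starts
from zero; configurable). AUC_total is the sum of the phase AUCs by
construction, CL/F = dose / AUC_total (F unobserved), Cmax/Tmax from the
samples with ties broken to the earliest time, and below-quantification
values are treated as missing (NaN), not zero. Phase rate constants come
from least-squares slopes of log10 concentration vs time multiplied by
2.303; half-life = ln 2 / rate. Default windows split the
post-administration span at the sample minimizing the total SSE of the two
log-linear fits (≥ 3 positive samples per side).

A bias worth knowing: with realistically separated phases the terminal
component still contributes ~40% of concentration just after the infusion,
so the plain early-window slope underestimates α substantially. The
classical correction — fitting β first, back-extrapolating, and regressing
the residuals (method of residuals) — is available via
`phase_rates(..., strip=True)` and recovers α within 1% on noiseless
series. At 5% measurement noise the residuals carry most of the noise, so
α recovery has a median error of ~13% under the 16-sample schedule, while
β recovery stays under 5% — the α figure is a property of the schedule and
noise, not of the estimator.

**Calibration.** Peak-area-ratio (analyte / internal standard) calibration
supports ordinary and 1/x²-weighted least squares (the bioanalytical
convention; default), plus single-point proportionality for tissue panels.
Back-calculation clips negative concentrations to zero with a flag, and
divides by tissue mass when given.

**Biodistribution generator.** Free-drug-arm organ levels are fixed
baseline constants (administration site ≫ organs); the depot arm divides
each non-site organ by a per-organ localization factor and enriches the
site by √factor — a heuristic chosen so factor 1 leaves both arms
identical in expectation while the spared drug plausibly accumulates at the
site. Only fold *ratios* are meaningful; absolute levels are synthetic.

## Orchestration and reproducibility

All randomness flows through one integer seed per generator spec; the
pipeline derives per-stage child seeds from the run seed via
`numpy.random.SeedSequence`. A full synthetic run is byte-stable for a
fixed seed (hash-checked in tests), stages are isolated (a failing stage is
recorded in the manifest without stopping the rest), and the manifest
records the package version and a hash of the analysis-relevant
configuration. Problem sizes in the shipped analyses — 0.75 mm phantom
spacing, 3 animals per simulated arm, 200 series for recovery studies —
were chosen as the smallest sizes at which the voxelization and sampling
errors are comfortably below the tolerances being tested.

## Known limitations

* No registration: alignment transforms are consumed, never estimated.
* No CT or ultrasound physics beyond linear HU encoding and multiplicative
  speckle; absolute HU and gray levels are conventions, not predictions.
* The PK simulator is linear and two-compartmental; enterohepatic
  recirculation, nonlinear binding and depot-limited availability (F < 1)
  are not modeled.
* 3D solidity of multi-component depots uses a joint hull; whether a
  per-component hull is preferable depends on the question being asked.
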