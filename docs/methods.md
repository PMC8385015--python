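# Methods

`pkchip` is the computational side of a perfused ("tumour-on-chip") dosing
experiment: it turns an in vivo free-plasma pharmacokinetic (PK) profile into
a stepwise reservoir exposure schedule a syringe-free pump setup can deliver,
plans the bench work (dilutions, volumes, pump program), and quantifies the
readouts (spheroid size from brightfield, biomarker-positive cells from
immunofluorescence).  A deliberately simple, clearly synthetic
pharmacodynamic (PD) simulator stands in for the wet-lab response so that
schedule-comparison logic can be exercised end to end.

## PK model and fitting

Free plasma concentration (nM) follows a one-compartment model with
first-order elimination `ke` and, for oral/IP dosing, first-order absorption
`ka`:

    C(t) = fu·F·Dose/V · ka/(ka − ke) · (e^{−ke(t−t0)} − e^{−ka(t−t0)}),  t ≥ t0

Multiple doses superpose; bolus input replaces the difference of
exponentials with a single exponential.  `ka = ke` is rejected (degenerate
closed form), and the flip-flop ambiguity is resolved by the convention
`ka > ke`.

Fitting minimizes squared residuals on **log** concentration over the
strictly positive samples (zeros are excluded, not imputed), which weights
the terminal phase the way standard PK regression does.  Only the composite
scale `fu·F·Dose/V` is identifiable from a single concentration curve, so
fits are parameterized as `(log scale, log ke, log(ka − ke))` — the last
coordinate enforces `ka > ke` — with a 1e-4 /h floor on rates.  Initial
values come from curve stripping: `ke` from a log-linear regression on the
last four points, `ka = 5·ke`.  A stalled optimizer sets `converged=False`
instead of raising.  Population (mixed-effects) structure, saturable
kinetics and prodrug→metabolite conversion are out of scope; the bundled
hourly profiles are treated as per-animal means.

## Schedule discretization

The support of a tabulated profile is partitioned into `n` intervals (8 by
default — one per disposable reservoir) and each interval becomes one timed,
constant-concentration step at the default 20 µL/min flow.  Two design
choices are configurable because published reservoir tables rarely state
them:

- **Boundaries.** The default rule is equal-AUC partition of the cumulative
  trapezoidal AUC (boundaries are exact quantile points of a
  piecewise-quadratic, solved per segment).  It preserves total exposure and
  degrades gracefully as `n` shrinks.  User-supplied boundaries are accepted
  and validated identically.  The convenience `mimic_schedule_from_series`
  additionally pins one hour-wide window on the peak sample (so the schedule
  reproduces the observed Cmax) and equal-AUC-partitions the rest.
- **Step concentration.** `interval_mean` (default) is the time-weighted
  trapezoidal mean of the linearly interpolated profile, which conserves AUC
  exactly before rounding; `sample_mean` averages the tabulated samples
  inside the window, the convention behind reservoir tables built from
  hourly observed data (an hour-wide peak window then holds exactly the
  sample Cmax).  Step concentrations are rounded to 3 significant figures.

Interpolation between samples is linear with no extrapolation; for post-dose
series that start at 1 h a `(0 h, 0 nM)` anchor can be prepended explicitly.
Clock convention: cycle day 1 starts at t = 0 h, steps are half-open
`[start, start + duration)` intervals, Tmax ties resolve to the earliest
time.  The bundled published reservoir table has seven drug steps (durations
1, 3, 2, 3, 3, 4, 8 h) occupying manifold positions 2–8; position 1 holds
drug-free medium for priming and washes.

Exposure metrics: AUC by trapezoid, Cmax/Tmax, time above threshold by
linear interpolation of crossings, and mismatch `∫|schedule − reference|`
with sign crossings resolved exactly on each linear segment.  For equal-AUC
boundaries on a monotone profile the mismatch is non-increasing in the step
count (verified for n = 1…16 on exponential decay) and schedule AUC matches
the reference within 1 % after rounding.

Treatment regimens tile a 24-h schedule over a 7-day cycle.  The named
tokens are `mono` (SN38 day 1), `combo_1_7` (+ATM inhibitor day 1),
`combo_7_7` (days 1–7), `combo_gap24` (days 2–4), `combo_gap72`
(days 4–6) and `control`.  The pump program serializes one record per
reservoir switch per drug-day, as delimited text and an equivalent JSON
document, and round-trips losslessly.

## Dilution planning

Stocks are DMSO solutions (defaults 0.1 mM SN38, 1 mM AZD0156).  Step 1
dispenses stock into 200 µL intermediate aliquots; step 2 pipettes from the
intermediate into each medium reservoir, sized as
`flow × duration + 5 mL spare`.  The intermediate concentration follows one
of three rules: explicit, `stock / first_step_factor` (SN38: 0.1 mM / 100 =
1 µM), or `top reservoir × second_step_factor` (AZD0156: 192 nM × 100 =
19.2 µM).  Every transfer obeys `C1·V1 = C2·V2` to 1e-9 relative and the
plan is re-simulated forward as a self-check.  Residual DMSO in a reservoir
is capped at 0.1 % v/v (a common cell-culture tolerance); transfers below
the 0.5 µL pipettable minimum are flagged for an extra serial step rather
than silently planned.

## Response simulator (synthetic)

The PD module is a stand-in for wet-lab readouts, not a mechanistic claim.
State variables are spheroid volume `V` and unresolved DNA damage `D`:

    dV/dt = V · [ kg − Emax_S·fS·(1 + α·D·fA) − Emax_A·D·fA ]
    dD/dt = kin·C_S − kout·D,            D(0) = 0

with Hill occupancies `fS = C_S/(EC50_S + C_S)`, `fA = C_A/(EC50_A + C_A)`.
The TOP1 inhibitor kills through `fS` and deposits damage; the ATM inhibitor
does nothing alone but (i) potentiates concurrent kill (α term) and
(ii) converts unresolved damage into kill while present (`Emax_A·D·fA`).
The second term is what makes *gapped* schedules differ from monotherapy:
damage decays at `kout` between the SN38 dose and a delayed ATM-inhibitor
window, so a 24-h gap preserves more of the combination benefit than a 72-h
gap.  With `α = Emax_A = 0` the combination collapses exactly onto
monotherapy.

Integration is fixed-step RK4 at Δt = 0.01 day on `(log V, D)`; working in
log volume makes the drug-free case `V0·e^{kg·t}` exact to round-off and
keeps `V > 0` (additionally floored at 1e-12·V0).  The simulator is
deterministic; measurement noise is a separate, seeded log-normal
observation step.

Defaults (`data/pd_defaults.yaml`, regenerated by
`scripts/calibrate_pd.py`): `kg = 0.30 /day`, `EC50_S = 2 nM`,
`EC50_A = 50 nM`, `kin = 1 /(nM·day)` fixed a priori at realistic scales for
low-nM SN38 and ~20–190 nM ATM-inhibitor exposure; `kout = 0.75 /day`,
`Emax_A = 0.5`, `α = 2` chosen by coarse grid search, and
`Emax_S = 1.402 /day` tuned so SN38 monotherapy lands near the published
~52 % growth inhibition at day 7.  Among grid points whose day-7 volumes
respect the published ordering

    control > mono > gap72 > gap24 > combo_1_7 > combo_7_7

with a clear margin, the selected point minimizes the log-RMS distance to
the published relative volumes (55/40/25/22/17 % of control).  Passing the
ordering tests therefore shows the simulator is a *consistent* synthetic
test-bed for schedule comparisons — it does not validate the model against
biology, and the published efficacy magnitudes remain experimental outcomes,
not simulation targets.

`%GI = 100·(1 − ΔV_treated/ΔV_control)` is undefined (rejected) when the
control fails to grow; it is invariant to volume-unit rescaling.

## Imaging

**Generator.** A disc (optionally rotated ellipse) spheroid of default
radius 150 µm at 1 µm/pixel, matching the 250–370 µm diameters typical at
treatment start.  Nuclei (default 300, radius 4 µm) are placed by seeded
dart-throwing Poisson-disc sampling at 2.5× nucleus-radius minimum spacing
(infeasible packings are rejected against a 0.55 packing-fraction capacity)
and rendered as Gaussian spots (σ = r/3, amplitude 150).  Brightfield is a
dark disc (80) on a light background (200) with softened rim; each marker
channel lights exactly `round(fraction·n)` seeded nuclei; Gaussian noise
(default SD 2) is added and clipped at zero.  Ground truth (mask, centroids,
per-marker labels) is recorded.  The generator emulates geometry, packing
and label fractions — not out-of-focus light, spectral bleed-through,
uneven illumination or 3-D occlusion — so passing tests bound algorithmic
error, not real-microscope performance.

**Quantification.** Segmentation: Gaussian smoothing (σ = 2 px), Otsu
threshold with polarity resolved from the image border, largest 8-connected
component, holes filled.  Feret diameters: rotating-calipers extents of the
convex hull of boundary pixels at 1° angular resolution, plus one pixel for
the pixel footprint.  Volume: `average_radius = (feret_min + feret_max)/4`
— the mean of the two caliper diameters, halved — and
`V = 4/3·π·average_radius³`.  Nuclei: large-scale background subtraction
(σ = 6·r), smoothing at r/2, local maxima at ≥ 2·r separation above a floor
set from the noise statistics outside the spheroid.  Positivity: mean marker
intensity in a nucleus-radius disc above background mean + 3 SD (background
sampled outside the dilated mask); the rule is a configurable strategy
because published macro thresholds vary.  γH2AX and CC3 are reported per
10⁴ µm² of spheroid projection area; Ki67 as a fraction of detected nuclei
(no area normalization needed for a ratio).  Pixel coordinates are 0-based
row-major; areas are pixel counts × pixel_size².

## Reproducibility and problem sizes

A single run seed fans out to per-module streams through
`SeedSequence(seed, spawn_key=(k,))` reduced mod 2³¹, so each module remains
independently reproducible.  Pipeline manifests list SHA-256 hashes of every
artifact; identical configurations produce identical hashes.

Test and acceptance workloads are desk-scale by design: 24-point PK series,
8-step schedules, 7-day regimens at Δt = 0.01 day, and ~380² px images with
200–400 nuclei — sizes at which every check runs in seconds while the
oracles (ODE integration, fine-grid quadrature, analytic shapes, generator
ground truth) remain exact.

## Known limitations

- The PK module fits a single curve; inter-animal variability and error
  models beyond log-normal are not represented.
- Equal-AUC boundaries are one defensible discretization; published
  reservoir tables may use hand-chosen durations, which is why user
  boundaries are first-class.
- The PD model is phenomenological; its parameters are not estimable from
  the bundled data and should not be interpreted biologically.
- The imaging pipeline is 2-D projection-based; confocal stack
  reconstruction and focus/foci morphology are out of scope.
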