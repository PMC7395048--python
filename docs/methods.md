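# Methods

## PBK model structure

The kinetic model is a perfusion-limited (flow-limited, well-stirred)
compartment system written in amounts (µmol). Methadone occupies a gut
lumen plus nine perfused compartments — liver, fat, lung, kidney, heart,
slowly perfused tissue, rapidly perfused tissue, arterial blood and
venous blood — and EDDP mirrors the perfused compartments.

For each perfused tissue T with blood flow Q_T, volume V_T and
tissue:blood partition coefficient P_T:

    dA_T/dt = Q_T · (C_art − C_T / P_T),          C_T = A_T / V_T

The lung sits in series between the venous and arterial pools
(venous → lung → arterial at total cardiac output); all tissue venous
outflows drain into the venous blood compartment. Specific terms:

- **Absorption.** Oral dosing is a bolus of Fa·dose (converted to µmol of
  free base, MW 309.45 g/mol) into the gut lumen at each dosing time;
  uptake is first order (dA_gut/dt = −ka·A_gut) and the absorbed flux
  enters the liver, so first-pass extraction emerges from the liver
  equations. The unabsorbed fraction (1−Fa)·dose is booked and never
  enters the system.
- **Metabolism.** Hepatic conversion of methadone to EDDP (1:1 molar)
  follows Michaelis–Menten kinetics in the liver venous (blood-equivalent)
  concentration CVL = C_liver/P_liver, with
  Vmax_vivo = Vmax_c · 60/1000 · MPL · (VLc·BW·1000 g) µmol/h (liver
  density 1 g/ml) and the apparent microsomal Km applied directly
  (no unbound correction, since the incubation constants are apparent
  values). No intestinal metabolism (incubations with intestinal
  microsomes produce <8% of the hepatic rate) and no further conversion
  of EDDP to EMDP (not detectable in vitro).
- **Excretion.** Renal clearance removes drug from venous blood at
  RCL·C_ven for both compounds; kidney is a distribution compartment
  only. Biliary excretion removes EDDP from the liver at kbile·A_liver
  into a feces sink without enterohepatic recirculation.
- **Cardiac output scaling.** The reference cardiac output (347.9 L/h)
  belongs to the 70-kg reference adult; for other body masses the model
  scales Qc ∝ BW^0.75, the standard allometric exponent for perfusion.
  Tissue volumes scale linearly with BW. Dose regimens are specified in
  mg/day and are not BW-normalized.

EDDP amounts start at zero and its cumulative inputs equal methadone's
cumulative metabolism exactly; a mass-balance audit (administered =
unabsorbed + compartments + renal + metabolized for methadone, formed =
compartments + renal + biliary for EDDP) stays below 1e-6 relative at the
default solver settings (observed ~1e-14).

### Numerical settings

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-8, atol 1e-10. Dosing is
implemented by integration restarts at each bolus (no discontinuity
smoothing); output is sampled at 120 points per dosing interval, enough
to resolve the interval Cmax and to make trapezoidal AUCs accurate to
<0.1% (verified against a closed-form mono-exponential). Steady state is
either the study's stated duration, or adaptive: dosing continues until
the venous Cmax of both compounds changes by <0.1% between consecutive
intervals (capped at 120 days; methadone's effective half-life in the
model is ≈25 h, so this engages after ~11 days). Simulations refuse
parameter sets whose flow fractions do not sum to 1 within 1e-9 unless
explicitly overridden (needed for one-at-a-time sensitivity
perturbations). Small negative amounts beyond −1e-6 µmol abort the run;
smaller solver wiggle is clipped to zero on output.

### Parameter provenance

Physiology is the standard 70-kg reference adult; compound parameters
(partition coefficients, blood:plasma ratios 0.70/0.87, unbound
fractions) and kinetic constants are the published values for methadone
and EDDP. EDDP's renal clearance (19.99 L/h) and biliary rate constant
(1.65/h) were originally calibrated against the steady-state EDDP blood
Cmax observed under 57.5 mg/day maintenance dosing; `fit_eddp_clearance`
reproduces that calibration for a single free parameter (fitting both to
one Cmax target is under-determined and rejected). Molar masses: free
base methadone 309.45 g/mol, EDDP 277.4 g/mol; doses are free base.

## Sensitivity analysis

Normalized sensitivity coefficients SC = ((C′−C)/(P′−P))·(P/C) with a 1%
one-at-a-time parameter increase; the output is the steady-state
methadone Cmax in heart venous blood (C_heart/P_heart), evaluated at 20
and 200 mg/day for a 70-kg adult. Both runs use a fixed 35-day regimen so
the residual approach-to-steady-state error cancels in the difference.
Volume and flow fractions are perturbed without re-normalizing the
remainder — the standard practice for this analysis — so the flow
fractions transiently sum to 1.00±0.002 and the simulator's flow-sum
check is bypassed for these runs; the compartment equations pair every
flux term, so drug mass stays conserved even with unbalanced flows (the
arterial outflow is written as the sum of tissue inflows). |SC| > 0.1 flags a parameter
as influential. Signed values are retained; headline tables show
magnitudes.

## Reverse dosimetry

The unbound in vitro concentration (C·fu_m) is equated to the unbound
steady-state Cmax in heart venous blood, converting plasma binding to
blood binding with fu_p/BPr. Because steady-state Cmax is strictly
increasing in dose (verified programmatically before translation), the
inversion is a monotone root search: log-log regula falsi on the cached
dose → Cmax map, terminating when the simulated Cmax is within 0.02% of
the target (forward/inverse round trips agree within 0.1% in dose). The
dose bracket is 1e-3 to 1e4 mg/day; targets outside the achievable range
are reported per point, never dropped silently. Four plasma-binding
scenarios (fu_p = 0.22, 0.15, 0.055, 0.034 with fu_m = 0.79, BPr = 0.70)
produce four dose–response curves; lower fu_p shifts the curve to higher
doses. The EDDP inversion (systemic venous blood output) is retained only
to show that the dose reaching the metabolite's unbound in vitro
benchmark is far above the therapeutic range; EDDP is otherwise excluded
from effect translation.

## Benchmark dose analysis

Continuous summary data (dose, mean, SD, n) are fitted by maximum
likelihood under normal errors on the group means (group variance
SD²/n taken as known). Families: 3-parameter exponential
a·exp(b·x^d), 4-parameter exponential a·(c−(c−1)e^{−b x^d}) and Hill
a·(1+(c−1)x^d/(b^d+x^d)) by default; inverse-exponential and log-normal
forms are available behind `extended_families=True`. Doses are scaled by
the maximum dose internally; d is bounded to [0.25, 8]; fits use
multi-start trust-region least squares (d₀ ∈ {0.5, 1, 2, 4}).

The benchmark response is a relative deviation (BMR, e.g. 0.20 for the in
vitro FPDc benchmark, 0.10 for the in vivo QTc analysis — 10% over the
407-ms population baseline is the conventional 450-ms abnormality
threshold) from the *fitted* control response. The model-averaged BMD
solves the Akaike-weighted average of the normalized fitted curves
(weights ∝ exp(−ΔAIC/2), ties share weight) for the BMR; BMDL/BMDU are
the 5th/95th percentiles of 200 parametric-bootstrap replicates that
resample group means ~ N(mean, SD/√n) and refit every family (restarting
from the original fit). A fit that does not beat a constant-response
model on AIC is flagged "no dose-related trend" and benchmark estimation
refuses flat data. These are this package's own conventions where the
reference web tools leave settings unstated (variance model, averaging on
the normalized curve); exact numerical replication of those tools is a
non-goal.

## MEA processing

Per-beat FPD and RR values (≥30 beats per 1-min recording) are averaged
before the Fridericia correction FPDc = FPD/∛RR (inputs in seconds;
per-beat correction is available as an option). Recordings must show a
depolarization peak ≥200 µV and a repolarization peak ≥20 µV (boundary
passes). Each treated well is normalized to its own pre-exposure baseline
(0.1% DMSO) and corrected for time/vehicle drift by subtracting the
excess response of the chip's time-matched vehicle well:
response = 100·treated/baseline − (100·vehicle_t/vehicle_0 − 100).
Concentrations showing irregular waveforms (arrhythmia-like trace,
flattened repolarization peak, beating arrest) are excluded from FPD
analysis with the reason recorded, and a concentration needs ≥3
independent experiments to enter the summary. Because the normalization
pins the control response at exactly 100, the control group enters
likelihood-based fits with a nominal 1-point SD representing measurement
resolution. Significance annotation (one-sample t tests vs the control
level with Holm adjustment) is reporting-only and never gates the
pipeline.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analysis assumes,
with truth sidecars for recovery testing:

- **MEA concentration–response**: cumulative exposure over the parent
  compound's grid (0.01–30 µM), 4 experiments × 2 treated wells + 1
  vehicle well (within the reported 4–9 wells per point and ≥3
  experiments), sigmoidal FPDc effect (Emax 80 points, slope 1.5,
  anchored so the 20%-effect concentration is 0.6 µM, the measured parent
  benchmark), linear vehicle drift (−0.5%/step) injected additively in
  response space, well-level Gaussian noise with SD 10% of response
  (approximating the published error bars; an approximation, not a
  reported value), and irregularity flags from 3 µM (beating arrest at 30
  µM), reproducing the observed exclusions. Vehicle wells carry drift but
  no response noise — a simplification that slightly understates the
  correction's variance.
- **Microsomal incubations**: the 8-point 10–1500 µM design in
  triplicate with 5% CV multiplicative noise around Vmax 0.82, Km 275.
  At this design Km has ≈10% sampling error (the published fit SD is the
  same size), so recovery checks use replicate medians.
- **Equilibrium dialysis**: chamber pairs at a 150 µM nominal sample
  concentration, triplicate × 2 experiments, 3% CV; no volume-shift
  correction is applied in the analysis (the raw ratio is used), matching
  the assay's standard evaluation.
- **Clinical kinetics**: the PBK model with ±20% uniformly perturbed
  parameters stands in for a study population; blood is converted to
  plasma via BPr and sampled over the final dosing day with 10% lognormal
  noise.

Passing recovery tests on these data shows the pipeline's estimators are
correct under their own assumptions (sigmoidal effect, additive drift,
independent Gaussian/lognormal noise). They do not establish robustness
to features real datasets may add: inter-batch potency shifts, serially
correlated drift, non-Gaussian outliers, electrode dropout, or
concentration-dependent binding.

## Problem sizes and determinism

Forward simulations integrate 23 stiff states over 11–60 dosing days in
~0.1–0.5 s; a full reverse-dosimetry translation (four scenarios sharing
one cached dose→Cmax map) takes a few dozen simulations, and benchmark
analyses use 200 bootstrap refits. All stochastic stages accept explicit
seeds and are bit-reproducible under a fixed seed; deterministic stages
are bit-reproducible unconditionally.

## Known limitations

- The compartment equations are a reconstruction of the standard
  perfusion-limited structure from the model's published parameterization
  and schematic; the renal-clearance sampling site (venous blood) and
  first-pass routing are the conventional choices, and forward
  predictions agree with the published model outputs within ~1% —
  residual structural ambiguity is absorbed by the evaluation tolerances.
- Racemic kinetics only: no R/S enantiomer separation, no CYP2B6
  polymorphism, no mechanistic α1-acid-glycoprotein binding model;
  inter-individual binding variability is represented only through the
  four fu_p scenarios.
- The in vivo translation treats the heart-venous unbound Cmax as the
  effective exposure; hysteresis, tissue accumulation of effect and
  electrophysiological dynamics are outside the model.
- Benchmark-dose settings follow documented defaults where the reference
  implementation's choices are unpublished; absolute BMDL values should
  be compared across scenarios rather than against other tools to the
  last digit.
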