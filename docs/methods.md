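# Methods

This note documents the models behind `looselayer`, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions used throughout.

## The loose-layer metric

A QCM-D adsorption run is a sequence of pump segments: baseline (buffer),
sample (protein at concentration c), rinse (buffer again). Frequency shifts
Δf (Hz, overtone-normalized) and dissipation changes ΔD (in 10⁻⁶ units) are
recorded at the odd overtones n = 3…13; overtone 3 is the primary channel.
The metric of interest is

    Δf_loose = mean Δf over the sample-end plateau − mean Δf over the
               post-rinse plateau,

and analogously ΔD_loose. A loosely interacting (reversibly bound) layer
present during sample flow but removed by the rinse makes Δf_loose < 0.
Because the irreversibly adsorbed layer contributes equally to both
plateaus, Δf_loose is exactly invariant to any constant offset common to
them — bound particulates, buffer-swap swelling shifts referenced within a
cycle — which is the robustness property the impurity tests exercise.

**Plateau definition.** "Steady state" is operationalized as a
trailing-window drift test, reusing the baseline stability rule: a window
(default 600 s) is stable when the OLS slope of Δf implies ≤ 1 Hz drift per
window and the ΔD slope implies ≤ 0.2×10⁻⁶ per window. `plateau_value`
scans trailing windows backward from the segment end in quarter-window
steps and returns the latest stable one; if none qualifies the final window
is returned flagged unstable rather than raising, so noisy real traces
still produce a value plus a QC flag that propagates into the metric.

**Segmentation.** With a known pump schedule, boundaries are taken from it.
Auto-detection works on the primary overtone: the time derivative of Δf₃ is
smoothed with both a rolling median (window 30 s; responds to sustained
adsorption/desorption ramps) and a moving average (a matched filter for
abrupt steps such as buffer swaps, whose impulse-like derivative a median
suppresses). Each channel is thresholded at 5× the robust (MAD-based)
scatter of the full-trace smoothed derivative — transitions occupy a small
fraction of a run, so the global MAD estimates the quiescent noise level —
active gaps shorter than 60 s are closed, and rising edges become
boundaries. Segments are labeled from the step between consecutive
trailing-fifth plateau levels: a drop beyond 5 Hz marks sample uptake, a
recovery directly after a sample marks its rinse, anything else (including
small buffer-swap steps) is baseline. All thresholds are keyword arguments.
On the bundled synthetic runs the detected boundaries land within ~20 s of
the true pump events.

**Multi-cycle runs.** Each sample/rinse pair is referenced to its own two
plateaus, so a sequential multi-buffer run (the BSA preset) yields one
metric per cycle and buffer-change offsets cancel within each cycle.

**Sauerbrey conversion.** mass = −C·Δf (normalized) or −C·Δf/n (raw), with
C = 17.7 ng cm⁻² Hz⁻¹ for a 5 MHz crystal. Generated traces are
overtone-normalized and flagged as such in file metadata; the analysis
honors the flag. Whether published single-value Δf₃ numbers are normalized
is generally ambiguous; the normalized convention is assumed and switchable.

## Synthetic QCM-D traces

No public instrument traces accompany the reference panel, so the generator
is the test bed. The surface model is the minimal scheme producing both an
irreversible plateau and a rinse-removable layer — two-compartment Langmuir
kinetics:

    Γ₁' = ka1·c·(Gmax1 − Γ₁)                      (base layer, no desorption)
    Γ₂' = ka2·c·(Γ₁/Gmax1)·(Gmax2 − Γ₂) − kd2·Γ₂  (loose layer, gated by base
                                                   coverage, desorbs at c = 0)

integrated with fixed-step RK4 at dt = 1 s (QCM-D sampling is ≈1 Hz).
Steps coarser than the fastest kinetic timescale 1/(ka·c + kd) are refused.
Concentration is piecewise constant; each RK4 step uses the segment
containing its midpoint so grid-aligned boundaries are exact. Signals are

    Δf_n(t) = −(Γ₁+Γ₂)/C + drift·t + buffer_offset + ε_f,
    ΔD_n(t) = α₁Γ₁ + α₂Γ₂ + ε_D,      α₂ > α₁ (loose mass is softer),

identical across overtones (rigid film) with independent Gaussian noise per
channel (defaults σ_f = 0.15 Hz, σ_D = 0.05×10⁻⁶ — typical bench noise).
The analytic loose-layer equilibrium Γ₂_eq = Gmax2·ka2·c/(ka2·c + kd2) is
the oracle the tests check against, and is how presets are calibrated:
given a target Δf_loose, Gmax2 = |Δf_loose|·C/(ka2·c/(ka2·c + kd2)). The
eight panel presets therefore reproduce their consensus means exactly in
the noiseless limit; their kinetic constants are otherwise arbitrary
(shared ka1 = 0.002 mL mg⁻¹ s⁻¹, Gmax1 = 450 ng cm⁻², ka2 = 0.005,
kd2 = 0.01 s⁻¹), since only the steady-state metric is constrained by
published data. The BSA preset runs three sample/rinse cycles in acetate,
histidine, phosphate (targets −60, −53.9, −47.6 Hz) with per-buffer loose
capacities and buffer offsets of 0/+6/+11 Hz.

What the generator does *not* emulate: viscoelastic (Voigt) film response
and overtone-dependent penetration depth, bulk-viscosity shifts from
high-concentration samples, temperature transients, flow artifacts, or
spike-like disturbances. Passing tests therefore validate the reduction
logic and its statistical behavior under Gaussian noise and drift, not
performance on viscoelastic films.

## DLS and kD

Diffusion series follow D(c,T) = D0(T)·(1 + kD·c/1000), c in mg/mL, kD in
mL/g. Temperature enters through Stokes–Einstein at constant radius,
D0(T) = D0_ref·(T/T_ref)·(η_w(T_ref)/η_w(T)), with water viscosity from the
Vogel closed form η_w = 0.02939·exp(507.88/(T_K − 149.3)) mPa·s (smooth and
accurate over 0–40 °C). Defaults: D0_ref = 4.0×10⁻⁷ cm²/s at 20 °C
(a ~5 nm-radius IgG), replicate noise 1% of D0.

When autocorrelation output is requested, curves follow the second-order
cumulant model g₂(τ) = baseline + β[exp(−Γτ)(1 + μ₂τ²/2)]², Γ = q²D, with
q = 4πn₀sin(θ/2)/λ. The reference instrument's wavelength is 825 nm; the
scattering angle and refractive index are not usually reported, so they are
configurable with defaults 150° and 1.33 (D-valued input bypasses optics
entirely). `cumulant_fit` seeds a nonlinear least-squares fit from a
log-linear fit of ln(g₂ − baseline)/2; order 1 pins μ₂ = 0; negative fitted
μ₂ is kept but the reported PDI clips at 0 with a flag.

`fit_kd` pools replicate points into one OLS fit (preserving leverage for
prediction bands) and reports kD = 1000·slope/intercept with a delta-method
95% CI from the coefficient covariance; a `per_replicate` mode fits each
run separately and summarizes between-run scatter, since published kD ± SD
values are typically per-run SDs. On the simulated study conditions (nine
concentrations 1–5 mg/mL, three replicates, 1% noise) the delta-method CI
covers the truth ~95% of the time.

**Impurity spiking.** 1 μm polystyrene beads (Rh = 500 nm; Stokes–Einstein
gives D ≈ 4.3×10⁻⁹ cm²/s at 20 °C) enter as an intensity fraction φ rather
than through Mie optics, which the available inputs do not constrain.
D-valued rows become the z-average harmonic mix
D_app = 1/((1−φ)/D + φ/D_imp) with replicate noise inflated ×5 (bead-count
fluctuations in the scattering volume dominate the signal); g₂ curves gain
a second exponential with rate q²·D_imp and weight φ. At φ = 0.3 the kD CI
widens ~4–5× while the loose-layer metric, by its offset invariance, moves
only within its noise bound — the robustness contrast the acceptance test
asserts.

**Temperature sensitivity.** `temperature_sensitivity` requires a full
c × T grid and reports the mean |ΔD| over adjacent temperature steps
(averaged across concentrations) and over adjacent concentration steps
(averaged across temperatures). Because the generator is multiplicative,
the *relative* per-degree change is concentration-independent (asserted to
10⁻¹² in tests). On the 20–26 °C × 1–5 mg/mL grid with the default
kD = 51.7 mL/g the model gives 1.35×10⁻⁸ cm²/s per 1 °C versus
1.12×10⁻⁸ per 0.5 mg/mL — the per-degree term dominates, which is the
practical point: a 1 °C error moves D as much as a whole 0.5 mg/mL
concentration step. A caveat discovered while deriving the closed form:
the ordering crosses over at kD ≈ 64 mL/g on this grid, so for the most
repulsive molecules the two sensitivities are comparable; the property
tests assert the ordering for kD up to 60.

## Panel statistics

Behavior ranks assign 1 to the best-behaved molecule — the least-negative
Δf₃_loose, the largest kD — with average ranks for ties. Spearman ρ is the
Pearson correlation of the rank vectors. The exact two-sided p-value
enumerates all n! permutations of the y-ranks (refused for n > 10) and
counts |ρ_perm| ≥ |ρ_obs| − 10⁻¹²; the tolerance avoids float-equality
misses at permutation-symmetric values. The t-approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df is reported alongside, because published
small-panel p-values rarely state their method; for the reference
eight-mAb panel the two give 0.0218 (exact) and 0.0149 (t). Relative error
is 100·SD/|mean| — the one simple formula consistent with every printed
cell of the reference panel. The bundled panel table itself (eight mAbs,
means ± SD for both metrics) is data, not computation; everything else in
the report is derived from it at run time.

## Viscosity and opalescence

Viscosity above the crowding onset is fit as η(c) = a·e^{bc} by OLS on
ln η (two parameters; multiplicative noise is the natural error model for
positive, exponentially growing data and makes prediction bands exact
linear-regression intervals on the log scale). The 95% prediction interval
at c₀ is ln ŷ ± t_{n−2}·s·√(1 + 1/n + (c₀−c̄)²/Sxx), exponentiated. Shear
rate columns are accepted and ignored (measurements in the relevant range
are shear-independent). Opalescence is the blank-subtracted mean OD over
exactly {340, 345, 350, 355, 360} nm, averaged across replicates.

## Numerical conventions and edge cases

- Determinism: every stochastic routine consumes a seed from the scenario;
  identical inputs give bit-identical outputs, and table I/O round-trips
  floats exactly (`float_precision="round_trip"`).
- Unstable plateaus flag rather than fail; validation errors
  (non-monotone time, missing f3, ragged grids, too-few concentrations)
  raise typed exceptions; the CLI maps them to exit code 2, QC failures to 3.
- Positive Δf in the Sauerbrey conversion returns the (negative) mass
  as-is rather than raising.
- The loose-layer subtraction is implemented as sample-plateau minus
  rinse-plateau, which gives the conventional negative sign for a loose
  layer.

## Problem sizes

Defaults keep everything lightweight: QCM-D runs are 4 500 s at 1 Hz
(BSA: 12 900 s), kD studies use 9 concentrations × 3 replicates, recovery
and coverage studies use 100 simulated series per condition, and
prediction-band coverage uses 500 fits. The full test suite runs in ~20 s
and the acceptance script in ~4 s on one core.
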