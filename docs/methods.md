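# Methods

## Physical conventions and units

Piezo height `z` increases toward the sample; deflection `d` is positive
when the cantilever is pushed up; force is positive in compression;
indentation `δ` is positive into the sample. Arrays are stored in µm, nN
and s (so nN·µm integrates directly to fJ and spring constants in N/m enter
through one explicit ×10³ factor); moduli are in Pa, viscosities in Pa·s.
The curve-file dialect is UTF-8 TSV with `#`-prefixed `key: value` header
lines whose keys carry the units (`spring_constant_N_per_m: 0.32`), one
curve per file.

Probe defaults: spring constant 0.32 N/m, bead radius 2.25 µm (a 4.5 µm
silica microbead; some summaries round this to 5 µm — the radius is
configurable), approach speed 5 µm/s, setpoint 1 nN. The 1 nN setpoint is
the "safe" load: applied forces up to 10 nN do not alter cortical-granule
release or aging dynamics, so 1 nN operates with a wide margin.

## Preprocessing

Baseline correction fits a line in `z` to the first 30% of approach samples
(assumed non-contact; grid acquisitions start well off the surface) and
subtracts it from the deflection of all segments. Contact is detected as
the first `z` after which force exceeds 3× the baseline noise SD for 5
consecutive samples; the sustained-run rule guards against the rough,
mesh-like ZP surface producing spurious single-sample crossings. Indentation
is `δ = (z − z_c) − (d − d(z_c))`, i.e. piezo travel minus cantilever
bending past the contact point.

A threshold detector necessarily fires *late*: on a layer of modulus E the
detected point sits ≈ (3σ·3/(4 pref·E))^{2/3} past true contact — about
0.4 µm on a 50 Pa outer layer at 1% force noise. All fits therefore carry
the contact position **and a constant force offset** as co-fitted nuisance
parameters; without the offset term, subtracting the deflection at the
late-detected contact biases moduli upward by ~5–10%.

## Elasticity fits

Single layer: nonlinear least squares of `F = pref·E·(δ−δ₀)^{3/2} + F₀`
over (E, δ₀, F₀), `pref = (4/3)√R/(1−ν²)`, E bounded to [1, 10⁶] Pa, with
five deterministic multistarts over δ₀ (seeded from a hash of the data, so
refits are reproducible). ν = 0.5 throughout (incompressible soft matter;
configurable — no measurement of ν exists for these samples).

Two layers: the additive model `F(δ) = H(δ; E1) + H(δ−δ_c2; E2′)·[δ>δ_c2]`.
The search runs a grid over candidate first-contact refinements (9 values
spanning 0.6 µm before to 0.2 µm after the detected/single-layer contact —
wide enough to contain the detection lateness of a soft outer layer) and
second-contact depths (interior order statistics of the in-contact samples,
≤ 60 candidates at sample resolution), solving a closed-form two-column
nonnegative least squares for (E1, E2′) at each node with the constant
offset projected out by mean-centering; the best node seeds a bounded
5-parameter polish. This avoids the nonconvexity of a cold 5-parameter fit
while keeping the final estimate continuous in the contact points.

Reported-E2 convention: the quoted E2 is the modulus a single-layer fit
restricted to the post-δ_c2 regime would report on the combined response
(the second slope, which is what is quoted for oocytes), computed by
projecting the fitted model onto the `(δ−δ_c2)^{3/2}` basis. The additive
component E2′ is preserved alongside; the mapping lives in one function
(`second_regime_modulus`) so a different convention (e.g. a piecewise
model) can be swapped in without touching the search.

Nested-model support: the second contribution is accepted only if it
improves the residual sum of squares by >5% over the single-layer fit and
δ_c2 is interior to the fitted range; otherwise the curve is reported as
single-layer (E2 = E1, δ_c2 = NaN, flagged). On truly single-layer input
this is the expected outcome, not an error.

Grid protocol: 3×3 positions × 3 replicates = 27 curves per oocyte; means
and SDs are taken over converged fits, with per-position means retained
because the within-cell scatter of E1 (irregular outer glycoprotein
surface) far exceeds that of E2 — the reason E2, not E1, is the aging
readout.

## Viscoelasticity

Dissipated energy: the retract branch is linearly interpolated onto the
approach indentation grid over the overlapping range, both branches are
clipped at F > 0, and the difference is integrated by the trapezoidal rule.
On piecewise-linear cycles this equals the shoelace polygon area exactly
(tested). A negative result beyond 3× the supplied noise bound is flagged
rather than silently clipped.

Maxwell fit: two-stage log-linear peel-off initialization (offset from the
trace tail; slow element from the last 40% of the hold; fast element from
the first 20% after subtraction) followed by bounded least squares of all
five parameters; output ordered τ₁ < τ₂. When τ₂/τ₁ < 1.5 or an amplitude
falls below 3× the residual SD, two exponentials are statistically
indistinguishable at these trace lengths and the fit falls back to a single
element with a flag; compartment assignment (ZP ← fast, ooplasm ← slow)
refuses fallback fits. Strain history during the 2 µm/s loading ramp is
ignored and t₀ is the end of the ramp — only the hold is fitted.

The Maxwell element relation is implemented as τ = η/E (hence η = τ·E);
one printed form of this relation is typographically garbled and is *not*
followed literally.

## Fluorescence

Profiles are bilinear line interpolations at ≤1 px spacing; the default
placement is radial lines at equally spaced angles through the intensity
centroid (the placement of the replicate profiles is not otherwise
specified, and radial lines cross the PVS ring perpendicularly). Background
is the median of the nearest 25% of flanking samples on each side of the
peak window; the default window is the widest interior run exceeding
background + 2× flank SD on the first frame, reused across frames (the
cell does not move between acquisitions). Five profile areas per cell and
timepoint are averaged; longitudinal series are divided by their first
value. Peak areas are invariant to additive background and linear in gain
(property-tested).

## Statistics

One-way ANOVA (F), Kruskal–Wallis (H with tie correction) and Mann–Whitney
(U by pair counting; continuity-corrected normal approximation with tie
correction) are implemented from the standard formulas and cross-validated
in the tests against an independent reference implementation and against
exhaustive enumeration at small n. α = 0.05 throughout.

The headline summary compares each aligned hour's values against the
baseline group (each oocyte's first measurement) and flags the first hour
with p < α per metric, with the direction of the change. No
multiple-testing correction is applied by default, matching the source
analysis; a per-hour-test calibration property (rejection fraction ≤ α +
2·binomial SE on no-effect cohorts) is enforced in the tests. Hours with
fewer than 5 observations are summarized but not tested. Measurements are
hourly and never interpolated; missing hours stay missing. A degradation
observed exactly at the classification horizon counts as degraded
(closed-interval rule, configurable). Yield percentages are rounded
half-up to integers, the printed-table convention; the pipeline computes
percentages from counts and will therefore disagree with any misprinted
table entry.

## Synthetic generators

Force curves invert `z(δ) = z_c + δ + F(δ)/k` on a fine grid to produce a
uniformly sampled piezo sweep that stops at the setpoint; Gaussian force
noise (default 1% of the 1 nN setpoint) is mapped back to deflection.
Hysteresis is phenomenological: the retract force is the approach force
scaled by `1 − 0.25·h·(v/5 µm s⁻¹)` with `h` a viscosity index — the
dissipation measurement needs only ordinal fidelity in `h` (tested as a
strict rank ordering), not a viscoelastic contact solution. Because the
reported E2 is a regime slope, the generator inverts the same convention
(fixed point on the additive component modulus) so that a requested
"E2 = 160 Pa" is recoverable by the fitter; the clip `E2′ ≥ 0.5 Pa`
engages only for extreme jitter draws.

Grids jitter the per-position moduli lognormally with CV 40% (E1) and 7%
(E2), reproducing the observed heterogeneity contrast. Relaxation traces
use a₀ = 0.5, a₁ = 1.0, a₂ = 0.5 nN, τ₁ = 1 s, τ₂ = 10 s (representative
values on the correct scales; no canonical amplitudes are published) with
1% noise on a 30 s hold. Fluorescence stacks are a disk-shaped ooplasm with
an annular PVS ring under Poisson + Gaussian noise; photobleaching scales
the whole frame exponentially to a 20% loss over 90 min; the default
19-frame, 5-min cadence keeps stacks small — only the 90-min endpoints
matter for the bleach ratio. Cohorts hold 15 healthy + 20 degrading
oocytes; degrading oocytes draw a degradation time U(4, 7) h, double E2 at
−1 h with 0.7× post-peak softening at 0 h, halve dissipation from −1 h,
and ramp the CG signal from −2 h (so the fluorescence rise leads the
stiffness jump by ~1 h). Cohort generation emits value-level timelines by
default; per-hour curves are an optional detail level, since the
headline-calibration property repeats cohort generation 500 times.

Every generator is a pure function of (config, seed) — bit-identical
across runs — and logs its truths (including noise-free force backbones)
in a sidecar, so estimators are scored without re-reading the config.

## What the synthetic tests do and do not show

Passing recovery tests demonstrates that the estimators are unbiased and
precise *under the generating model*: additive two-regime elasticity,
proportional hysteresis, exact double-exponential relaxation, a stationary
ring geometry, and i.i.d. Gaussian/Poisson noise. Real curves add adhesion
on retract, bottom-effect stiffening at deep indentation, drift that is
not linear in z, cell movement between frames, and relaxation spectra with
more than two modes — none of which the generators emulate and all of
which are explicit non-goals. The two-layer model is one declared
interpretation of a two-slope response; finite-thickness corrections,
JKR/DMT adhesion, >2 layers, and Ting-style viscoelastic contact are out
of scope.

## Problem sizes

Default test/acceptance scales: 600-sample curves, 30–50 curves per
recovery cohort, 100 relaxation traces, 19-frame 128² stacks, 500 null
cohorts of 8 oocytes for flag calibration. The full suite runs in well
under a minute on one CPU; the acceptance script in a few seconds.
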