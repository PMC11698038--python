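# Methods

This note documents the models, conventions and numerical choices behind
`springboard`, and what the synthetic-data tests do and do not establish
about real recordings.

## Measurement model

**Coordinates.** +x is the jump direction, +y up, origin at the undeflected
platform surface beneath the animal. Recordings filmed in the opposite
direction must be mirrored before entering the pipeline. All calibrated
quantities are SI; angles are reported in degrees.

**Take-off velocity** is the Euclidean chord of the body landmark between
the last frame of tarsi–platform contact and the frame 10 ms later, divided
by 10 ms. The window must be an integer number of frames (10 frames at the
default 1000 fps); other frame rates are accepted only if 10 ms remains an
integer frame count. No gravity correction is applied over the window:
over these masses and distances gravity is a 1–2% term in the energy
budget and is excluded everywhere, which also keeps the chord an unbiased
estimate of the separation speed in the simulator's gravity-free flight.
Frames missing inside the required set (last contact, +10 ms, the tarsus
pair) are hard errors, never interpolated — those exact frames are what a
digitizer would have placed by hand.

**Elevation** is measured relative to the *deformed* platform plane: the
line from the platform's clamped end to the displaced tarsus point at last
contact. This makes jump direction comparable between rigid and sagging
substrates. The sign is positive above the plane in the jump direction;
values are wrapped to (−180°, 180°]. A zero take-off displacement leaves
elevation undefined and raises an error.

**Acceleration distance** treats femur and tibia as an isosceles two-bar
linkage: x = √(L_f² + L_t² − 2 L_f L_t cos α). Femur length defaults to
tibia length. The body landmark (leg joint or pronotum tip, whichever stays
visible) is recorded per animal but no offset correction to the centre of
mass is applied — the two landmarks differ by a roughly constant offset
that cancels in the displacement chord. Mean acceleration is v/t, not a
peak value: only v and t are observable from the two-position protocol.

## Energetics

KE = ½ m_g v² and P = KE/t hold exactly by construction. The effective leg
stiffness is k_g = m_g v²/x², i.e. the linear spring that would deliver the
observed kinetic energy over the stroke; ½ k_g x² ≡ KE is a tested
identity.

**Muscle mass.** Energy and power densities are normalized by
jumping-muscle mass, which is rarely weighed directly. The default muscle
mass is a fixed fraction f of body mass with f = 0.0418, obtained by
back-solving f = ½v²/KED from the control-population means (v = 1.44 m s⁻¹,
KED = 24.79 J kg⁻¹): normalizing by whole body mass is arithmetically
inconsistent with densities of that magnitude (½v² ≈ 1 J kg⁻¹). The
fraction is configurable per run and a measured muscle mass column, when
present, overrides it.

## Platform model

Per-line stiffness from load–deflection calibration is the mean over
entries of k = m·g/δ (g = 9.81 m s⁻²); a least-squares-through-the-origin
option exists but the per-entry mean matches how manual weight-by-weight
measurements are taken and is robust to one bad entry. Each line is one
linear spring: large-deflection nonlinearity of the wooden board is
ignored.

Synthetic profiles use the Euler–Bernoulli end-loaded cantilever,
k(L) = 3EI/L³ with I = b h³/12, evaluated at marked lines every 0.05 m from
the clamp; line 1 (closest to the clamp) is stiffest by construction. The
default effective modulus for the 2 mm basswood sheet is 2.5 GPa, chosen
so the ten-line profile of the long board spans ≈0.3× to ≈300× a
3.4 N m⁻¹ jumper — bracketing the 30%–200× span such experiments aim for.
For dynamics the overhanging board is lumped into a tip mass of 33/140 of
the overhang mass (first-mode Rayleigh coefficient of a uniform
cantilever, configurable).

## Normalization and statistics

Per-animal control means are computed from rigid-surface jumps only; an
animal without controls is an error, not a silent drop. Ratios are used for
every variable except elevation, which is differenced (a polar quantity has
no meaningful ratio). Regimes split at the across-animal mean control k_g:
`compliant` strictly below, `stiff` at or above (the measure-zero tie goes
to stiff, since the strict-inequality split leaves it undefined).

One-sample two-sided t-tests compare each platform line's normalized
values against 1.0 (0.0 for elevation). A Shapiro check at α = 0.05 flags
non-normal samples; for those a Wilcoxon signed-rank result is reported
alongside the t-test rather than replacing it, so the two can be compared.
Zero-variance samples are an error (the statistic is undefined).

Regime models are linear mixed-effects fits (statsmodels `MixedLM`, REML)
with platform stiffness as covariate and a per-animal random intercept; in
the stiff regime platform type enters as a fixed factor with an initial
stiffness×type interaction that is dropped and the model refitted when its
p ≥ 0.05. The stiffness covariate is rescaled internally (divided by its
standard deviation) for conditioning and estimates are transformed back;
this leaves F, p and the intercept untouched. Per-term F statistics use
Wald chi-square over numerator df, with a between–within (containment)
denominator df, n − rank(X) − (groups − 1); a Satterthwaite approximation
would need the variance-parameter covariance, which `MixedLM` does not
expose. Slope recovery and confidence-interval coverage — the properties
the tests verify — are insensitive to this df choice. No multiple-testing
correction is applied across variables.

## Simulator

One-dimensional dynamics along the leg-thrust axis:

    m_g s̈_g = F_leg
    m_p s̈_p = −k_p s_p − c ṡ_p − F_leg

with damping c = 2ζ√(k_p m_p), ζ = 0.02 by default (no damping data exist
for such boards; the value is configurable and results quoted here are
insensitive to it below ζ ≈ 0.1). Contact is unilateral: F_leg ≥ 0 and
take-off occurs when the contact force reaches zero, which under both
force profiles coincides with the leg reaching full extension. Flight is
ballistic without gravity, consistent with the analysis' energy
bookkeeping. The elevation angle resolves the 1-D solution geometrically
into the camera plane; platform tip displacement lies along the same axis,
so rendered plane angles follow directly.

**Leg force profile.** Two conservative profiles share the same stored
energy ½ k_g x² and hence the same rigid-substrate take-off speed
x√(k_g/m_g):

* `linear_spring`: F = k_g (x − ext) — the textbook pre-compressed spring.
  Its force steps to k_g·x at release, which on a platform much stiffer
  than the jumper deposits ≈ k_g/k_p of the stored energy into tip
  ring-down. That ringing is an adiabatic invariant: no platform mass or
  damping choice returns it, so take-off speed caps near √(1 − k_g/k_p)
  of rigid even on boards 10× stiffer than the animal — contradicting the
  observed insensitivity of take-off velocity on stiff substrates.
* `leg_linkage` (default): F = C (x − ext)(ext + d), with d = 0.1·x and C
  set so the work over the stroke is exactly ½ k_g x². This folds the
  extending leg's varying mechanical advantage into the force law: ground
  force rises from a small value at full flexion, peaks mid-stroke and
  falls to zero at take-off, the shape measured ground-reaction forces of
  spring-actuated jumps actually have. The soft onset excites essentially
  no ring-down, so stiff platforms return what they borrow and the
  simulated regime structure matches the experimental one: speed losses
  only for k_p < k_g, ≥98% of rigid speed for k_p ≥ 10 k_g, and
  recoil-before-take-off on a light stiff board (k_p = 24 N m⁻¹,
  m_p ≈ 0.25 g bottoms out ~8 ms before take-off and springs back while
  loaded).

The energy ledger tracks leg-spring PE, jumper KE, platform elastic PE,
platform KE and dissipated heat per frame; with ζ = 0 the ledger closes to
better than 10⁻⁶ of the stored energy (tested at ≤10⁻³ across a 20-point
stiffness×mass grid). Momentum bookkeeping integrates the wall force so
that system momentum equals the external impulse to integrator tolerance.

**Integration.** `scipy.solve_ivp` with LSODA, rtol 1e-9 / atol 1e-12,
event-terminated contact phase followed by a 20 ms flight phase, densely
sampled on the camera frame grid. `k_p = inf` freezes the platform exactly
(no stiff ODE). A configuration that never reaches take-off within 1 s
raises an error with the config echoed.

**Rendering.** Recordings mimic the digitization protocol: the body
landmark sampled every frame with 5 stationary pre-roll frames, the tarsus
point at exactly two frames (first movement, last contact), independent
Gaussian noise of sd 0.1 mm (≈0.2 px at typical magnification) added to
every coordinate, seeded for exact reproducibility. The last-contact frame
is the last camera frame at or before separation, so rendered chords carry
the same sub-frame quantisation real recordings do.

## Synthetic demo population

The generator draws per-animal morphometrics around the study-population
control means (body mass 1.13 g, tibia 15.6 mm, take-off angle 113°,
k_g ≈ 3.42 N m⁻¹), with standard deviations recovered from the printed
standard errors at n = 40; per-jump stiffness jitter is 2% and elevation
is drawn around 43.5° (clipped to the observed 19–69° range). Each animal
contributes 3 control jumps, one jump per line of the long board and two
of the short board. What it does **not** emulate: landmark occlusion and
tracking dropouts, non-Gaussian digitization blunders, animal fatigue or
behavioural refusal, off-axis (3-D) jump components, and distributed-beam
platform modes beyond the single lumped tip mode. Passing tests therefore
validate the arithmetic and the inference machinery under the stated noise
model, not robustness to those artefacts.

Along the real tapered board, effective tip mass grows with overhang while
stiffness falls, so the outermost lines sit in a momentum-exchange regime
(jumper KE fraction ≈ m_p/(m_g+m_p)) that can flatten or even invert the
within-regime velocity–stiffness slope; the statistical battery treats the
slope as an empirical quantity either way.

## Problem sizes and tolerances in the test suite

Worked-example checks run closed-form. Simulator properties use a 20-point
conservation grid, a 10⁶ stiffness-ratio rigid-limit check at 0.1%,
end-to-end k_g recovery over 50 seeded rigid recordings at 0.1 mm noise
(mean absolute error bound 5%; observed ≈1.6%), and mixed-model slope
coverage over 100 seeded datasets of 6 animals × 8 jumps (≥90/100
required). The full suite completes in well under a minute on one core.

## Known limitations

* The deformed platform plane uses the only two platform references the
  protocol digitizes (clamp and tarsus point); board curvature between
  them is ignored.
* Mixed-model denominator df are containment, not Satterthwaite (see
  above); p-values for small animal counts are correspondingly
  approximate.
* The simulator is 1-D along the thrust axis; elevation is resolved only
  geometrically, so it cannot generate elevation *changes* caused by the
  platform (the experimental finding that elevation is unaffected is an
  assumption here, not an output).
* Resonance-frequency analysis of board and jumper is out of scope.
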