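# Methods

`decobubble` simulates decompression bubbles as a vascular phenomenon:
dissolved inert gas stored in the tissues during an exposure returns to
the blood after decompression, and bubbles nucleate, grow and detach at
surfactant patches (active hydrophobic spots, AHS) on the luminal
vessel wall. This note records the model, its assumptions, the
parameter defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Gas loading and unloading

Tissues are treated as eight well-mixed, perfusion-limited inert-gas
stores (seven aqueous — four visceral, three lean — and one adipose).
Each compartment's tension approaches the inspired inert tension
exponentially with its half-time; the mixed-venous tension is the
perfusion-weighted mean. The inspired tension is
`(ambient − water_vapor) × inert_fraction`, with the alveolar
water-vapor default 6.3 kPa (configurable; the saline-bath chamber
fixture is run with 0, since no alveolar stage is involved).

The compartment half-times (2.5, 5, 10, 20, 40, 80, 160, 300 min) and
perfusion weights (0.30 … 0.03) are implementation defaults spanning
the fast-viscera-to-adipose range; no authoritative table is bundled,
and both are overridable per run. The integrator holds the inspired
tension at its mid-step value inside each sub-step (profile pressure
linearly interpolated, profile sample times always included in the
grid) and applies the closed-form exponential update. This midpoint
rule is second-order: at the 15 s default step the fastest compartment
agrees with a tenfold-refined run within 0.1 kPa even across the 5-min
compression/decompression ramps used in the fixtures. Single inert gas
only; diffusion-limited tissues, multi-gas mixtures and oxygen-window
effects are out of scope.

## Arterial inert-gas loading

For a segment with internal radius `r`, intima-media wall thickness `W`
(the diffusion barrier; the blood-rich adventitia belongs to the
well-mixed tissue), flow `V` and diffusion coefficient `D`, the blood
tension at distance `x` from the entrance is

    Px = PT − (PT − P0) · exp(−(2π r D / (W V)) · x)

the steady-state solution of `dP/dx = (2πrD/WV)(PT − P)`. The exponent
includes `r`; this is the only dimensionally consistent form and is the
one implemented (verified against a forward-Euler march of the ODE to
1e-6 relative error). Segments are stored in clinical units (cm, mL/s,
mm) and converted to SI at a single boundary. Chaining feeds each
segment's exit tension to the next; "% rise" always means
`100·(Px − P0)/P0`.

The packaged aorta → common carotid → internal carotid → anterior
cerebral path uses representative adult human dimensions assembled from
the vascular-anatomy literature (the JSON is labelled synthetic and
fully editable). `D` defaults to 1.1331e-9 m²/s: it was calibrated
once, within the physically plausible aqueous-tissue range 1–3e-9 m²/s
for nitrogen, so that the full-flow rise at the end of the path with
PT = 500 kPa and P0 = 101 kPa is exactly 1.0%, and then frozen;
`calibrate_diffusivity` re-derives it for any other tree.

**Structural bound on flow-reduction amplification.** Reducing the flow
of one segment by a factor `f` multiplies only that segment's exponent
by `1/f`. Because the total exponent is additive over segments and
`1 − e^(−K)` is concave, the end-of-path rise with the terminal
segment at 10% flow can never exceed ten times the full-flow rise —
with the default path it is 3.64% against the 1.00% baseline. Larger
amplification would require concurrent flow reduction in upstream
segments, a longer low-flow distal path, or tension re-equilibration
mechanisms outside this steady-state model. This bound is a property of
the equation itself, independent of the tree geometry or of `D`.

## AHS population variability

Three fitted frequency curves drive the samplers:

* subject sensitivity (bubbles/h): `0.0582 + 0.7419·e^(−0.0278·b)`
* spot productivity (bubbles in 1 h): `1.256·e^(−1.139n) + 0.078·e^(−0.1632n)`
* AHS density on the wall: a six-bin histogram.

The curves are frequency *fits*, not normalized densities (the
productivity curve is 1.334 at n = 0), so they are treated as
unnormalized weights truncated to finite support: b ∈ [0, 250]
bubbles/h and n ∈ {1…50} by default (the axis ranges are not published;
both are configurable). Sensitivity is sampled by exact inverse-CDF of
the uniform + truncated-exponential mixture; productivity by normalized
discrete choice. The six density-bin weights are not published either:
the default (geometric decay 32:16:8:4:2:1 over centers 0.5–5.5
spots/cm²) is a synthetic stand-in, flagged as such in the code.

Age and acclimation are qualitative mechanisms given minimal monotone
forms: the age multiplier on AHS count and patch area is
`1 + 0.02·(age − 20)` per year (floored at 0.2), and each detached
bubble strips a fixed fraction (default 0.05) of the spot's remaining
DPPC pool, whose value is also the spot's productivity multiplier.
Slope, reference age, floor and stripping fraction are all exposed.

## Bubble dynamics

**Initiation (Phase I).** The time for a spot to produce its first
0.1 mm bubble is gamma-distributed with mode 45 min and SD 20 min
(shape 6.92, scale 7.60), supported on (0, ∞) so completion extends
beyond one hour. Only the family's mode is empirically anchored; the SD
and the gamma family itself are configurable choices.

**Growth (Phase II).** Diameter grows linearly at a rate proportional
to the venous supersaturation (diffusion-driven growth at nearly
constant blood tension). The observable anchoring the rate is the
Phase-II *duration*: at the reference exposure (saturation at 1000 kPa,
surface return; supersaturation ≈ 899 kPa) a bubble takes 2–24 min to
go from 0.1 mm to its detachment size. Each bubble therefore draws a
log-uniform reference duration T ∈ [2, 24] min and gets
`k = (d_detach − 0.1)/(T · 899)` mm/min/kPa, scaled linearly by the
actual supersaturation. Conditional on the mean 1.0 mm detachment
diameter this reproduces rates of 0.0375–0.45 mm/min at the reference
exposure. Drawing the rate *independently* of the detachment size was
rejected: it puts ~5% of bubbles beyond 24 min and ~15% under 2 min,
contradicting the observed duration window. Growth-time evaluations use
the model's stated assumption that venous tension is constant over the
short growth period, taking the supersaturation at its
post-decompression onset (peak mixed-venous minus surface pressure).

**Detachment.** Bubbles detach by buoyancy. Volumes are
`V = V(0.4 mm) + Exp(s)` with `s` solved (quadrature + bisection,
s ≈ 0.6615 mm³) so the mean equivalent-sphere diameter is 1.0 mm; the
0.4 mm support minimum encodes that smaller detachments are essentially
never seen, which is also why tiny arterialized bubbles from the AHS
are not expected. Two volume-to-force conversions ship deliberately:
the empirical constant 9.80×10⁻⁷ N/mm³ (default; a 4.2 mm sphere
weighs 38×10⁻⁶ N under it) and a physical ρg mode at 9.81×10⁻⁶ N/mm³.
They differ tenfold and the discrepancy is preserved, not corrected;
detachment is triggered by the sampled volume, which is equivalent to a
force threshold under either linear conversion. Pulsatile flow does not
trigger early detachment, so no shear term exists.

**Activation.** Repeat detachments from one spot follow
`t(s) = 1.657 + 13.81·e^(−0.03833·s)` min between detachment `s−1` and
`s`, with unit-mean lognormal jitter (sd 0.25, configurable; set 0 for
exact intervals). The first detachment instead comes from initiation +
growth, since Phase I dominates it. DPPC stripping divides intervals by
the remaining pool; a spot's total output is capped by its productivity
draw scaled to the window length. Whether activation persists across
exposures is a per-site state (`sequence`, `dppc_pool`) the caller can
reset or carry over.

## Risk aggregation

Detachment records over a window become per-hour venous counts and
volumes. Three arterialization pathways: PFO and IPAVA shunt fixed
fractions of the venous count; distal formation counts flow-restricted
tree segments whose blood tension exceeds ambient by a threshold
(default 10 kPa). Arterial delivery splits 8:1 brain:spinal. Risk tiers
are ordinal only — score `(venous/h + 10·arterial/h)·(1 + b/50)` with
boundaries 1 and 20 — because no clinical-incidence calibration is in
scope; the thresholds are documented defaults, nothing more.

## Synthetic data and what passing tests show

The fixture generators produce square, yo-yo and saturation-chamber
pressure profiles and seeded subject populations (independent
`SeedSequence` substreams per subject, so removing one subject never
perturbs another's draws). They emulate the *study conditions* —
idealized pressure schedules, population draws from the fitted curves —
not real dives: no thermal or exercise modulation, no breathing-gas
switches, no measurement noise, and vessel-patch areas are nominal.
Tests passing on these fixtures therefore validate the mechanism's
internal consistency and its agreement with the fitted curves and
printed anchors, not predictive accuracy on human dive outcomes.

Problem sizes used by the verification scripts — 10⁵ draws for the
detachment and initiation statistics, 10⁴ bubbles for the growth-time
window, 10⁴ samples for parameter recovery — were chosen to pin the
sampler statistics well inside their tolerances while keeping every run
interactive (the full acceptance script completes in about a second).

## Known limitations

* Single inert gas; perfusion-limited compartments only.
* The arterial model is steady-state, single-path and non-pulsatile;
  see the structural bound above for what flow reduction alone can do.
* Compartment half-times, density-bin weights, initiation SD, jitter,
  stripping fraction and tier thresholds are defaults, not fitted
  values; conclusions sensitive to them should scan them.
* Joint-pain ("bends") mechanisms, inflammation/microparticle
  biochemistry and clinical DCI incidence are out of scope.
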