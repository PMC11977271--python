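# Methods

`discsense` models the sensing chain of an electrified lab-on-a-disc (eLOD)
that watches a radial fluidic channel through an array of light-dependent
resistors (LDRs) behind cone-shaped waveguide apertures, and implements the
inverse computations the instrument performs on those signals. This note
records the models, their assumptions, the defaults, and what the synthetic
scenarios do and do not establish about real hardware.

## Optical forward model

Each aperture (diameter `D1`, typically 0.2–1 mm, pitch `D1 + gap` with a
0.3 mm minimum gap) restricts one LDR's view to a sub-millimeter spot on the
channel. The per-sensor instantaneous light intensity (LI, the instrument's
min–max normalized [0, 1] scale) is

    LI = B(V) · η_tilt · [(1 − f) · T_cont(h) + f · T_disp(h)]

* `B(V)` — LED baseline from a monotone piecewise-linear calibration through
  (0 V, 0.02) and (3.5 V, 0.95); the 0.02 anchor doubles as the dark floor
  applied after the mix (an opaque full cover reads the dark level, not 0).
* `η_tilt` — static per-cone efficiency; default (0.95, 1.0, 0.95) for the
  center + two-oblique triple. Tilt is a calibration factor, not ray optics.
* `T(h) = 10^(−k·h)` — decadic Beer–Lambert transmittance over the channel
  depth `h` (mm). Attenuation coefficients are fitted from two (depth, LI)
  observations; the blue-dye fit from LI 0.74 at 0.08 mm and 0.60 at 0.80 mm
  gives `k ≈ 0.127 /mm` with zero-depth baseline ≈ 0.757, and `k = 0.1265`
  is the packaged default for blue-dyed mineral oil.
* `f` — occlusion fraction: the droplet or fluid column is projected as a
  disc of its own diameter onto the aperture plane (axial offset only; the
  channel is only 1–2 mm wide, so lateral offset is ignored) and `f` is the
  circular-lens intersection area over the aperture area. A partially
  covered aperture mixes the two media's transmittances area-weighted; this
  mixed-pixel rule is a modeling choice, not a measured property.
* The LDR applies a single-pole low-pass with `τ = 10 ms` (midpoint of the
  8–12 ms part band); output is clipped to [0, 1]. Default sampling 100 Hz.

Simultaneous shadows on one aperture are summed and renormalized at full
cover — adequate for well-separated droplets, wrong for colliding ones.
Normalization of raw resistance is linear min–max, `LI = (r_dark − r) /
(r_dark − r_bright)`, clipped rather than erroring, and applied per sensor
(whether the hardware shares one normalization across channels is unknown;
per-sensor is the package default).

## Droplet transport

A reduced-order force balance replaces full two-phase CFD:

    m dv/dt = Δρ · V · ω²r(t) − 18 µ V v / (d² H(κ)),   H(κ) = (1+κ)/(2/3+κ)

Stokes drag with the Hadamard–Rybczynski mobility factor for a fluid sphere
(viscosity ratio κ = µ_drop/µ_phase; H → 1 for a rigid sphere). Added-mass
and history forces are neglected (Re ≪ 1); interface deformation, breakup
and pinning are out of scope. The centrifugal term advances with the droplet
(`r(t) = r0 + x(t)`); a fixed-radius mode is available. Integration uses
scipy's LSODA at rtol 1e-6 — the momentum relaxation time (~1 ms) makes the
system stiff relative to second-scale traces — and is verified against the
closed-form terminal velocity to < 0.5%.

Wall retardation and the unprinted channel mounting radius are absorbed into
a single effective radius `r_eff` calibrated from one (rpm, velocity)
observation; the packaged calibration point is (64 rpm, 0.9 mm/s) for a 1 mm
water droplet in 75 cP oil. The closed form then scales as ω² at fixed
radius, which reproduces the 240 rpm (13 mm/s, within ~3%) and 95 rpm
(2 mm/s, within ~1%) observations. The 170 rpm / 4.8 mm/s point deviates
~30% from the square law and is treated as out-of-model: the calibration is
not asked to explain it and nothing downstream depends on it.

Coriolis-driven lateral deflection is summarized as the stress ratio
`2ρωw²/µ` (flag threshold 1 by default): low-viscosity phases score high,
matching the simulated asymmetry ordering; no 3-D field is computed.

## Sedimentation kinematics

RBC–plasma separation is modeled as Kynch-style two-front kinematics with
Richardson–Zaki hindrance (`n = 4.65`). The clear (plasma) front advances at
`v = v_ref (ω/ω_ref)² (1−φ0)^n` from the inner end; the packed bed grows
from the outer end under cell conservation `(φ_max − φ0) · d(bed)/dt =
φ0 · dc/dt`; fronts merge and the state is exactly constant afterwards, with
packed height `φ0 d0 / φ_max`. The ω² scaling of the front speed uses
`ω_ref = 1600 rpm`, the assay's rotation speed.

The sedimentation height `d1` is the height of the visible red column from
the channel's outer end — suspension plus bed, `d1 = d0 − c(t)` — which is
what the strobe photographs measure; the sedimentation index
`SI = (d0 − d1)/d0` then rises monotonically from 0 to the conservation
ceiling `1 − φ0/φ_max`.

Deformability enters solely through the packing fraction `φ_max` (deformable
cells pack denser). With channel length `d0 = 41 mm`, the four sample
classes are calibrated so the steady-state SI equals the photographic
endpoints: normal 0.68, 0.01% glutaraldehyde (GA) 0.64, 0.02% GA 0.50,
sickle-cell patient 0.63. The nominal 40% V/V preparation is inconsistent
with those endpoints (φ0 = 0.40 and SI = 0.68 would require φ_max = 1.25),
so the effective in-channel hematocrit defaults to `φ0 = 0.30`, which puts
every calibrated φ_max in (0.6, 0.94]; φ0 remains a parameter. `v_ref`
defaults to 0.06 mm/s so separation completes in ~40 min at 1600 rpm, the
time scale of the assay; it sets timing only, not endpoints.

Known limitation: because deformability affects only φ_max, all classes
share the same front speed and are indistinguishable before the first merge
(~30 min). The instrument's 15-min discrimination presumably reflects
rate effects (aggregation, compressible-bed rheology) this model omits; the
classification presets therefore read at 3000 s, after all classes reach
steady state. No cell-scale mechanics, rouleaux kinetics or plasma-protein
effects are modeled.

## Detection

* **5% rule** — a sensor is *disabled* when its LI falls ≥ 0.05 below
  baseline, with a half-threshold hysteresis on re-enabling (an unstated but
  necessary anti-chatter guard). Baseline is a per-sensor rolling median
  (default window 2 s; a whole-trace median is available for records where
  passages are sparse) for dynamic scenarios, or the fixed pre-run
  plasma/PBS level (0.90) for sedimentation protocols.
* **Events** — one event per contiguous supra-threshold excursion, runs
  closer than the 0.05 s refractory window merged (half the minimum printed
  inter-sensor interval); the event time is the deviation-weighted centroid
  of samples above half the excursion maximum, giving sub-sample timing.
  Polarity (peak for a transparent droplet in dark oil, trough for the
  reverse contrast) is auto-detected per sensor from the dominant excursion.
* **Velocimetry** — events on adjacent apertures are matched greedily in
  time order; each match gives `v = pitch/Δt` and the summary is the mean.
  Simultaneous events can never match (Δt > 0 by construction); unmatched
  events are counted and excluded.
* **Interface & volume** — the two-phase boundary is bracketed between the
  last disabled and first enabled aperture center (half-aperture margins at
  the array edges); the reported volume is the maximal sample volume
  consistent with the states, `(d0 − lower bound) × width × depth`
  (mm³ = µL), so a fully transparent 40 × 1 × 2 mm channel reads 80 µL.
  Non-monotone patterns warn and return the widest bracket.
* **Deformability call** — enabled sensors are counted at the protocol read
  time and mapped through a count → label calibration; the enabled/disabled
  pattern also brackets `d1`, whose midpoint yields an SI estimate. Three
  protocols ship: a 3-class GA grading (counts 2/1/0 for normal / 0.01% /
  0.02% GA), a 2-class healthy/patient screen (1/0), and a 4-class protocol
  (sensors at 14/15/16 mm from the outer end, counts 3/2/1/0) that
  separates all four calibrated classes. Sensor positions are free config
  parameters: the printed 14–18 mm band and its reference end are not fully
  specified, so positions were chosen in or near that band to realize the
  printed count orderings at steady state.

## Synthetic scenarios

The generator composes the forward models into ground-truthed traces:
droplet passes over the rpm grid {64, 95, 170, 240} (the rotor frame is
placed so the calibrated `r_eff` coincides with the first aperture), and
sedimentation runs rendered as plasma-level (0.90) vs RBC-level (0.72)
plateaus per the two-front occupancy. Noise is additive Gaussian on LI,
default σ = 0.005 (about a tenth of the instrument's reported 5% repeat
deviation; σ = 0.0125 is the stress tier), clipped to [0, 1]; all
randomness flows from the explicit seed and fixed seeds give byte-identical
traces.

What passing tests show: the inverse computations recover what the forward
models put in (velocities within 2% noise-free / 5% noisy, labels with 100%
recovery at σ = 0.005, suspension parameters within 5% from noisy SI
curves), and the closed forms agree with independent oracles (Monte-Carlo
occlusion, ODE steady states). What they do not show: hardware-specific
absolute LI curves (LED/cone calibration), real-blood settling transients,
1/f sensor noise, temperature drift or vibration — the generator does not
emulate these, and no claim about them is tested.

## Numerical choices

Units are mm, s, cP, rpm, µL at every interface (SI internally). Occlusion
uses the closed lens formula with clipped arccos arguments at tangency.
Trace CSVs round-trip losslessly at 6 decimals; marginally out-of-range LI
is clipped with a warning rather than rejected. Test problem sizes: 10⁶
Monte-Carlo points per occlusion case, 100-trial noise sweeps on a shared
noise-free base trace, 20-seed × 4-class classification sweeps — all chosen
to keep the full suite in a few seconds while leaving estimator error an
order of magnitude below the asserted bounds.
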