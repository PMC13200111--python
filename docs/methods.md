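# Methods

## The QA problem

In spot-scanning (pencil-beam-scanning, PBS) proton therapy the machine
paints the target spot by spot, layer by layer. AAPM TG-224 recommends tight
tolerances on spot position (1 mm for annual QA) and MU delivery, because
small systematic deviations accumulate over fractions and can matter in
steep dose gradients. After every delivery the machine writes a log
("demand data") with the position, width and MU of each spot as seen by the
spot position monitor (SPM) and dose monitor. `protonqa` compares those logs
against the planned spot map of the DICOM RT Ion Plan, detects sustained
systematic deviations, learns to *predict* delivered positions from plan
data alone, and estimates the dosimetric impact of position deviations.

## Coordinate handling

Planned spot positions live in the isocenter plane; the SPM sits upstream,
so logged coordinates are scaled onto the isocenter plane by dimensionless
projection factors,

    x_iso = x_spm · f_x ,   y_iso = y_spm · f_y ,

with defaults f_x = 1.696 and f_y = 1.391 for the modelled beamline
(configurable; the factors may in principle differ per room). Deviations are
signed **delivered − planned** throughout; the spot-wise Euclidean distance
d and its square d² = Δx² + Δy² summarise both axes. Under independent
normal axis errors, E[d²] = μx² + σx² + μy² + σy²
(`expected_squared_distance`), the mean of a noncentral-χ²-type variable.

## Spot matching

Demand data records every planned spot in delivery order, so plan and log
are paired strictly positionally by (layer index, order within layer). Any
count mismatch is treated as a data-integrity failure (synchronisation
error), never "rescued" by nearest-neighbour matching. The nominal energy
label always comes from the plan.

## The synthetic campaign

Clinical delivery logs cannot be redistributed, so the package ships a
simulator that generates the whole campaign. What it emulates:

- **Plan**: 20 energy layers, 99.2–124.8 MeV evenly spaced, 725 spots per
  layer on a serpentine raster over a ±100 mm field, uniform metersets
  summing to 233.3 MU, fixed gantry angle.
- **Schedule**: 2 treatment rooms (G1, G2) sharing 32 paired QA dates over
  three months (April–June; the June dates follow the per-session test-day
  pattern of the campaign's final month), i.e. 64 sessions and 928,000
  spots at full scale.
- **Position errors** (per axis, additive, mm): global mean + per-room
  offset + linear-in-energy slope about the plan's mid-range energy +
  per-date drift + independent Gaussian jitter (optionally room-scaled).
  Defaults: x errors 0.163 ± 0.199, y errors 0.096 ± 0.151; room offsets
  G2 − G1 = (0.02, −0.015); energy slope (0.004, 0.003) mm/MeV; date drift
  ramping ±0.025/∓0.02 mm across the campaign; jitter scale 1.1 in G1 vs
  0.9 in G2 (G1 shows larger spot-to-spot fluctuation). The axis means/SDs
  are the campaign's observed global distributions; the systematic-term
  magnitudes are not published anywhere, so they were fixed once at values a
  clinical log analysis would plausibly show — large enough that energy,
  day and room are all statistically detectable at campaign scale, small
  enough to stay well inside daily tolerances.
- **MU noise**: additive Gaussian, mean 0.70 × 10⁻⁵ MU (the observed global
  MU bias), SD 10⁻⁴ MU (a free parameter, chosen at the same order as the
  mean so MU deviations stay negligible), truncated at zero.
- **Fault injection**: a constant extra offset applied to one (room, date)
  session; the default campaign injects +1.1 mm in x for G2 on 2025-05-20,
  the kind of session-specific systematic error the window check must catch.
- x and y jitters are sampled independently (cross-axis correlation of
  deviations is treated as negligible).

Per-session seeds are SHA-256-derived from (campaign seed, room, date), so
any session is reproducible in isolation.

What it does **not** emulate: beam-optics physics (the energy/room terms
are phenomenological, not magnet models), time-resolved intra-spot motion,
spot-width errors, correlated drifts within a session, or non-Gaussian
tails. Passing tests therefore demonstrate that the *pipeline* recovers
whatever structure the error model contains — not that real machines behave
this way.

## Statistics

- Distribution summaries use the sample (n−1) SD; the Gaussian density fit
  is the moment fit (mean, SD).
- **Levene's test** (classic mean-centered variant, configurable center)
  checks variance homogeneity; it routinely rejects for these data, which
  motivates **Welch's ANOVA** (heteroscedastic F with Satterthwaite-type
  denominator df) for group means and **Games–Howell** post hoc pairs
  (studentized-range reference with Welch–Satterthwaite pairwise df).
  Welch/Games–Howell are implemented from the standard formulas and
  cross-checked against pingouin in the test suite; zero-variance groups
  are rejected (the statistics are undefined), and `factor_analysis` skips
  degenerate cases with a warning rather than failing a whole report.
  No correction beyond the studentized-range one is applied across factors.
- **Moving-window flags**: per session and axis, the running mean over every
  contiguous 50-spot window (trailing, never spanning sessions) is compared
  with the 1 mm annual and 2 mm daily tolerances; a spot is flagged at a
  tier if *any* covering window exceeds it on either axis. The union over
  axes is the headline count; per-axis counts are reported too. The daily
  tolerance value of 2 mm is the conventional TG-224 daily spot-position
  figure and is configurable. The rolling-sum implementation is
  property-tested against a brute-force re-scan of all windows.

## Position prediction

Two independent gradient-boosted tree regressors (XGBoost, 500 trees,
learning rate 0.1, squared-error objective, fixed seed) predict the
delivered x- and y-coordinate from {planned x, planned y, energy, date
ordinal, room code}. Separate axis models reflect the physically separate
horizontal/vertical steering systems. Evaluation uses a **temporal split**:
every session in the final calendar month is held out, mimicking
prospective use on future sessions. Metrics: per-axis MSE = (1/n)Σ(Aₜ−Pₜ)²
and R² = 1 − SSR/SST, per-spot Euclidean distance between predicted and
delivered positions, broken down by (room, date) and by beam-energy band
(90–109 / 110–119 / 120–129 MeV), plus the Pearson correlation of the
(Δx, Δy) deviations as an independence check. Feature importances are
gain-based fractions normalised to sum to 1. Because the planned coordinate
spans ±100 mm while errors are sub-millimetre, R² is dominated by the
planned coordinate; the meaningful comparison is against the identity
baseline (predict planned as delivered), which the model must not lose to —
this is a test-suite invariant. No hyperparameter search is performed; the
hyperparameters are exposed but fixed.

## Dose impact

A deliberately simple, fully-disclosed analytical pencil-beam engine — not
a commissioned clinical model — quantifies *relative* dose impact on a
uniform grid (default 2-mm isotropic). Each spot deposits
MU · scale · DD_E(z) · G(Δx, Δy; σ_E) with the beam axis along +z, DD_E a
normalised analytic Bragg curve (Bragg–Kleeman range R = 0.022·E^1.77 mm,
plateau + Gaussian peak + sigmoid distal falloff) and G a 2-D isotropic
Gaussian density truncated at 5σ (mass beyond < 10⁻⁵; in-plane integrals
are accurate to ≪1%). Dose is exactly linear in MU. Absolute dose values
have no clinical calibration; only comparisons between grids computed with
the same engine are meaningful, which is why no absolute dose magnitude is
part of the acceptance checks.

## Numerical choices and edge cases

- DICOM: per-spot MU = scan-spot meterset weight × beam meterset / final
  cumulative meterset weight (the standard RT Ion Plan convention). The
  final cumulative weight is written as the float64 sum of the float32
  weights actually stored, so total MU round-trips to better than 1e-6
  relative. Positions/weights use the DICOM-mandated float32 VR. Layers are
  kept in control-point order — delivery order, never re-sorted by energy.
  The writer emits one beam per plan; the reader supports multi-beam files.
- Reference energy for the energy slope: midpoint of the plan's energy
  range (centres the term; at the midpoint the slope contributes nothing).
- Windowing edge handling: the first window−1 spots of a session are only
  evaluated through windows that contain them.
- Degenerate inputs: empty samples, zero-variance groups, single-level
  factors, constant targets, zero SST (R² reported as missing), empty test
  sets and incongruent dose grids all have defined behaviour (validation
  error, warning + skip, or missing value) rather than NaNs.

## Problem sizes used by the shipped checks

The full 725-spot-per-layer campaign (928,000 spots) is exercised for exact
bookkeeping and I/O; distribution-recovery checks use ≥50,000 spots (3·SE
acceptance bands); the model-accuracy check uses a 100-spot-per-layer
campaign (128,000 rows, 96,000 train / 32,000 test), where both axis models
comfortably exceed R² = 0.999 — at sub-millimetre error scales against a
±100 mm positional spread, R² is an undemanding summary, which is exactly
why the per-spot Euclidean distances and the identity baseline are reported
alongside it.

## Known limitations

- The error model is phenomenological; it cannot validate beam-optics
  explanations of room or energy effects.
- The dose engine omits nuclear halo, heterogeneities, and absolute
  calibration; gamma analysis and DVH metrics are out of scope.
- Matching assumes complete logs; partially delivered sessions are rejected
  rather than analysed.
- Factor analyses treat spots as independent observations, as is
  conventional for these QA comparisons; within-session correlation is not
  modelled, so p-values on factors with few sessions per level are
  anti-conservative.
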