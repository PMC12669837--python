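# Methods

`beevector` re-implements, as a tested pipeline, the analysis of an
enforced-detour experiment on honeybee vector navigation: bees leaving
the hive with a remembered or dance-communicated food vector are forced
through a tunnel detour, and the corrective turn they make on release
is read out as their intended vector. This note documents the models,
conventions, parameters and numerical choices, and what the synthetic
data do and do not establish.

## Geometry of the two predictions

The local frame puts the detour entrance at the origin with +x along
the hive→food bearing; the release point stands in for the hive, so the
*virtual feeder* sits at `(D, 0)` with `D` the trained food distance
(12.4 m). A detour of length `L` (2 m) at relative angle `θ` puts the
exit at `(L cos θ, L sin θ)`. Two corrective turns are computed:

* **shortcut**: the signed turn from the detour heading onto the
  straight line exit → virtual feeder,
  `wrap(atan2(−L sin θ, D − L cos θ) − θ)`. For `θ = +45°` this is
  −52.33°, reported to the nearest degree as −52.
* **bearing resume**: `−θ` — simply turning back onto the food-vector
  compass bearing (−45° for a +45° detour).

The shortcut always over-corrects relative to bearing-resume for
`0 < L < D`, and the two coincide as `L → 0`; both facts are asserted
by the test suite across the full angle range. Angles are degrees
throughout, counterclockwise-positive in the local frame, wrapped to
(−180, 180]; a positive *error* is a deviation to the left of a target.
Geographic azimuths are clockwise from North in [0, 360).

Where the detour entrance sat relative to the hive is not part of the
record; treating the entrance as the origin of the replayed vector is
an assumption of this implementation, and it is the one under which the
−52° worked value is reproduced.

Solar azimuth (needed to map comb angles to geographic bearings) uses
the NOAA mid-accuracy solar position algorithm, cross-checked in the
tests against an independent low-accuracy Astronomical Almanac
formulation to within 0.5° — two orders of magnitude below the
behavioural scatter. Comb angle 0 (waggling straight up) means "toward
the solar azimuth", clockwise-positive; the sign convention is a single
explicit choice, as dance conventions differ between labs.

## Synthetic data

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes. It is a behavioural
caricature, not a bee simulator.

**Flights.** Each bee draws an intended bearing from a von Mises
distribution centred on its condition's target (default concentration
`κ_pop = 3`, circular s.d. ≈ 35°, matching the broad scatter of real
post-detour bearings); a configurable minority (`disoriented_fraction`)
instead draws uniformly, emulating the observed >±90° deviants (whether
real deviants are uniform or homeward-biased is unknown; uniform is the
default and the alternative is a parameter, not a claim). From the exit
the heading relaxes toward the intended bearing by first-order
exponential dynamics, `Δh = (1 − e^{−λΔt}) · wrap(intended − h)` plus
von Mises per-frame noise (`κ_noise = 400`, ≈ 2.9° jitter). The
relaxation rate `λ` defaults to 2 s⁻¹, chosen so that at the tunnel
flight speed of 0.44 m s⁻¹ (the measured average) the correction is
clearly in progress across the 0.22/0.44/0.66 m boundaries — the
progressive per-boundary shift the real data show — while the turn
still begins immediately at the exit. Speeds are truncated-normal
(mean 0.44, s.d. 0.05 m s⁻¹).

**Video.** Flights are rendered at 60 Hz as a dark circular silhouette
(default 6 px radius at 200 px m⁻¹) over a static bright random
texture, on a 1.56 m × 0.84 m field of view. The camera is aimed at
the expected flight corridor: the exit sits 0.2 m inside the upstream
edge and is shifted 0.25 m laterally away from the predicted shortcut
side, without which the 0.66 m boundary cannot geometrically stay in
view for ±45° detours. Flights terminate 4 cm before the FOV edge so
the rendered silhouette is never clipped (a clipped blob biases the
extracted centroid). An optional moving distractor patch stresses the
tracker's gating.

**Dances and followers.** Waggle-phase comb angles are von Mises about
the signalled direction with `κ_phase = 2` — wide enough that nearly
every 20-phase dance contains phases deviating >±60° from the target,
as observed. Durations are truncated-normal with a 0.05 s floor and
resolution (the measurement precision). Follower traces at the hive
camera's 80 Hz place the follower's body at a configurable offset from
the dance axis and point the circular midpoint of her two antennal
angles from her heading toward the dance direction, plus Gaussian
angular noise, so the decoding round trip is exact at zero noise by
construction.

All generators are deterministic given their seed; per-bee substreams
derive from `SeedSequence([seed, bee_id])` so cohorts are reproducible
element-wise.

What passing tests show: the pipeline recovers what the generator
encodes, at the scatter and sampling rates of the experiment. What they
do not show: robustness to real-video nuisances (wind-blown objects
beyond the scripted distractor, lighting drift, wing-blur, gradual
ascent of the bee toward the camera), or correctness of the behavioural
model itself.

## Tracking

A per-pixel Gaussian-mixture background model (Stauffer–Grimson update
rules; K = 3 components, learning rate 0.05, 2.5 σ match threshold,
background weight ratio 0.7) classifies foreground, with the dominant
component seeded from the pixel-wise median of the whole clip — clips
are sub-second, so the full history is available and this removes
warm-up ghosting around the bee's first position. Foreground contours
come from connected-component labelling; the contour centre nearest
the previous position, within a gating radius (default 30 px ≈ 5 blob
radii), extends the track. A lost track returns the partial trajectory
flagged rather than failing, leaving room for the manual-rescue
workflow used on wind-perturbed clips. The tracker is deterministic:
identical frames give identical trajectories.

Boundary bearings are taken at the *first frame* whose distance from
the exit reaches each radius — no sub-frame interpolation, matching
the frame-based measurement; interpolation exists as an off-by-default
option. A boundary never reached is reported missing, never imputed.
The mean tunnel speed estimator measures the time to cover a 0.2 m arc
window in the midsection of the path (default: starting at 40% of the
arc length), inherently quantised to the 1/60 s frame period.

Exclusions follow the stated rule: bees that stopped in the tunnel or
took longer than 30 s to exit are dropped; "longer than" is read
strictly, so exactly 30.0 s is retained. "Stopped" has no quantitative
definition in the record and is carried as an upstream metadata flag.

## Circular statistics

Descriptives are the standard circular mean and mean resultant length
`R`, with circular s.d. `√(−2 ln R)` (in degrees) and von Mises `κ` by
the usual A⁻¹(R) approximation (capped at 10⁶ for degenerate samples).

The **Mardia–Watson–Wheeler** k-sample test converts pooled ranks to
uniform scores `β_j = 2π·rank/N` and uses
`W = 2 Σ_i (C_i² + S_i²)/n_i`, asymptotically χ² with 2(k−1) df (four
groups give the `W₆` form). Ties get midranks with a warning —
angle data recorded at 1° resolution can tie — and a label-permutation
p-value is available and recommended in that case.

The **equal-kappa** (concentration homogeneity) test follows Fisher's
three-regime construction, switching variance-stabilising transforms on
the pooled mean resultant length (arcsine below 0.45, asinh to 0.70, a
Bartlett-type statistic on circular dispersions above), χ² with k−1 df.
Which exact variant the original analysis used is not stated, so a
permutation fallback on mean-centred angles is provided and is the
authoritative answer for small or degenerate groups (it engages
automatically when a group has R = 1). Both tests are verified by
simulation to hold their nominal size (type-I error within
[0.03, 0.07] at α = 0.05 over 2000 null replicates, n = 30/group,
κ = 2 — a pooled R̄ near the 0.70 regime boundary, so both upper
regimes are exercised).

No multiple-testing correction is applied; the analysis reports single
omnibus tests.

## Dance decoding

Waggle angles come from the thorax line between the first and last
waggling frame (clockwise from gravity-up). A follower is a bee within
one body length (default 13 mm) of the dancer facing her within a
configurable cone (default half-angle 90°, since "facing towards" is
otherwise unquantified). The antennal midpoint is circular (angle of
the sum of the two unit vectors); antipodal antennae are flagged and
the frame skipped; a linear-average flag exists because the original
phrasing does not disambiguate.

The per-phase assimilation estimate is an explicit **baseline**, not a
neural-circuit model: per frame, pointing = gravity heading + antennal
midpoint; the phase vector is the resultant of unit vectors at those
pointings (magnitude grows with usable frames, so longer coherent
phases weigh more), and a follower's overall estimate is the
magnitude-weighted circular mean over the phases she followed. The
operation signature is the input/output contract of published
assimilation circuits, so a faithful circuit can be slotted in behind
it. How such circuits scale magnitude with duration, and whether
followers weight later phases, are parameters here, not claims; the
weighted mean is permutation-invariant in phase order.

## Pipeline summaries

Signed errors are `wrap(angle − target)` with the shortcut prediction
as the default target (both predictions are attached to every summary
row, since the convergence of flights from different detours on one
location is what distinguishes them). Cells are role × detour angle ×
boundary. Because mirrored detour conditions carry lag errors of
opposite sign, a naive pool across conditions cancels the turning
signature; the `progressive_shift` summary therefore reflects
(negates) errors from positive-target conditions before pooling and
uses complete cases only (bees observed at all four boundaries), so
consecutive boundaries compare the same animals. Unreflected pooled
summaries are emitted alongside, since whether the original figures
pool with reflection is not fully stated.

Individual repeatability reports per-bee circular summaries (bees with
≥2 retained records) and the ratio of the median individual circular
s.d. to the pooled s.d. The goal-convergence estimator solves the
closed-form normal equations for the point minimising summed squared
perpendicular distances to the bearing lines `(ΣP) q = Σ P p` with
`P = I − dd^T`, rejecting (near-)parallel line sets by condition
number (> 10¹⁰). Pipeline outputs carry the manifest seed and a
configuration hash; a fixed manifest reproduces byte-identical CSVs.

## Problem sizes in the standard checks

The bundled checks run at the scale of the original experiment where
that is known: cohorts of 200 bees (the repeat-testing analyses used
33 foragers and 24 dancers; population panels pooled similar numbers),
20 tracked synthetic videos for the tracking round trip, 2000 null
replicates for test calibration, and 100 replicates for the noisy
dance-decoding round trip.

## Known limitations

* The assimilation estimator is a baseline; it reproduces round trips
  by construction and says nothing about real central-complex
  dynamics.
* Horizontal-plane geometry only; no altitude, wind, terrain or
  magnetic declination.
* The duration→distance map is a placeholder affine map; calibrate per
  colony before interpreting distances.
* The tracker is single-animal with nearest-contour gating; it is not
  a multi-target tracker and does not re-associate identities across
  clips.
* Synthetic backgrounds are far cleaner than sky footage; tracking
  accuracy figures from the round-trip tests are upper bounds.
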