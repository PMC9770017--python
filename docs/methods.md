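# Methods

This note documents the models behind `quadgait`: what the synthetic
generator simulates and deliberately does not, how the analysis operations
are defined numerically, the tunable parameters with their defaults, and
the design choices made where the problem left the design open.

## 1. The measurement model

All quantities live in SI units in a sagittal treadmill frame: `x` grows in
the direction of travel, `y = 0` is the belt surface. Marker data are
sampled at 60 Hz, EMG at 5000 Hz. Limbs are named by their role relative to
the stimulated hindlimb: *ipsilateral* (stimulated hindlimb),
*contralateral* (other hindlimb), *homolateral* (forelimb on the stimulated
side), *diagonal* (other forelimb).

Per limb and cycle:

* cycle duration = time between successive stance onsets;
* stance duration = onset → offset; swing duration = cycle − stance
  (an exact identity, asserted in tests);
* duty factor = stance/cycle;
* stride length = |x(onset) − x(offset)| + belt speed × swing duration
  (on a treadmill the swing progression is relative to the moving belt; on
  steady unperturbed cycles stride = belt speed × cycle duration, which the
  tests verify to 10⁻⁶ m);
* step length = |x_leading − x_trailing| of the girdle's two toes at the
  leading limb's stance onset. A step is attributed to the cycle *closed*
  by that touchdown (the touchdown ending the cycle's swing), so a
  prolonged swing shows up in the stimulated cycle's step length.

Support periods are maximal intervals with a constant set of limbs in
stance, computed by an exact sweep over stance-interval boundaries inside
one ipsilateral cycle window and labelled into nine categories (four
two-limb supports: ipsi–homo, ipsi–diag, contra–homo, contra–diag; four
three-limb supports, named by the absent limb; quadrupedal). Category
durations recurring within a window are summed. A symmetric walk at duty
0.65 with limb phasing 0 / 0.5 / 0.25 / 0.75 produces exactly eight
periods per cycle, alternating triple/double; when the diagonal forelimb
lands before the ipsilateral hindlimb lifts, the short diagonal support is
replaced by a quadrupedal period — hence nine categories overall.

## 2. Synthetic sessions

The generator is not a musculoskeletal simulation; it produces data with
exactly the statistical structure the analysis assumes, with every injected
effect recoverable in the noise-free limit.

**Footfall schedule.** Each limb follows a periodic grid (period `T`, duty
factor `d`, phase offset φ) with independent Gaussian jitter per event
(non-accumulating). Defaults for the canonical demonstration schedule are
the symmetric walk above. The *session* baseline uses φ(diagonal) = 0.71
instead of 0.75: walking cats place the diagonal forelimb almost as the
ipsilateral hindlimb lifts, making the diagonal contra–homo support brief
(0.06 of a cycle here) — the geometry that lets a near-tripling of that
support fit inside the homolateral stance.

**Toe trajectories.** During stance the toe rides the belt backward from
its landing position at belt speed; during swing it moves forward along a
minimum-jerk profile. Toe height is zero in stance; in swing it follows a
flat-topped bell (apex = configured swing height, default 0.03 m) with
*linear terminal segments*: the paw leaves and approaches the ground at a
fixed vertical speed (0.35 m/s over the final 60 ms). The terminal speed is
a property of the gait, not of the swing's height or duration — raising
the paw four times higher does not make it land four times faster — and it
gives contact detection a descent geometry that is identical across
control and perturbed cycles.

**Proximal markers.** A sagittal chain (pelvis→thigh→shank→foot;
shoulder→arm→forearm) driven by smooth prescribed segment-orientation and
joint-angle waveforms places the remaining markers; the implied hip, knee
and ankle angles are available in closed form and serve as the
forward-kinematics oracle for the angle computation. The chain and the
prescribed toe are deliberately uncoupled — the chain carries the
joint-angle ground truth, the toe the contact/length ground truth. This is
a simplification a real limb does not have, and it is one reason the
generator validates the *pipeline*, not limb mechanics.

**EMG.** Each channel is band-limited (30–1000 Hz) unit-RMS Gaussian noise
under a flat-topped Tukey envelope (5% cosine ramps) gated to the muscle's
active sub-phase — flexors (SRT, BFP, ST, BB) in swing, extensors (BFA,
VL, LG, SOL, TRI, ECU) in stance — plus an independent baseline carrier at
SNR 20. Muscle availability per animal follows a realistic chronic-implant
pattern (SRT and TRI in 7/7 animals, ST/LG/SOL/BB in 6/7, BFP/BFA/VL/ECU
in 5/7).

**Stimuli and perturbation.** Stimuli are planted pseudo-randomly every
5–6 cycles (shuffled gaps), 10 per phase per animal, placed at a uniform
position inside the target phase window. The affected cycles are
*regenerated from modified schedule parameters*, never by warping
already-generated signals:

* duration multipliers set the stimulated cycle's stance/swing/cycle
  durations per limb (the limb's own cycle containing the stimulus);
* the contra–homo support effect is emergent, so the generator solves for
  it: the diagonal touchdown is delayed to
  `ipsilateral liftoff + gain × baseline gap`;
* step-length effects are likewise emergent: the landing position of the
  touchdown closing the stimulated cycle is shifted relative to the partner
  limb's extrapolated position. At mid-swing most of the −13.3%
  contralateral step length emerges from the delayed ipsilateral touchdown
  alone; the landing shift closes the remainder;
* toe-height gain scales the stimulated swing's apex; joint-flexion
  multipliers scale the swing flexion depth; EMG gains scale envelope
  amplitude and gate duration for the keyed muscle and cycle.

The cycle after the post cycle absorbs accumulated shifts and returns the
limb to the grid, so consecutive triads never interact at the 5–6-cycle
spacing. `paper_effects.yaml` transcribes the published stimulated-cycle
effect sizes into these profiles; post-cycle carryover effects are not
encoded (the post column of the synthetic effect tables reflects only the
mechanical aftermath of the stimulated cycle, which qualitatively
reproduces the reported post-cycle support redistribution, e.g. emergent
quadrupedal support after a prolonged mid-swing cycle).

**Noise defaults** (chosen once from the acquisition geometry, with a
design-stage error-propagation analysis, and not revisited): marker jitter
σ = 0.5 mm (sub-pixel tracking at ~1 mm/px); per-event timing jitter
σ = 2 ms; EMG SNR 20; between-animal log-normal σ = 0.05 on cycle period
and EMG gains; belt speeds uniform within ±0.05 m/s of the nominal
0.4 m/s. Real cats show larger stride-to-stride timing variability; the
small default keeps single-triad support decompositions cleanly
interpretable and is the main respect in which passing recovery tests
understate the difficulty of real data.

**Scale.** The default session is 7 animals × 230 cycles × 40 stimuli
(10 per phase), ~253 s of data per animal — enough cycles to fit 40
stimuli at 5–6-cycle spacing with planning margin.

## 3. Event detection

Contact (stance onset) is defined by toe height dropping below 5 mm for at
least 3 frames. The reported onset is refined to sub-frame precision: the
limb's terminal descent speed is estimated once per limb (median slope of
the last two airborne samples across touchdowns), and each contact is the
last airborne sample extrapolated to the belt surface at that speed. Stance
offset (most caudal toe position) is refined by fitting the two-piece model
`x(t) = A + v·(t_k − t)₊` (stance line) continuing into a minimum-jerk
rise toward the next touchdown, with a grid search over the kink time
`t_k` and closed-form least squares for the linear part. Minimum-jerk is
the standard smooth point-to-point limb-trajectory model; on synthetic
data these estimators are unbiased to ≲0.5 ms, and on real data any
residual bias is sub-frame. `refine=False` restores plain frame-grid
events (the historical convention for 60 Hz video analysis); the refined
events are the default because percent-change effects on ~60 ms support
periods are visibly distorted by ±8 ms quantization.

Cycles are built from consecutive onset pairs; a cycle whose offset is
missing (no caudal turning point, truncated record) is dropped.

## 4. Phase windows and triads

Phase is computed on the stimulated cycle's *own* measured stance/swing
split, not a session average. Default windows: mid-stance = stance
fraction ∈ [0.3, 0.7]; mid-swing = swing fraction ∈ [0.3, 0.7];
transitions = last 10% of the outgoing plus first 10% of the incoming
sub-phase. The windows are config keys and validated to be disjoint. For
every limb the stimulated cycle is the limb's own cycle containing the
stimulus onset (a convention: the alternative alignment by wall-clock
"first cycle after stimulation" differs for forelimbs in rare boundary
cases). A triad is invalid if the phase is excluded, any limb lacks three
consecutive complete cycles, or another stimulus falls within the
ipsilateral control-to-post span.

## 5. EMG processing

Band-pass: zero-phase 4th-order Butterworth, 30–1000 Hz. Envelope:
full-wave rectification, zero-phase 50 Hz low-pass. Burst detection is a
double threshold on the envelope: baseline median + 3·MAD (MAD scaled by
1.4826 to a Gaussian σ) with hysteresis at half that excursion, ≥20 ms
sustained, ≤20 ms gaps merged; baseline statistics are seeded from the
lowest-quartile region and iterated twice excluding detected bursts, so a
65%-duty extensor cannot drag the baseline up. Detected bursts are trimmed
at a *burst-relative* level (25% of the burst's median envelope), which
localizes the smeared edges without introducing amplitude-dependent bias.
Bursts are detected on the whole channel and assigned to the cycle
containing their onset — a burst outlasting its cycle (e.g. a prolonged
flexor burst) keeps its true offset — and the longest burst per cycle is
retained. Mean amplitude integrates the rectified band-passed signal over
the burst divided by its duration; amplitudes are normalized to the
control-cycle burst of the same triad (control ≡ 100%) before statistics.

## 6. Statistics

For each variable and phase, per-animal means over valid triads form an
n × 3 matrix. The Friedman statistic uses average ranks with the standard
tie correction (cross-checked against an independent implementation and a
brute-force rank enumeration in tests); p-values use the χ²(2)
approximation by default, which for n = 7 blocks rejects exactly when the
exact tail mass is 0.051 — empirically calibrated type-I error ≈ 0.05 on
null sessions. An exact tail (dynamic programme over column rank sums,
k = 3, no ties) is provided for verification; it is not the default
because its attainable levels are coarse at small n (the level just below
0.05 is 0.027). The post hoc is Bonferroni-adjusted Wilcoxon signed-rank
tests of stimulated-vs-control and post-vs-control (raw p × 2, capped at
1), run only after a significant main effect; whether the third contrast
enters the correction is a config option. Shapiro–Wilk is reported but
never gates the nonparametric test. Percent change is the mean of
per-animal changes (each vs its own control mean), not the ratio of group
means — it matches the repeated-measures design and is unbiased for
multiplicative effects.

The type-I calibration simulates the statistical layer (per-animal triad
means with between-animal log-normal and within-animal noise, no cycle
effect, 2000 replicates), not 2000 full marker/EMG sessions; full-pipeline
null behaviour is covered by the identity-profile phases of the recovery
sessions.

## 7. Validation problem sizes

The test suite and `scripts/acceptance.py` use: one full default session
(7 animals × 230 cycles, 10 stimuli/phase, EMG restricted to the ST
channels for the amplitude check) for effect recovery; 2000 statistical
replicates for the Friedman calibration; 200 random schedules against a
1 kHz brute-force labelling oracle for the support decomposition; and a
zero-noise session for the exactness identities (angle recovery to
10⁻⁶ deg, stride conservation to 10⁻⁶ m, byte-identical regeneration under
a fixed seed).

## 8. Known limitations

* The generator's marker chain and toe trajectory are uncoupled, and its
  EMG is amplitude-modulated noise: recovery results validate the analysis
  chain, not tracking quality, skin-marker artifact handling or
  motor-unit-level physiology.
* Event refinement assumes a belt-linear stance and a smooth
  (minimum-jerk-like) swing; on real data with irregular paw drag the
  frame-grid mode may be the safer choice.
* Marker coordinates are required in calibrated meters; a pixel-to-meter
  calibration must be applied upstream if real tracking output is used.
* Burst detection replaces expert visual scoring; all constants are
  exposed, and externally scored burst tables can be substituted for the
  detector's output.
* No multiple-testing control is applied across variables, matching the
  reporting convention of per-variable Friedman tests.
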