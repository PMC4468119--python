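# Methods

This note documents the models and numerical choices behind `romscreen`:
what each stage computes, which parameters matter, what the synthetic
generators do and do not emulate, and where the design was genuinely open.

## Angle computation

**Segment lines.** Trunk (head, shoulder_center, spine, hip_center) and
arm (shoulder, elbow, wrist, hand when tracked) directions are obtained
by orthogonal least squares: the first principal axis of the centered
landmark scatter, computed by SVD. Orthogonal fitting — rather than
coordinate-wise regression — is rotation-equivariant, which angle
computation requires: rigidly rotating the subject must rotate the fitted
line with it. The fitted direction is sign-disambiguated against an
orientation hint (head→hip for the trunk, shoulder→distal for the arm).
Both landmark sets are the obvious Kinect-v1 upper-body subsets and are
configurable; line fitting across several joints suppresses per-landmark
jitter compared with a two-point segment.

**Body angle** is arccos of the clamped dot product between the arm
direction and the caudal trunk direction: 0° with the arm at the side,
180° overhead, independent of any plane.

**Projection angle** projects the arm direction onto the movement's
anatomical plane — coronal (longitudinal × mediolateral) for abduction,
sagittal (longitudinal × anterior) for flexion — and measures the angle
of the projection from the caudal direction. The anatomical frame is
rebuilt every frame from the trunk landmarks (longitudinal = hip→shoulder
center; mediolateral = right→left shoulder, orthogonalized; anterior
completes the right-handed triad), so the measure is invariant to where
the sensor stood. A `sensor_fixed` plane mode (sensor axes instead of the
trunk frame) is retained for fidelity experiments, since it is not known
whether the original processing used anatomical or sensor-fixed planes.
Projections with norm ≤ 1e-6 (arm essentially orthogonal to the plane)
raise a degenerate-projection error rather than returning an arbitrary
angle.

For motion confined to the projection plane with a straight trunk the two
measures agree identically; this geometric identity is verified
numerically in the tests.

**Peaks and ROM.** Within each repetition the maximal angle is averaged
over 3 consecutive frames centered on the peak (compensating frame-rate
differences against the 25 Hz video reference the angles are calibrated
to); at a window boundary the 3-frame stencil shifts inward, and ties
break to the earliest frame. The inward-shift boundary rule is this
package's choice — any 3 valid frames near the peak serve the purpose.
ROM is the arithmetic mean of repetition peaks; records with fewer than 3
repetitions are retained but flagged, and cohort analyses exclude them.

## Preprocessing

Coordinates are filtered per channel with a 2nd-order Butterworth
low-pass at 6 Hz (fs 30 Hz) applied forward-backward (`filtfilt`).
Zero-phase filtering is the default because a causal 2nd-order filter at
this cutoff would lag the signal by 1–2 frames and bias the 3-frame peak
window; the causal single pass is available via `zero_phase=False`. The
forward-backward pass squares the magnitude response (stopband gain at
12 Hz: |H|² ≈ 0.059; passband at 1 Hz: 0.9992), which the tests check
against the designed response. Filtering requires at least
3·(order+1)+1 samples (the pad length of the forward-backward pass).

Tracking dropouts are repaired before filtering: runs of non-tracked
samples up to `max_gap_frames` (default 5 ≈ 167 ms) flanked by tracked
samples are linearly interpolated and re-flagged `inferred`; longer runs
stay missing and block filtering of that landmark. Repetition windows are
maximal runs with angle ≥ 20° lasting ≥ 0.5 s — a rest-threshold
segmentation on the angle trace, standing in for the manual per-protocol
segmentation an operator would do; both parameters are exposed.

## Calibration and screening

Goniometric ROM is regressed on capture ROM (per movement and angle
method) by ordinary least squares. The regression direction is chosen so
that screening operates on the clinical (goniometric) scale: adjusted
ROM = slope·capture + intercept, clamped to [0, 180]°. Alongside the
line, the fit reports Pearson r, the exact two-sided p from the
t-distributed statistic with n−2 df, and post-hoc power from the Fisher-z
normal approximation — adequate at cohort sizes of 10–20 and monotone in
both n and |r|. With two angle methods tested per movement, the
Bonferroni-corrected per-test α is 0.05/2 = 0.025.

The referral rule flags a subject when both active movements and at least
one passive movement fall strictly below T = threshold_fraction × 180°
(126° at the default 0.7). Inequalities are strict exactly as the rule is
stated; at T the subject is not referred. Requiring both active terms
suppresses single-movement tracking failures; the passive OR keeps
sensitivity to capsular patterns where one passive direction is spared.

## Artificial population model

The landmark-level generator (`synth_trajectory`) produces an upright
trunk with a straight arm sweeping a raised-cosine elevation profile in
the movement's plane, with rests between repetitions and optional
isotropic Gaussian landmark noise. It is deliberately idealized — no
elbow flexion, no soft-tissue or depth-sensor noise physics, no trunk
sway — so that the programmed peak is an exact ground truth for pipeline
parameter-recovery tests. Passing those tests shows the geometry and
signal chain are correct, not that real Kinect noise is handled
optimally.

The population-level generator (`synth_population`) draws per-subject
true-ROM quadruples (AA, AF, PA, PF) from a two-component mixture:
restricted (prevalence π = 0.15) vs unrestricted, each a multivariate
normal with movement-specific means/SDs, common cross-movement
correlation ρ, truncated to [0, 180]° (exact rejection sampling).
Measured ROM adds independent Gaussian error per movement (clamped to
[0, 180]°), representing capture noise and calibration residual
combined. A subject is *truly restricted* at a threshold when the
referral rule's logical structure holds on the true angles; the rule on
the measured angles is the screening decision. False-positive and
false-negative rates are stratum proportions with Wilson 95% intervals,
and threshold sweeps reuse one cohort (common random numbers) so rates
are comparable across thresholds.

**Default parameters and their calibration.** The generating
distributions of the original artificial-data experiment are not
recoverable, so the defaults were reconstructed once by fitting the
model's free parameters to the cohort statistics that are on record:
restricted prevalence 15%; active capture–goniometry correlations in the
0.6–0.8 band with passive correlations distinctly lower (≈0.4–0.6);
FP/FN ≈ 0.21/0.02 at the 30% restriction threshold and ≈ 0.08/0.02 at
40%. The fitted defaults (degrees):

| movement | restricted μ, σ | unrestricted μ, σ | error σ |
|----------|-----------------|-------------------|---------|
| AA       | 39.4, 5.4       | 112.8, 18.4       | 27.0    |
| AF       | 39.4, 5.4       | 126.7, 18.7       | 26.6    |
| PA       | 43.0, 5.4       | 141.2, 5.9        | 51.3    |
| PF       | 43.0, 5.4       | 141.2, 6.1        | 49.6    |

with π = 0.15 and ρ = 0.78. Structurally, the operating point demands
exactly what the clinical picture suggests: a deeply restricted minority
(so misses are rare at both thresholds), an early post-surgical
unrestricted majority whose *active* ROM often dips below 126° while
*passive* ROM is preserved and tight (pulley-assisted motion), and much
larger measurement error on passive movements (the pulley interferes
with skeletal tracking) — it is predominantly passive measurement noise
crossing the threshold that produces false positives. Under these
defaults the simulated error rates are FP ≈ 0.23 / FN ≈ 0.022 at the 30%
threshold and FP ≈ 0.078 / FN ≈ 0.022 at 40% (n = 2×10⁵; the acceptance
script recomputes them). All parameters are config-exposed
(`PopulationModel.from_dict` / JSON via the CLI); the defaults are a
documented reconstruction, not measured population values, and analyses
of real cohorts should refit them.

What the population generator does not emulate: skewed or floor-effect
ROM distributions, movement-specific prevalence (a subject restricted in
flexion only), error heteroscedasticity across the ROM range, and any
coupling between measurement errors of different movements. Each of these
would change the absolute FP/FN values; the qualitative ordering
(FP shrinks sharply as the restriction criterion deepens while FN stays
flat) is robust across the parameter ranges explored.

## Numerical choices and degenerate inputs

- arccos inputs are clamped to [−1, 1]; all emitted angles lie in
  [0, 180]°.
- Line fitting rejects < 2 points or coincident points; zero-norm
  vectors raise rather than propagate NaNs.
- Angle-trace errors are annotated with the frame index at which the
  geometry degenerated.
- Monte-Carlo sample sizes default to 10⁵–2×10⁵ subjects, which puts the
  Wilson-interval half-width near 0.002 on the FP rate and keeps a full
  sweep under two seconds; the truncated-normal rejection sampler
  resamples only out-of-range rows (rejection is rare because component
  means sit far from the bounds).
- All generators are deterministic given their seed
  (`numpy.random.default_rng`).

## Known limitations

- The trajectory generator's idealized skeleton cannot probe
  image-recognition failure modes of a real depth sensor (occlusion by
  the pulley, merged limbs); real-data validation of the angle pipeline
  is outside what synthetic tests can show.
- Post-hoc power for a correlation uses the Fisher-z approximation; for
  n < 10 it is rough (and reported as 0 for n ≤ 3).
- The screening rule's operating characteristics inherit the
  population-model reconstruction; they should be read as "rates under a
  cohort statistically like the one described", not as properties of the
  rule alone.
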