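# Methods

## The sensing model

The package operates downstream of a millimetre-wave MIMO FMCW radar whose
proprietary tracker emits, at a fixed 10 frames/s, a set of 3D reflection
points (the *point cloud*) and one *spot* per tracked person, nominally at
upper-torso height.  We never model the RF chain; the simulator emulates the
tracker's *output* statistics.  Coordinates are metres in a right-handed
room frame with z up and the floor at z = 0; the sensor pose (2.5 m mounting
height, 45° downward tilt, mid-wall at y = 0) is carried as track metadata.
Rooms default to 4×5 m or 4×3 m.

Three posture classes are used throughout: 1 = standing upright,
2 = sitting, 3 = falling.

## Synthetic scene generator

The generator exists because real acquisitions of this kind are scarce and
not freely redistributable; it is first-class, tested code, and its defaults
define the study conditions used by the tests and the acceptance script.

**Body model.**  Each posture is a 3-axis Gaussian point source:

| posture  | σ (m)                 | cloud centre z | body centre z |
|----------|-----------------------|----------------|---------------|
| standing | (0.15, 0.15, 0.45)    | 0.92           | 0.90          |
| seated   | (0.18, 0.18, 0.20)    | 0.95           | 0.55          |
| fallen   | (0.45, 0.18, 0.12)*   | 0.20           | 0.20          |

\* long axis along the fall heading.  The seated cloud centre sitting
*above* the body centre encodes the sensor's compaction of the cloud toward
the most reflective part of the body (the upper torso); the near-isotropic
seated σ makes the z-plane eccentricities drop, which is the feature the
classifiers exploit.

**Point count.**  Poisson with mean `max(5, f · (42 − 6·d))` where d is the
horizontal distance to the sensor in metres — the cloud thins as the subject
moves away — and f = 0.25 during the fall transient, producing the
point-count collapse at the fall instant.  Observed direction of both
effects is qualitative in the source material; the linear-Poisson law is the
simplest model with the right monotonicity.

**Spot.**  Position = body xy plus a posture-dependent height
`base + gain·d` (standing: 0.88 + 0.12·d), with 5 mm Gaussian jitter per
axis.  The distance gain reproduces the observed growth of spot height with
range: near the device only part of the body is inside the beam and the
reconstructed height drops.

**Walking.**  Waypoint-following with per-leg cruise speeds drawn in
[0.35, 0.75] m/s, acceleration-limited at 1.2 m/s², and each velocity
component clipped to 0.8 × the 1 m/s cap.  The 20% headroom absorbs the
finite-difference noise that spot jitter adds, so *measured* spot speeds
stay within ±1 m/s per axis (the calibration the acceptance script checks).

**Falls.**  A walk segment, then a half-cosine descent of the spot to floor
level over 5–7 frames (0.5–0.7 s) with a 0.3 m forward lurch, then
stillness.  The scripted frame of maximum negative z variation is recorded
as ground truth, which is exactly the quantity the detector estimates.
Fall onsets are drawn in the 55–70% span of the track so the analysis
windows always fit.

**Sit cycles.**  Enter → sit on a chair 2.5 m from the sensor → sit 5 s →
stand → return, repeated 5 times; 1 s sit/stand transitions interpolate the
cloud geometry.  A fixed-y variant walks to the chair along a constant-y
line, holding sensor distance (hence point count and spot height) roughly
stable.

**Artifacts** (`inject_artifacts`) overlay tracker failure modes without
touching labels: a spurious knee-height second spot over a random span, a
few-frame spot dropout followed by a lower-leg-height reconstruction, and a
small static clutter cluster that reflects even with nobody in the room.

**Study dataset.**  `generate_study_dataset(seed)` emits 12 fall tracks
(30 s) and 14 sit/walk tracks (5 cycles each, half with the fixed-y
approach), distinct subject ids, rooms alternating 4×5 / 4×3 m — about
14,500 frames in total.  Per-track seeds spawn from one `SeedSequence`, so
the dataset is a pure function of the seed.

**What the generator does not model:** inter-subject anthropometric
variation, limb articulation and micro-Doppler texture, multipath and
occlusion, and multi-person interaction beyond the artifact demos.  Tests
passing on this data show the pipeline is correct and well-calibrated under
the stated geometry, not that the accuracies transfer to human recordings.

## Fall kinematics

Speeds are forward differences of the resolved spot position times the frame
rate; `spot_speed` applies a centred 3-frame moving average by default.
With several spots per frame the primary spot is the one nearest the
previous primary (highest wins on the first frame, since artifact spots
appear low); spot gaps of ≤ 5 frames are linearly interpolated, longer gaps
stay NaN and are ignored by the statistics.

The fall instant is `argmin` of the *unsmoothed* one-step z difference (ties
to the earliest frame), reported as the frame where the drop lands; a track
whose largest drop stays above −0.15 m/frame is declared fall-free.  The
threshold sits an order of magnitude above walking-induced z fluctuation
(≲ 0.05 m/frame) and comfortably below the mid-fall drop rate (≈ 0.2 m/frame
for a 0.7 s fall), giving both ≥ 95% recovery within ±2 frames and ≤ 5%
false positives on walk-only tracks at the defaults.  Smoothing before
differentiation is available but off by default: it spreads a sharp drop
over neighbouring frames and biases the located instant early.

The peri-fall window is 40 frames — 2 s on each side of t\* at 10 Hz,
frames [t\*−20, t\*+19] — and the post-fall span is frames
[t\*+10, t\*+50] inclusive (41 samples).  `peak_speed` is the signed speed
component of largest magnitude inside the peri-fall window, taken over all
three axes since a fall's dominant component is vertical while the
walking-range comparison is horizontal.  Post-fall mean speed is
horizontal-only by default (`horizontal_only=False` gives the 3D magnitude);
the horizontal choice matches the way walking speed is assessed, making the
two directly comparable.  Windows that overrun the track are truncated with
a warning rather than rejected.

## Confidence ellipsoid and features

Centre = sample mean; axes from the eigen-decomposition of the sample
covariance; semi-axis_i = √(χ²₃(q)·λ_i) at coverage q = 0.95.  Eccentricity
per coordinate plane uses the projected 2D covariance eigenvalues,
e = √(1 − λ_min/λ_max); it is invariant to uniform scaling, in-plane
rotation and the confidence level, so every posture conclusion drawn from
it is free of the coverage constant (which affects only the volume
feature).  The major axis is *a* by definition, keeping e real in [0, 1).

Fits need ≥ 4 points with full-rank covariance; degenerate frames (e.g.
during the fall point-collapse) carry the last valid feature vector forward
with a `stale` flag (configurable to drop).  The spot feeds kinematics only;
the 7 features come from the cloud alone.

## Classifiers

**KNN** ranks Euclidean distances with a stable sort (distance ties → lower
training index) and majority-votes the k = 5 nearest (vote ties → smallest
class code); the test suite proves exact agreement with an exhaustive
oracle.  **Forest**: 50 trees, depth ≤ 8, bootstrap fraction 0.7, greedy
splits maximizing Shannon-entropy reduction, modal vote.  **SVM**: linear
two-class maximum-margin separator (standing vs falling), Pegasos-style
deterministic subgradient descent with projection, λ = 1/(C·n), C = 10;
after training the separator is rescaled so the minimum functional margin is
1, the canonical form in which the margin constraints hold exactly on
separable data.  Features are z-scored with statistics fitted on the
training split only.

**Recurrent stack** (all four variants): per-frame FC (7 → 32) + ReLU, a
recurrent layer of inner size LS = 100 (projection p = 32 for the projected
variant), a final FC to 3 classes and softmax.  The constant forget bias
(default 1) goes on the forget-gate pre-activation; a strict switch places
it on the output gate for comparison with the alternative printed
convention.  The projected LSTM recurs through p_t = P·h_t (U ∈ R^{4LS×p})
and emits p_t, so its parameter count 4·LS·(m+p+1) + LS·p is below the
plain LSTM's whenever p(LS+m+p) < LS(LS+m) — comfortably true at the
defaults.  Gradients are exact BPTT, verified against central finite
differences at 1e-5 relative for every variant.

**Training.**  Adam at the flat rate 0.001 (plain SGD available), batch 128,
10 epochs, reshuffling every epoch with the run seed; trailing partial
batches are dropped, so iterations per epoch are ⌊n/128⌋ — 87 under the
80-20 split of the default synthetic dataset, 54 under 50-50.  Hidden sizes
are package defaults (the source hardware study never printed them) of a
magnitude consistent with a ~50k-parameter footprint.

**Sequence framing.**  Windows of 20 frames (2 s) at stride 1, window label
= majority frame label (ties → smallest code).  Stride 1 keeps samples
frame-denominated: the default dataset yields ≈ 13,900 windows, matching
the ⌊n/128⌋ per-epoch iteration counts of the reference protocol (51 at
50-50, 83 at 80-20); coarser strides are supported but break that
correspondence.

## Evaluation

Ratio splits stratify by class by default (switchable) and cut at
⌊ratio·n⌋; leave-one-out holds out one experiment (track) per fold and
reports fold means, with confusion matrices accumulated across folds.
Precision/recall/F1 are macro-averaged over the three classes (the balanced
alternative given the class design; accuracy doubles as the micro view);
AUC is the mean one-vs-rest Mann-Whitney statistic with tie correction,
classes absent from the truth being excluded with a flag.

## Resource profile and quantization

FLOPs use an explicit convention — multiply-accumulate = 2, nonlinearity
= 1, elementwise op = 1 — itemized per layer so every total can be re-derived
from the shapes.  Parameter counts are closed-form per variant and are
cross-checked structurally against the stored arrays.  Qm.n quantization is
round-to-nearest with saturation at [−2^(m−1), 2^(m−1) − 2^−n] (sign bit
inside the integer field; the half-step reconstruction bound is
property-tested).  Quantized inference requantizes after every matrix
product (wide accumulator assumed) and every nonlinearity (standing in for
a lookup table), applied post-training to weights and activations — no
quantization-aware retraining.  On the synthetic dataset 32(16.16) inference
is indistinguishable from float (< 0.5 points) and 8(4.4) degrades accuracy
by under 2 points, the bounded-degradation pattern expected of a
well-conditioned network with large decision margins.

## Scale and determinism

Everything is a pure function of (config, seed): dataset generation, split
shuffling, weight initialization and epoch shuffling all derive from
explicit `numpy` generators, and a repeated run reproduces learning curves
bit for bit.  The full study protocol (`run_study`) crosses 7 methods with
6 plans; at default dimensions the leave-one-out retraining of the
recurrent variants dominates the cost, so the test suite exercises the
orchestration at reduced dimensions and reserves the full-size runs for the
reference 80-20 and 50-50 splits (roughly half a minute per recurrent
variant on one CPU).

## Known limitations

- Synthetic Gaussian bodies make the three classes more separable than
  human recordings; reported synthetic accuracies (≈ 99%) are upper bounds
  on realism, useful for correctness and calibration, not benchmarks.
- The fall detector keys on a single spot's z derivative; a dampened fall
  (caught on furniture) with a slow descent can stay under the threshold —
  the reason the pipeline classifies postures from cloud shape rather than
  relying on speed alone.
- The SVM is linear and binary by design; multiclass problems belong to the
  other methods.
- Quantized inference emulates fixed point in floating point; it reproduces
  the arithmetic's rounding and saturation, not its execution time.
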