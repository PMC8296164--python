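# Methods

## Problem and system model

Patients who cannot reposition themselves develop pressure ulcers where
sustained contact pressure (above roughly 32 mmHg) occludes capillary flow —
typically at the sacrum, heels, shoulder blades and trochanters. The package
models a smart medical bed built from 20 horizontally partitioned bed
segments (HoPBs): independently height-adjustable slats, each carrying 10
pressure sensors, each able to move ±40 mm. Every 80 s control period the
system (1) reads a 32×64 pressure image, (2) classifies the lying posture,
(3) scores per-slat ulcer risk from calibrated pressure and dwell time, and
(4) moves the slats via Mamdani fuzzy inference to shed pressure from
at-risk tissue onto support areas.

## Coordinate convention

A frame is 32 rows × 64 columns. Columns run along the bed's long axis
(column 0 at the head end); rows run across its width. The 20 slats
therefore partition the 64-column axis (3.2 sensor pitches per slat) and the
10 pooled cells per slat partition the 32-row axis. Left/right body
mirroring is a reflection across the row axis, which leaves every slat's
aggregate pressure unchanged — slats span the full bed width.

## Synthetic pressure generator

Each posture template is a list of anisotropic Gaussian contact blobs
(center, axes, orientation, peak pressure) for the load-bearing body parts.
The ten templates cover the supine family (symmetric about the bed's lateral
midline), right/left lateral and right/left fetal postures; left-side
templates are exact mirrors of right-side ones, so the generator satisfies
mirror symmetry by construction. Body variability enters through four
parameters: `height_scale` (0.8–1.2, stretches the template along the long
axis), `weight_scale` (0.8–1.2, scales peaks; total load is monotone in it),
`lateral_offset` (±3 pitches) and `noise_sd` (0.5–2.0 pressure units of
additive Gaussian sensor noise, truncated at zero because sensors report
non-negative pressure). Peaks are calibrated so the average body's sacral
blob exceeds the 32-unit threshold, making the risk pipeline exercisable at
default settings.

What the generator does *not* emulate: soft-tissue mechanics, postural
micro-movements, sensor cross-talk or drift, and real inter-subject shape
diversity beyond the four parameters. Classifier scores on this generator
therefore demonstrate that the architecture and training loop work, not that
they transfer to clinical pressure-mat data.

## Preprocessing

* **Pooling.** 32×64 → 20×10 by exact fractional area-overlap averaging
  (each output cell integrates its 3.2×3.2-sensor footprint; sensors
  straddling a boundary contribute proportionally to covered area). This
  preserves constants and conserves total load to machine precision —
  nearest-neighbour resizing would do neither.
* **Heat units.** A slat's heat is the *mean* of its 10 pooled cells:
  risk is framed as pressure per unit slat area, so the aggregate must not
  grow with contact area alone.
* **Calibration and ulcer levels.** Over a calibration sample, the mean of
  strictly positive heats is pinned to level 10 and the sample maximum to
  level 20. The level map is the simplest curve through the three anchors:
  0 at no contact, linear (0, mean] → (0, 10], linear (mean, max] → (10, 20],
  clamped at 20. Integer levels use round-half-up for platform-independent
  ties. Calibration is computed over the training sample, not per frame.
* **Phases and time levels.** Levels bin into phases by width 4
  (1–4 → phase 1 … 17–20 → phase 5; 0 = no contact); consecutive 80 s
  periods in one posture bin into time levels by width 2, saturating at 8.
  These widths make the rule grid 20 slats × 10 postures × 8 time levels ×
  5 phases = 8000 rules.
* **Split.** A seeded permutation with one held-out fold of size ⌈n/5⌉:
  n = 20,024 gives the 16,019/4,005 partition used for training/testing.

## Posture classifier

A multi-input convolutional-recurrent network over windows of 5 pooled
20×10 grids: two 3×3 valid convolutions (8 and 16 channels, ReLU) with
global average pooling embed each grid; the embedding, concatenated with a
raw per-slat summary (the 20 slat means), feeds an LSTM (32 units) whose
final hidden state drives a 10-way softmax. Windows are built with stride 1
inside single-posture segments only, so no window mixes labels.

The network is implemented directly in numpy with hand-written reverse-mode
gradients (im2col convolutions, backpropagation through time, Adam,
forget-gate bias initialised to 1). This keeps initialisation, shuffling and
the whole training loop deterministic for a fixed seed; gradients are
verified against central differences in the test suite. Defaults: learning
rate 3e-3, batch 64, 20 epochs — at 200 windows per class this trains in
about a minute on one CPU and reaches ceiling accuracy on the generator.
Ties in the argmax resolve to the lowest class index. Evaluation reports a
10×10 confusion matrix with per-class and support-weighted
precision/recall/F1; classes absent from a test set get zero metrics, a
warning, and zero weight.

## Fuzzy controller

Standard Mamdani semantics: AND = minimum over antecedent degrees,
implication = truncation at the firing strength, aggregation = pointwise
maximum, defuzzification = centre of gravity. Slat and posture are
categorical, so they enter as crisp singleton selectors — fuzzifying an
index has no semantics — and each inference touches one (slat, posture)
cell of 40 rules.

Membership functions (fixed design choices, not fitted):

* TimeLevel on [1, 8]: 8 triangles centred at 1…8, half-width 2.
* UlcerLevel on [0, 20]: 5 triangles at the phase-bin midpoints
  2.5, 6.5, 10.5, 14.5, 18.5, half-width 4.
* HoPBControl on [−2, 2]: five symmetric triangles — Large Descent
  (−2, −1.5, −1), Slight Descent (−1.2, −0.6, 0), Not Moving (−0.6, 0, 0.6),
  Slight Rise (0, 0.6, 1.2), Large Rise (1, 1.5, 2). Symmetry makes a
  single-rule centroid independent of truncation height, and the centre
  spacing puts mixed-rule outputs in the ±0.6–1.1 range appropriate for
  gentle slat adjustments.

The 8000 consequents are generated from a per-posture body-region map
(which slats carry the head/shoulders/sacrum/heels in each posture; the
supine map is slat 4 cervical, 5–6 shoulders, 7–8 spine, 9–11 pelvis, 16
calf, 18 heel). The policy: pressure-prone slats hold still through phase 3
(descending from phase 3 only after long dwell), descend at phase 4 and
escalate to Large Descent when phase 5 persists; "support" slats within two
pitches of a prone region rise at low phase once dwell builds, taking over
load; all other slats hold still through phase 3 and descend beyond. The
policy is non-increasing in phase at fixed slat/posture/time, and the region
map is an ordinary Python mapping that callers can replace. Rules serialize
one per line (`HoPB1 & Supine & Time1 & Phase 4 -> SlightDescent`).

Rule purging removes rules whose maximum firing strength over a calibration
input set is ≤ ε; because aggregation is a max over fired rules, purging
never-fired rules provably leaves calibration outputs unchanged.

**Numerics.** COG uses trapezoid quadrature on a uniform grid over [−2, 2]
with step 5×10⁻⁴. Trapezoid error on these piecewise-linear aggregates comes
only from kinks off the grid and scales as h²; at this step the COG agrees
with a 10×-refined grid to ≲6×10⁻⁷ (a step of 10⁻³ was measured at up to
2.2×10⁻⁶ and rejected for the 10⁻⁶ accuracy budget). A zero-area aggregate
defuzzifies to 0 (fail-safe: not moving), and slats with level 0 bypass
inference entirely and hold still.

## Bed simulator

Heights update as `clip(h + 20 mm × setting, ±40 mm)` — the 20 mm/unit gain
maps the output universe [−2, 2] exactly onto the hardware's ±40 mm range.
Pressure redistribution is deliberately minimal: slat i attenuates its
columns by max(0, 1 + h_i/40), and the shed load is reassigned
proportionally to remaining contact so the frame total is conserved (the
only defensible constraint without a contact-mechanics model). The degenerate
all-slats-lowered case cannot conserve load through attenuation; it is
reported via a warning and the load stays on the least-lowered slats.
Dwell counters are per-slat: a counter increments each period the slat is in
contact under an unchanged posture and resets on posture change or contact
loss. Any slat at phase ≥ 3 raises an immediate-reposition flag in the
period log. The guidance report lists the posture, each at-risk slat with
its body-region name and phase, contacted slats, and a recommendation
(maintain / schedule a change / immediate reposition).

## Study conditions and problem sizes

Tests and the acceptance workflow run the classifier at 200 windows per
class (2000 windows, 80/20 split, 20 epochs) — the package's desk-scale
stand-in for the ~20k-frame public corpus — and verify the
16,019/4,005 fold arithmetic at n = 20,024 directly. Oracle-equivalence
checks run 100 random crisp inputs against an independent all-8000-rule
dense-grid evaluation.

## Known limitations

* The consequent policy and membership placement are design choices of this
  package; controller outputs are validated qualitatively (sign,
  monotonicity, magnitude range) and against its own numeric oracles, not
  against any bed's recorded actuation log.
* The redistribution model has no lateral coupling or tissue mechanics.
* The classifier is validated on the generator only; no claim is made about
  accuracy on real pressure-mat recordings.
* Body-region maps for non-supine postures are plausible defaults, not
  clinically validated.
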