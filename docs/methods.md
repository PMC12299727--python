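# Methods

`gaitwin` implements and validates, end to end on synthetic cohorts, a
pipeline for extracting temporal gait parameters (stride, stance, swing
and double-support time) from a single smartphone-sized IMU carried
loosely in the hand, trouser pocket or jacket pocket. Two measurement
chains are compared: an optical-marker chain that defines the reference
("experimental", M1) gait events, and an IMU chain in which a windowed
conv+LSTM classifier detects the events ("predicted", M2). The agreement
battery — relative RMSE, tiered Pearson association, Bland–Altman bias and
95% limits of agreement — quantifies how faithfully the IMU chain
reproduces the reference parameters.

## The synthetic cohort

Real cohorts of this kind (treadmill walking with optical motion capture
plus a carried IMU) are rarely public, and every downstream stage needs
exact ground truth to be testable. The simulator therefore generates the
full factorial design — subjects × belt speeds (1.0, 1.25, 1.5 m/s) ×
carry placements (hand, trouser pocket, jacket pocket) — from an explicit
event schedule, then renders markers and IMU signals from that schedule.

**Subject model.** Each subject draws a base stride time (uniform
1.02–1.18 s, referenced to 1.25 m/s and scaled as `(1.25/v)^0.3` with belt
speed `v`), a double-support fraction of the cycle (0.110–0.150, with
stance fraction = 0.5 + half of it, so the two are mutually consistent), a
per-cycle stride-time coefficient of variation (0.8–1.8%, jitter clamped
at 3 sigma), a heel-strike impact amplitude (1.2–2.2 g) and a left/right
phase asymmetry ratio (0.99–1.01). These ranges put every cycle's
double-support time in the physiological 0.1–0.2 s band and stride times
in roughly 0.97–1.26 s across all three speeds, and give ~80 strides per
side in a 90 s trial. Between-subject stride-time variance is what makes
inter-subject association measurable.

**Event schedule.** Left heel strikes accumulate jittered stride times;
right heel strikes sit at the asymmetry-scaled half-stride phase; toe-offs
follow each heel strike by the stance fraction of that cycle. The schedule
yields the truth event list and, by direct arithmetic, per-cycle truth
parameters (each cycle contains two double-support phases, each ending
with a contralateral toe-off). Optional condition transitions transiently
lengthen strides and are recorded as timestamps so the cycle filter's
transition rule can be exercised.

**Markers (100 Hz, mm).** Each side's vertical calcaneus track is a
baseline plus a smooth swing bump (two half-cosines, apex at 57.6% of
swing) and a 6 mm raised-cosine dip centered at each heel strike; the
metatarsal track is analogous with its dip at toe-off. The bump ends with
zero slope 70 ms before the next dip, so each dip sits on a locally flat
baseline and is the only local minimum in its neighborhood; with zero
measurement noise the band-minimum rules recover truth exactly up to grid
quantization. The apex placement puts heel strike at ~18% and toe-off at
~76% of the apex-to-apex interval — inside the 0–30% and 40–80% search
bands with margin for stride jitter. Gaussian marker noise (0.5 mm
default) models mocap residuals.

**IMU (1259 Hz; acceleration in g, angular rate in deg/s).** Channels
combine (i) a gravity projection with slow orientation wobble, (ii)
stride-periodic body motion phase-locked to the cycle, (iii) an event
transient at every heel strike and toe-off — a low-frequency raised-cosine
deceleration pulse (half-width 55 ms at heel strike, 75 ms at toe-off,
toe-offs at 55% amplitude) plus an exponentially damped 18 Hz burst — and
(iv) placement-dependent artifacts. The four event streams get distinct
channel mixtures, and left-side events are attenuated with flipped
gyroscope sign (the sensor rides on the right side of the body), so the
streams are separable in principle. The low-frequency pulse is what
survives the 10 Hz low-pass downstream; the burst mostly does not, which
is deliberate: detectability must not hinge on out-of-band energy.

**Placement effects.** Transient attenuation (hand 1.0, trouser 0.85,
jacket 0.60), broadband accelerometer noise (0.02 / 0.055 / 0.08 g, chosen
so that total >10 Hz power orders jacket > trouser > hand even though the
hand carries the strongest unattenuated impact bursts), a mechanical delay
jitter between skeletal event and sensed transient (4 / 7 / 15 ms SD) and,
for the jacket only, a 0.9 Hz pendulum sway (0.25 g). The delay jitter is
the irreducible error floor of the IMU chain and is what degrades the
jacket condition most, mirroring the qualitative placement ordering such
experiments report.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue and clothing dynamics beyond a
single sway tone, sensor re-orientation inside a pocket, non-stationary
gait (fatigue, turns), pathological gait patterns, marker occlusion and
mislabeling, and any spatial (distance-related) quantity. Results on this
cohort demonstrate correctness of the machinery and the error *mechanisms*
(window quantization, parameter magnitude), not clinical accuracy.

## Signal preparation

IMU streams are downsampled from 1259 Hz to the 100 Hz mocap rate
(zero-phase 8th-order anti-alias Butterworth at 45 Hz, then linear
interpolation onto the half-open target grid), low-pass filtered with a
4th-order Butterworth at 10 Hz, and robust-scaled per channel
((x − median)/IQR, quartiles by linear interpolation; a zero-IQR channel
is flagged degenerate and passed through centered). Filtering is
forward–backward by default: a causal filter would delay event signatures
by tens of milliseconds, biasing every event time, and zero-phase
filtering is the gait-lab standard; the effective attenuation doubles
(half-power at the cutoff). The scaler is fitted per trial — the
deployment-realistic choice, since no training statistics exist for a new
phone — and windows of 200 ms are cut every 100 ms, trailing partial
windows dropped to keep the model input shape fixed.

A window is labeled positive for one of the four event streams only when
an event of that stream falls within the central 45–55% of the window
(endpoints inclusive). Note the geometry this implies: the central band is
20 ms wide while training windows start every 100 ms, so an event labels
at most one window and only ~20% of event phases label any window at all.
Sparse positives are intentional — they teach the classifier temporal
precision — but they dictate the inference-time design below.

## Event detection

One classifier per event stream (heel strike / toe-off × left / right),
since each parameter needs typed, sided events. The network is a small
conv+recurrent stack: two valid 1-D convolutions (kernel 5, widths 16 and
32, ReLU) over the 20×6 window, an LSTM (32 units) over the remaining 12
steps, and a sigmoid read-out of the final hidden state. It is implemented
directly in NumPy (im2col convolutions, backpropagation through time,
Adam, inverted dropout 0.1 on the read-out), trained for 12 epochs with
batch 256 and learning rate 3e-3 on a class-weighted binary cross-entropy
(positive weight = negatives/positives on the training fold, ~45 here;
unweighted training collapses to the majority class). All randomness flows
from one seed and runs are bit-reproducible; the backward passes are
verified against central finite differences in the test suite.

The split is at subject granularity (80/20 by default,
leave-one-subject-out available), asserted leak-free on every run.

**Reconstruction of event times.** Supra-threshold windows (default 0.5)
are grouped into runs of temporally adjacent windows; each run yields one
candidate at the confidence-weighted mean of its window centers, and
within any 0.4 s refractory span (the minimum plausible stride interval at
these speeds) only the highest-confidence candidate survives. One design
point matters: the trained classifier is sharply shift-sensitive — its
probability collapses for events more than ~30 ms from the window center,
a direct consequence of the labeling band — so detection slides the
inference windows at a 20 ms hop rather than the 100 ms training hop.
At the training hop the nearest window center can be 50 ms from an event
and recall saturates near 60% regardless of threshold; at 20 ms some
window always falls inside the firing band, and measured recall is ~1.0
with median timing error under 10 ms. Training strictly keeps the
200 ms / 100 ms scheme.

## Ground-truth events from markers

Foot-motion peaks are the swing apexes of the (10 Hz-filtered) calcaneus
track, found with prominence ≥ 10 mm and separation ≥ 0.4 s (stride times
at these speeds exceed 0.8 s; both configurable). Heel strike is the
minimum of the calcaneus track within the first 30% of each apex-to-apex
interval; toe-off is the minimum of the metatarsal track between 40% and
80% of the same interval. Interior local minima are preferred; on a
monotone band the band's global minimum (possibly a boundary sample) is
the deterministic fallback, and ties break toward earlier time. Which
signal defines the "foot motion peak" is a convention of this package
(apex-per-stride makes the search bands well defined), not an established
standard; the search-band rules themselves are the published ones.

## Cycle parameters and quality filter

Per side, each consecutive heel-strike pair defines a cycle: stance is
heel strike to the next ipsilateral toe-off, swing is that toe-off to the
cycle-closing heel strike (so stance + swing = stride by construction),
and double support is the total time inside the cycle during which both
sides' stance intervals overlap — computed by interval intersection, which
implements the definition literally and tolerates missing contralateral
events (a stream-leading toe-off opens an interval from the left, a
trailing heel strike leaves one open to the right). The intersection is
cross-checked in tests against a 1 ms occupancy oracle and against the
simulator's configured per-cycle values.

The quality filter excludes, in order of precedence: incomplete cycles
(no intervening toe-off), cycles with any negative duration, cycles whose
span contains a marked condition transition, and strides outside
[0.4, 2.5] s (a configurable plausibility band; negativity and transitions
are the canonical causes, the bounds catch the rest). Left and right sides
are pooled for aggregation, and condition-level means are taken per
subject × speed × placement. A left/right symmetry index is provided as
the normalized absolute mean difference, 100·|R̄−L̄|/(½(R̄+L̄)) — one of
several formulas in use; the choice is this package's.

## Agreement battery

Predicted cycles are paired to reference cycles by greedy nearest
heel-strike matching within 0.25 s (each cycle used at most once;
unmatched cycles counted and dropped — a spurious extra detection can
never silently inflate agreement).

* **Relative RMSE**: 100·RMS(M2−M1)/mean(M1), computed per
  subject × speed × placement and summarized per speed × placement cell by
  median, IQR and a seeded percentile-bootstrap 95% CI of the *mean*
  (1000 draws). A mean CI is used deliberately: rRMSE distributions are
  right-skewed (skewness is reported as Fisher–Pearson g1), and under
  right skew the sample median can fall below the mean CI's lower bound —
  a property the summary preserves rather than hides. The M1-mean
  denominator is the dominant convention in the gait literature.
* **Pearson association** on condition-level means (one point per
  subject × speed × placement), tiered weak (r < 0.3) / moderate
  (0.3 ≤ r < 0.6) / strong (r ≥ 0.6), with the two-sided t-transform
  p-value and * p < 0.05 / ** p < 0.001 annotations.
* **Bland–Altman** on the same points, differences oriented M1−M2: bias,
  bias ± 1.96·SD (sample SD, n−1) limits, and the percentage of points
  inside the limits; reported per placement and pooled.

## Orchestration and numerical choices

A single master seed derives per-stage seeds (simulate / split / model /
stats) through `SeedSequence` with a CRC-stable stage tag, so the whole
experiment is reproducible bit for bit and stages can be re-run in
isolation. Every intermediate (manifest, both cycle sets, paired cycles,
the three report tables, stage seeds and exclusion tallies) is persisted
as CSV/JSON. The default experiment is sized for a desk machine: 10
subjects × 3 speeds × 3 placements at 90 s per trial (~81k training
windows; the full run takes a few minutes on one CPU). Degenerate inputs
are handled explicitly: upsampling requests, NaNs, cutoffs at or above
Nyquist, inverted label bands, single-class training labels, single-
subject cohorts and empty event sets all raise or degrade with a logged
warning rather than guessing.

## Known limitations

* The conv+LSTM stand-in is desk-scale; it preserves the architecture
  contract, not any particular published network's capacity or its
  event-level metrics.
* Cycle pairing by nearest heel strike is a pragmatic alignment; with
  gross detection failure (many missed events) matched pairs can still
  represent different physical cycles, which inflates rRMSE rather than
  hiding error.
* The Bland–Altman "% within limits" statistic is computed against limits
  estimated from the same sample; with ~18 points per parameter its
  expected value sits near, not exactly at, 95%.
* Synthetic-cohort results bound what the machinery can do under the
  modeled artifact structure; they are not evidence about human data.
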