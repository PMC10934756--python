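# Methods

`drowsikit` implements a multimodal driver-drowsiness monitor: four
independent detection channels produce unit-interval alertness scores over
sliding windows, and a Mamdani fuzzy inference system fuses three of them
into a crisp drowsy/alert decision. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic study
design does and does not show.

## Eye aspect ratio (EAR)

For six eye-contour landmarks p1..p6 (p1 outer corner, p2/p3 upper lid,
p4 inner corner, p5/p6 lower lid, counter-clockwise),

    EAR = (‖p2 − p6‖ + ‖p3 − p5‖) / (2 ‖p1 − p4‖).

The ratio of Euclidean distances makes EAR invariant under translation,
rotation and uniform scaling of the landmark set, and monotone in the lid
separation when the corners are fixed. Closed intervals are maximal runs of
frames with EAR strictly below a threshold (default **0.2**, the
conventional operating point in the EAR literature; equality counts as
open). Intervals are half-open `[start, end)` in 0-based frame indices.

Blink events are closed intervals whose duration falls in
**[0.04 s, 0.5 s]**; longer closures are prolonged eye closure — drowsiness
evidence in its own right — and deliberately excluded from the blink list so
that the blink-rate statistic and the eye-closure fraction remain distinct
signals. The EAR fusion score is the fraction of frames at or above the
threshold (1 = eyes open throughout the window).

Landmark detection itself is out of scope: landmarks arrive as CSV records
(`frame_index, x1, y1, …, x6, y6`) or from the synthetic generator.

## EOG blink signatures

Three periocular channels (EOG1/EOG2 horizontal, EOG3 vertical) carry two
pulse classes: **S1**, a biphasic positive-then-negative wave, modelled as a
derivative-of-Gaussian, and **S2**, a monophasic bump, modelled as a
zero-mean Gaussian. Template width defaults to **150 ms**; the shapes are
parametric stand-ins chosen for the qualitative morphology, since no
closed-form waveforms exist for these pulse classes.

Processing: linear detrend, 4th-order Butterworth band-pass **0.5–20 Hz**
(zero-phase `sosfiltfilt`), then sliding normalised cross-correlation with
each template at **250 Hz** (all configurable). Correlation local maxima
above **0.7** become candidates. Because normalised correlation is
scale-invariant, smooth band-limited noise alone can exceed any correlation
threshold; candidates must therefore also carry a least-squares fitted
template amplitude of at least **3×** the channel's robust noise level
(MAD/0.6745). Within one template length the best-scoring candidate wins and
its kind is the better-matching template, so pulse kinds are mutually
exclusive per location.

A blink is the channel configuration **EOG1 = S2, EOG2 = S1, EOG3 = S1**
with all three pulse times pairwise within the coincidence tolerance
(**50 ms**). Matching is greedy earliest-first with single-use pulses —
deterministic and checkable against an exhaustive maximum-matching oracle
(the tests do exactly that). Other configurations (S1/S1/S1, S2/S2/S2 …)
correspond to non-blink eye movements and are ignored.

The EOG fusion score maps the window's blink rate r against an alert
baseline r₀ (**15 blinks/min**): `score = max(0, 1 − |r − r₀|/r₀)`. Both
absent blinking (microsleep) and doubled blinking lower the score to 0; the
linear map is a documented invention, as no standard reduction of blink
evidence to a unit score exists.

## EEG spectral classification

PSD estimation is Welch's averaged periodogram with **1 s Hann segments,
50 % overlap**, density scaling (total power tracks time-domain variance
within the windowing tolerance; tested at 5 %). Band powers integrate the
PSD over delta [0.5, 4), theta [4, 7), alpha [8, 12], beta [13, 30] Hz by
the trapezoid rule. The (7, 8) and (12, 13) Hz gaps stay unassigned,
matching the band definitions as stated rather than smoothing them.

Drowsiness is flagged by alpha-peak prominence: the largest PSD bin in the
**10–12 Hz** search window, divided by the median PSD over [0.5, 30] Hz with
the whole alpha band excluded. A sharp alpha peak gives a ratio far above 1,
flat noise gives ≈ 1; the epoch is DROWSY when the ratio reaches the
threshold (default **3.0**, configurable — chosen so that broadband noise at
its natural fluctuation never crosses it while a sinusoidal alpha component
at SNR ≥ 3 always does). The EEG fusion score is
`clip(1 − ratio/(2·threshold), 0, 1)`, which passes 0.5 exactly at the
classification boundary.

## Eye-state networks

Images are cropped, anti-aliased down-sampled to **51×51** (2601 pixels) and
scaled to [0, 1] (integer rasters by dtype maximum; float rasters above 1 by
their own maximum; floats already in [0, 1] untouched, so constant images
keep their value). Upsampling is refused. Rasters are flattened row-major
into the 2601-wide input layer.

Two variants share the training machinery:

* **MLP_1H** — 2601–10–2, sigmoid hidden units, softmax output,
  cross-entropy with L2 penalty 1e-4, full-batch L-BFGS to a loss-change
  tolerance of 1e-5 or 500 iterations.
* **STACKED_AE** — 2601–100–50–2. Greedy pretraining: autoencoder 1
  (2601–100–2601, sigmoid code, linear reconstruction, MSE), autoencoder 2
  on the level-1 codes (100–50–100), softmax head on the level-2 codes, each
  for up to 60 L-BFGS iterations; then end-to-end fine-tuning of the
  assembled classifier (up to 200 iterations). The hidden widths 100/50 are
  a design choice; pretraining budgets are set where reconstruction loss has
  clearly dropped (recorded in `history`) and further iterations no longer
  change the fine-tuned classifier's holdout behaviour.

Training is a pure function of (data, seed, hyperparameters): Glorot-uniform
initialisation from `numpy.random.default_rng(seed)` and deterministic
full-batch L-BFGS make refits bit-identical, which the tests assert.
The corpus design is 100 images per class (200 total), 70 + 70 for
training and 60 held out (30 + 30 per class). The FR fusion score is the
fraction of window frames classified open/half-open.

## Mamdani fusion

Three scores (channel 1 = EEG or EOG, selected by configuration; channel 2 =
FR; channel 3 = EAR) enter a Mamdani system with two linguistic terms per
input (L low/drowsy evidence, H high/alert) and two output terms (DR mass
below 0.5, AL above). The rule base covers all 8 corners of {L, H}³ with the
majority rule: **DR exactly when at least two antecedents are L**. Stack:
AND = min, implication = clip, aggregation = pointwise max, defuzzification
= area centroid on a 1001-point output grid; crisp < 0.5 ⇒ DROWSY, ties to
ALERT (DR sits below AL on the output axis).

Default trapezoids: input **L = (0, 0, 0.5, 0.8)**, **H = (0.2, 0.5, 1, 1)**;
output **DR = (0, 0, 0.3, 0.5)**, **AL = (0.5, 0.7, 1, 1)**; all
configurable. The input plateaus deliberately overlap at 0.5 so that
max(L(x), H(x)) = 1 for every x. This is load-bearing: with a majority rule
base, an input's H degree feeds the one DR rule where the other two inputs
are L, so term pairs that both dip mid-range (e.g. L ending at 0.6 and H
starting at 0.4) make the crisp output bump non-monotonically as that input
sweeps 0 → 1. With the overlapping plateaus the crisp output is
non-decreasing in every input — verified exactly on a 21³ grid — while
corner decisions, midpoint symmetry (crisp(0.5, 0.5, 0.5) = 0.5) and input
permutation invariance are unchanged.

## Pipeline

Windows default to **10 s with a 5 s hop** — long enough for a blink-rate
estimate to be meaningful (2–3 expected blinks at baseline) and for a Welch
PSD with 1 s segments, short enough to localise a drowsy episode to ±5 s.
Every window's label is exactly the fuzzy decision on that window's three
scores; the only cross-window state is the warning gate, which opens after
**2** consecutive DROWSY windows and closes at the next ALERT window.

## Synthetic data

The generators define the study conditions; all are pure functions of
(parameters, seed):

* **Eye images** — schematic rendering (bright almond aperture + dark
  iris/pupil for open; dark horizontal crease for closed) with per-seed
  geometry jitter and additive Gaussian noise (default sd 0.05). After
  down-sampling to 51×51 only coarse structure survives in real crops too,
  so coarse structure is the honest target; the corpus is linearly separable
  by design, which is what makes the perfect-holdout expectation meaningful.
* **Landmarks** — corners fixed, lid points displaced by
  openness·max_lid_gap/2, so EAR is exactly proportional to openness.
* **EOG** — template pulses injected at scenario blink times with
  per-channel jitter below half the coincidence tolerance, optional
  distractor triples, Gaussian noise at a stated amplitude SNR (default
  study condition SNR 5).
* **EEG** — DROWSY: a sinusoid at a seeded frequency in [10, 12] Hz over
  1/f-weighted noise at SNR 3–5; ALERT: beta-band (13–30 Hz) weighted
  broadband over the same background.
* **Sessions** — 60 s at 25 fps with one 15 s drowsy span (eyes closed,
  blinking stopped, alpha-dominant EEG) and baseline 15 blinks/min
  elsewhere.

What passing these conditions does **not** show: robustness to real-world
nuisance — lighting, head pose, electrode drift, EMG/motion artifacts,
non-stationary alpha, individual baseline variation. The synthetic corpus is
separable by construction, so perfect classification demonstrates that the
training and inference machinery is correct, not that the architecture
would separate real driver imagery. On-road recordings would be needed for
any claim about deployed accuracy.

## Degenerate inputs and tie-breaks

Coincident eye corners raise on construction; empty series, single-class
training sets, out-of-range scores and zero-area aggregate curves raise
`ValueError` with a description. EAR equality at threshold counts as open;
crisp ties at 0.5 label ALERT (a 1e-9 guard absorbs grid round-off at
exactly symmetric inputs); within one EOG template length the
higher-correlation candidate wins, earlier time breaking exact ties.
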