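# Methods

This note records the models, parameter choices, and numerical decisions
behind vte-kit, and what the synthetic study conditions do and do not
establish about real recordings.

## Trajectory features

Heading angles are computed from first differences of successive frames
(`phi = arctan2(dy, dx)`), with no smoothing by default; an optional
moving-average pre-smoother is deliberately not applied because the
original formulation is silent on it. Zero-displacement frames (the head
stationary between frames) carry no heading and hold the previous value.

Angular differences are wrapped to the shortest circular distance in
[0, π] by default. The raw `|phi_a − phi_{a−1}|` alternative (which counts
a ±π crossing as a ~2π turn) is selectable via `wrap=False`; wrapped is the
default because heading change is a circular quantity and unwrapped values
spuriously inflate IdPhi for westward travel.

All standard deviations (position SDs, session z-scores) use the
population convention (divisor N), matching numpy's default `std`.

zIdPhi is z-scored **within each session** over the retained trials, so a
session's zidphi column always has mean 0 and SD 1; consequently the
feature is only comparable within, not across, sessions — which is also
why the multi-feature tables carry raw IdPhi alongside. Seven features are
produced per trial: `x_sd, y_sd, zidphi, dur, r2, n_coef, idphi`. Raw
IdPhi is the seventh, togglable (`include_raw_idphi`); it is the only
natural per-trial candidate already computed that completes the announced
seven alongside the six listed.

`dur` is the dwell time inside a configurable choice-region polygon (an
even-odd ray-casting test; boundary points count as inside), summed over
inter-frame intervals whose starting frame is inside. The default region
is the simulator's 60 × 60 px center platform.

`r2 = 1 − SSE/SST` comes from an ordinary least-squares degree-6
polynomial fit of y on x (`numpy.polyfit`). Fits are refused when SST = 0
(no y spread). `n_coef` sorts the DFT magnitudes of the mean-removed
fitted curve and counts the bins needed for 95% of non-DC energy; a
constant estimate needs 0. Because the fitted curve is generally
non-periodic, smooth monotone fits still leak into several bins — the
feature is comparative (oscillatory sweep fits need more bins than smooth
arcs), not an absolute count of physical oscillations.

The zIdPhi baseline classifier scans thresholds at the 50th–80th
percentiles of the score distribution in 1-percentile steps and keeps the
threshold maximizing `(TPR + TNR)/2`, the two-point ROC area of a hard
classifier. In cross-validation the threshold is selected on each split's
training portion.

## Oscillation features

Raw wide-band traces are decimated ×30 (FIR anti-aliasing, zero-phase) to
1 kHz and z-scored over the full session, putting amplitude in SD units.
Plain subsampling is selectable but not default: 30× subsampling without
anti-aliasing folds >500 Hz noise into the band.

Theta cycles are landmarked on a zero-lag (forward–backward) third-order
Butterworth low-pass at 80 Hz. The low-pass order/type mirrors the stated
gamma filter design. Peaks are local maxima with an enforced minimum
separation of 0.0833 s (the 12 Hz upper edge of theta); the trough is the
global minimum between consecutive peaks, earliest sample on ties. Cycles
run peak → trough → next peak; descending = peak→trough, ascending =
trough→next peak; `AI = ln(asc) − ln(desc)` (natural log — the base only
rescales AI). No upper cycle-duration cap is applied by default; a 250 ms
cap is exposed.

**Estimator attenuation.** Landmark-based AI is biased toward zero by
additive wide-band noise and phase-locked gamma: the argmax of
signal + noise wanders toward the flatter (slower) side of an asymmetric
peak, and toward phases of high gamma variance. Under the simulator's
default amplitudes (theta 1.0, gamma 0.06/band, background 0.25) the
expected attenuation is roughly 30% of the generative AI. This is a
property of the estimator itself, not of the simulator; recovery tests
therefore check that the generative target lies inside the 95%
Monte-Carlo interval of per-trial estimates and that recovered means are
strictly ordered in the target.

Gamma bands (35–55 and 61–100 Hz) are filtered with third-order zero-lag
Butterworth bandpasses, z-scored **at the session level**, and squared
Hilbert-envelope power is taken per sample. Session-level normalization
matters: z-scoring each trial segment separately would erase exactly the
between-trial power differences the classifier needs. Per-cycle gamma
powers are averaged within each cycle first; trial statistics (mean, SD)
are then taken over cycles, so trial features are cycle-weighted rather
than sample-weighted — consistent with treating the theta cycle as the
unit of organization. `GR` is the per-cycle ratio of cycle-mean LG to
cycle-mean HG power; zero-HG cycles are skipped with a warning. The trial
vector has 12 entries: mean and SD of AI, GR, LG, HG, and cycle duration,
plus mean ascending and descending durations.

PSD features are single-window Hamming periodograms of the (already
z-scored) epoch, sampled at the 100 integer frequencies 1–100 Hz (native
resolution ≤ 1 Hz requires ≥ 1 s segments; nearest-bin lookup maps the
grid). Powers stay linear — no dB conversion. Feature selection runs a
two-sample two-tailed KS test per frequency and keeps Benjamini–Hochberg
survivors at α = 0.05. Inside cross-validation the selection uses the
training portion of each split only, preventing selection leakage. Note a
subtle confound of single-window periodograms: spectral-line bins (8 Hz
theta and harmonics) have duration-dependent statistics, so classes with
systematically different epoch durations can legitimately differ at the
theta line even with identical physiology.

The 4 SD artifact gate is applied to the full z-scored session trace
within the analyzed epoch (threshold in units of the whole-timeseries SD).

## Curation

Consensus over exactly four votes: 3–1 and 4–0 majorities label the trial;
2–2 ties are excluded. Majority is the only consistent completion of the
stated tie rule. Percent agreement and Cohen's κ (observed vs. marginal
chance agreement) are computed for each of the 6 rater pairs and averaged;
a pair with a constant rater has undefined κ, reported as NaN and omitted
from the average. Session gates: "more than 20% excluded" is strict
(12/60 keeps, 13/60 drops), and the AI-skew gate checks the sign of the
median per-trial AI against a configurable required direction (+1 by
default for this preparation; other electrode placements are reported to
skew negative, hence the configurability; 0 disables).

## Classification

The split matrix (default seed 1, 100 columns) puts every consensus-VTE
trial in every column plus an equal-sized draw of non-VTE trials sampled
without replacement within a column and independently across columns,
shuffles the column, and cuts train/test at `floor(0.67 · n)`. The same
matrix is reused across models and feature sets so per-split metric
differences are paired.

Standardization (train mean/SD; test transformed with train parameters)
precedes every fit; zero-spread training features are dropped with a
warning. KNN uses k = 5 with the Euclidean metric and scores a query by
the fraction of VTE neighbors, giving it a genuine ROC. The SVM is an
RBF-kernel soft-margin machine exposing its signed decision score. Its
grid is γ ∈ {0.01…0.1 step 0.01} ∪ {0.2…1.0 step 0.1} and C ∈ {0.1…1.0
step 0.1} ∪ {2…10 step 1} (19 × 19 = 361 pairs), selected by stratified
5-fold AUC within the training portion; ties resolve to the smallest C,
then the smallest γ. How the original selection AUC was computed is not
stated; internal CV is the conservative, leak-free choice and a possible
source of small discrepancies from reported hyperparameters. By default
`run_cv` tunes once on the first split's training data and reuses the pair
across splits (`tune='per_split'` re-tunes everywhere); at the package's
desk-scale problem sizes the first-split optimum is representative and the
full per-split search costs ~100× more fits.

The random-label baseline replaces each split's training labels with a
balanced uniform-random relabeling (seeded) at fixed moderate
hyperparameters (γ = 0.1, C = 1 — tuning on noise labels is itself noise)
and keeps real test truth, so its metrics quantify chance performance of
the identical pipeline. Δ scores subtract baseline metrics per split. Note
that when features are *strongly* clustered, a noise-trained classifier's
per-split AUC is bimodal near {0, 1} (it latches onto cluster structure
with a random sign); the mean is still 0.5 but single-split values are
not — chance calibration statements are about means over splits.

## Evaluation and statistics

Accuracy, precision, recall, and FNR come from confusion counts;
zero-denominator metrics are NaN (undefined), never 0. Hard labels use
score > 0.5 for KNN vote fractions and score > 0 for SVM decision values.
ROC curves sweep all score thresholds; the abscissa is the conventional
false positive rate, and the trapezoidal area is evaluated in integer
count space so the perfect-separation and all-ties limits are exact (1 and
0.5). This equals the Mann–Whitney concordance probability with ties
counted half, verified exhaustively in the tests. KS tests are asymptotic
by default (exact is exposed for small samples); the Wilcoxon signed-rank
drops zeros and mid-ranks ties; BH adjustment is the standard step-up with
enforced monotonicity; Cohen's d uses the pooled (n−1)-weighted SD.

## The simulator

The generator emulates the study conditions end to end. Sessions default
to 60 trials with VTEs at 20%, camera frames at 35 Hz in pixel units (arms
~190 px, center platform ±30 px), LFP at 1 kHz. Non-VTE trials are smooth
corner-rounded arcs from start arm through the center to the chosen arm;
VTE trials insert 1–3 head-sweep excursions toward the unchosen arm
(depth 18–85 px) before committing. Half of non-VTE trials contain one
shallow hesitation glance (12–60 px) — without such within-class
variability zIdPhi would separate the classes nearly perfectly, unlike
real data, where the overlap is the method's entire motivation. Run speed
is lognormal (median 80 px/s, CV 0.35) and tracking jitter is 0.5 px per
frame. Under these conditions the zIdPhi class separation lands at
d ≈ 0.8, with the multi-feature SVM/KNN in the 0.86–0.94
accuracy/AUC regime — the qualitative regime the method was designed for.

LFP theta is a phase-warped 8 Hz cosine: within each fixed 125 ms period
the trough is placed so that asc/desc = exp(AI target) exactly, giving
direct control of the quantity AI measures without changing the period.
Low gamma is a 40–50 Hz narrowband-noise carrier amplitude-modulated at
mid-ascending theta phase; high gamma a 70–90 Hz carrier modulated near
the peak (phases configurable). Class-conditional parameters apply only
during choice epochs (AI 0.18 vs 0.10; LG power ×1.3 vs ×1.0; HG ×1.08 vs
×1.0), so delay epochs are statistically identical across classes and the
"choice informative, delay not" contrast has a known ground truth. The
background is AR(1) pink plus white noise (SD 0.25 total against theta
amplitude 1.0) — strongly theta-dominant, as at the CA1 fissure. Rater
votes flip the truth independently per rater and trial (5% default),
which puts expected pairwise agreement at 90.5% and expected κ at 0.73,
just clearing the reliability gates.

Per-trial ground truth records the generative class, AI target, power
multipliers, and the realized band powers of the generated signal computed
by an independent spectral route (rFFT weighted by the analysis filter's
|H|⁴ zero-lag response), which is what the Hilbert-envelope recovery tests
compare against.

What the simulator does **not** emulate: tracking dropouts, non-stationary
theta frequency and amplitude, movement/EMG artifacts, volume-conduction
and electrode-placement effects on theta shape (including the negative AI
skew of other layers), cross-frequency phase drift, and rater biases that
correlate across raters. Green tests therefore establish that the pipeline
is correct and recovers known structure under its stated assumptions — not
that the effect sizes transfer to any particular recording.

## Problem sizes and determinism

The packaged experiments pool 4 simulated sessions × 60 trials (~238
trials, ~43 VTEs after curation) and use the full 100-column split matrix;
parameter-recovery runs use 100 synthetic trials. Every random step flows
from an explicit seed (`numpy.random.default_rng`); rerunning any
experiment with the same seed and configuration is bitwise reproducible.
The original study's headline numbers were computed on its own 828-trial
rat dataset, which has no public accession; they are not reproduced here,
but the package reproduces the study's *orderings* (multi-feature over
zIdPhi; choice-epoch LFP informative, delay not; combined features adding
nothing once trajectories are known) on synthetic ground truth.
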