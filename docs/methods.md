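# Methods

## Pipeline model

The package treats arrhythmia discrimination as a cascade of binary
decisions over fixed 8 s analysis windows, ordered by clinical urgency:
ventricular fibrillation first (a lethal rhythm must never wait on later
stages), then atrial fibrillation, then per-beat PVC detection, then a
deterministic grammar over the beat labels. The cascade is strict: a
window labelled VF or AF never receives an episode code, and windows whose
R-peak detection yields fewer than 5 beats are carried through flagged
`unclassifiable` rather than dropped.

## Preprocessing

All input is resampled to 300 Hz (polyphase, rational approximation of the
rate ratio), filtered with a 3rd-order Butterworth band-pass of 0.4–30 Hz,
and cut into 8 s windows advanced by 5 s (3 s overlap). Filtering is
applied forward-backward (zero phase): QRS morphology feeds the beat-level
features, and a causal IIR pass would skew it. Windows are standardised
individually to zero mean and unit (population) variance *after* cutting,
so every downstream consumer — in particular the fixed amplitude extent of
the phase-plot binning — sees the same scale regardless of slow amplitude
drift across a recording. The window length and step are parameters; the
end-to-end evaluation of multi-rhythm recordings uses step = 8 s so that
each analysis window coincides with exactly one ground-truth rhythm block.

## Stage 1: phase-plot image features

Two time-delay embeddings per window, lag 1 and lag 5 samples. The
trajectory is rasterised onto an 800×800 binary grid over amplitude
[−3, 3] (edge-clipped) as *connected line segments* between successive
embedded points, exactly as a plotted phase portrait is drawn. This choice
is load-bearing: the 45° line structures counted by F2/F3 are the chords
of smooth signal sweeps (s_{i+1} − s_i ≈ s_{i+2} − s_{i+1}), which exist
only in a connected rendering; marking isolated points produces no line
structures at any grid size. The resolution must also be high enough that
the lag-5 image remains a thin curve — on a coarse grid (~100 px) it
blankets the lag-1 image and the difference image B1 − B2 carries no
structure. Both resolution, extent and the rasterisation mode are
configurable.

Features: F1 is the difference of occupied-pixel fractions (lag-5 minus
lag-1). F2/F3 count maximal runs of set pixels along the (+1, +1) diagonal
direction, strictly longer than 20 px, on the *lag-1* image; measurement
during development showed that counting on the subtracted image inverts
the VF/non-VF direction, because subtracting the long, heavily overlapping
lag-5 trajectory erases precisely the near-diagonal chords the feature is
meant to capture. F4 follows the subtract-then-fill recipe: B1 − B2
(clamped to {0,1}), 4-connected morphological hole filling
(`scipy.ndimage.binary_fill_holes`), occupied fraction of the result.

F5 is the number of bins of the single-sided amplitude spectrum (FFT
length = window length = 2400, hence 0.125 Hz resolution; rectangular
window; unit-maximum normalisation) strictly above the mean amplitude over
the whole 0–150 Hz range. F6 is the Shannon entropy of a 16-bin amplitude
histogram over the data range, normalised by log₂ 16 to [0, 1]; the bin
count is a free choice — 16 bins keep the estimate stable at n = 2400
while leaving headroom below 1 for realistic signals.

## Stage 2: RR statistics

R peaks come from a Pan–Tompkins-style detector: five-point derivative,
squaring, 150 ms moving-window integration, adaptive signal/noise
threshold (initialised from the first 2 s, exponentially updated), 200 ms
refractory spacing, and refinement of each detection to the raw-signal
maximum within ±75 ms. Intervals outside [0.2, 3] s are discarded, then
intervals deviating more than 30% from the centred running median of five
(an ectopy exclusion; premature beats would otherwise masquerade as AF
irregularity). The three features — normalised RR histogram entropy,
turning point ratio with denominator n − 2 (ties count as non-turning),
and RMSSD divided by mean RR so thresholds transfer across heart rates —
are computed on the cleaned series. For windows with fewer than 8 cleaned
intervals the entropy bin count is capped at twice the interval count so
the statistic remains defined. The ectopy rule costs some genuine AF
variability in short windows (occasionally halving RMSSD), which is a
known trade-off of interval cleaning at 8 s scale; class separation is
unaffected because entropy and TPR remain high.

## Stage 3: beat features

Beats are the 200 samples [R−70, R+129]; windows crossing a segment edge
are skipped, not padded (padding would distort the beat spectrum). LMMD is
the max-minus-min of the window (window-global extrema; equivalent to the
QRS peak-to-valley for centred beats since P/T amplitudes are smaller).
MSA is the maximum of the *raw* single-sided amplitude spectrum —
normalising to unit maximum would make the feature identically 1. The
wavelet entropy uses a 4-level Daubechies-4 decomposition with
p_i = c_i²/Σc_j² over all coefficients, normalised by log₂ of the
coefficient count; kurtosis is the population, non-excess form (normal
≈ 3, minimum 1). Family, level and bin counts are parameters.

## Classifiers and evaluation protocols

Decision tree: Gini impurity, unlimited depth, minimum leaf 1 —
hyperparameters deliberately minimal; the features are designed to
separate, and the evaluation protocols expose variance honestly. Linear
SVM: C = 1, features standardised on the training split only (trees are
scale-invariant and stay unscaled). The unbalanced protocol draws 5 random
half/half splits of the pooled data; the balanced protocol subsamples the
majority class to the minority size B (5 outer draws) and splits each
balanced pool into B train / B test (5 inner draws), averaging 25 trials.
Splits whose training half lacks a class are re-drawn rather than failing
the run. All splits, subsamples and tree seeds derive from a single seed;
identical seeds give identical results. Metrics are sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and accuracy, in percent, mean ± sd
over trials.

## Stage 4: pattern grammar

The longest run of consecutive PVC labels decides NSR (0), couplet (2),
triplet (3) and VT (≥ 4). For isolated PVCs (longest run 1) the successive
differences of the PVC positions are taken; a modal difference of 2, 3 or
4 maps to bigeminy, trigeminy or quadrigeminy. Two cases the canonical
patterns leave open are resolved conservatively: a single isolated PVC
(fewer than two positions) and isolated PVCs with any other spacing map to
NSR, and a modal tie breaks toward the smaller spacing (bigeminy before
trigeminy before quadrigeminy). The mapping is a total function on
{0,1}ⁿ, n ≥ 1, verified exhaustively against an independent rule-tracing
oracle for n ≤ 10.

## Synthetic data

The generator exists so that every stage can be built and tested with
exact ground truth and no external recordings. Beat-based rhythms are
trains of Gaussian-bump PQRST templates (P/Q/R/S/T amplitudes 0.15 / −0.10
/ 1.00 / −0.25 / 0.35, physiologic widths) at a configurable heart rate
(default 75 bpm) with ≤ 2% Gaussian RR jitter; PVC beats drop the P bump,
double the QRS bump widths and scale QRS amplitudes to 1.6× the normal
peak-to-valley; AF removes the P bump and draws RR iid uniform on
[0.4, 1.2] s; additive white noise has sd 0.02 (relative to a 1.0 R-peak
amplitude). VF-like signals are a sum of three oscillators whose
frequencies random-walk inside 3–7 Hz, with small phase noise,
mean-reverting amplitude envelopes and a non-sinusoidal waveshape (second
and third harmonics at 0.5 / 0.25 relative amplitude). The envelope drift
and harmonics are what make the surrogate fill the phase plane the way
fibrillation does — three pure tones trace a thin quasi-periodic curve
with none of the self-crossing density the image features respond to.

What the generator does *not* emulate: real QRS morphology variants
(bundle-branch blocks, paced beats), PVC prematurity and compensatory
pauses (PVCs are scheduled on the regular RR grid; the grammar operates on
beat order, not timing), baseline wander, motion artifact, or multi-lead
projection. Consequently, passing tests demonstrate that the features and
cascade behave as designed under their stated statistical assumptions —
not clinical performance on recorded data, which depends on noise and
morphology sources absent here.

## Numerical choices and problem sizes

FFTs use the sample count as transform length (no padding, no taper).
Histogram entropies return 0 for constant input; all-zero beats and
constant windows raise typed errors rather than propagating NaNs.
Degenerate protocol splits are re-drawn up to 100 times. The evaluation
suite uses 200 samples per class for stage separability, 10 generator
seeds for feature-direction checks, 20 beat pairs for PVC directions, and
a 16-block (128 s) recording for the end-to-end cascade; these sizes keep
the full build-and-verify cycle under a minute while leaving the
statistics comfortably clear of their acceptance margins.

## Known limitations

Episode boundaries are assumed to align with analysis windows in the
end-to-end evaluation (step = 8 s); overlapped windows straddling a rhythm
change have no single true label and are not scored. The R-peak detector
is tuned for upright lead-II-like QRS; inverted complexes rely on the
±75 ms refinement finding the dominant positive deflection. The AF stage
inherits the short-window instability of RR statistics at low heart
rates (7 intervals in 8 s at 60 bpm). F1's sign convention follows the
occupied-fraction definition (lag-5 minus lag-1) and is larger for VF
here; the trained classifiers are indifferent to the sign.
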