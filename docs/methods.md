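# Methods

This note documents the analysis procedures, the synthetic-data model that
validates them, the numerical choices, and the limitations a user should
know before trusting the outputs on real recordings.

## Electrophysiology

### Recording model

All patch-clamp analysis assumes stimulus-aligned sweeps at a fixed
sampling rate (20 kHz in the generators, arbitrary in the readers). The
current-clamp protocol is a ladder of 38 depolarizing steps, 3 pA apart
and 400 ms long, starting 12 pA below the holding current that keeps the
cell at −60 mV. The voltage-clamp protocol steps −90…80 mV in 10-mV
increments from a −60 mV hold. Units are fixed package-wide (mV, pA, pF,
ms, Hz); converters belong at the I/O boundary.

### Spike detection

Spike apexes are local maxima above a detection level (default −10 mV)
pruned to a minimum separation (default 3 ms), keeping the larger — then
earlier — of any conflicting pair. Both parameters are configurable; the
defaults are robust for the template morphology used in validation and
for typical cultured-neuron spikes. The detector is verified against a
brute-force enumeration oracle in the test suite.

### Evoked-spike counting

The total sums detected spikes over the first `n_steps_counted` sweeps
(30 for hippocampal, 32 for dopaminergic cultures; configurable). Cells
whose holding current exceeds 50 pA in magnitude are excluded with an
explicit reason rather than silently dropped, and exclusions are logged
per stage by the pipeline.

### Spike shape

Features are measured on the first spike of the lowest step that evokes
any spike:

* **Threshold.** The second derivative of a 5-sample moving-mean-smoothed
  trace (central differences) is scanned over the 10 ms preceding the
  apex; the threshold is the voltage at the first local maximum of
  curvature. Raw second differences at 20 kHz are noise-dominated, hence
  the light smoothing. Two numerical details matter: candidate maxima
  must reach 5% of the window's peak curvature (numerically flat segments
  of the rising phase otherwise produce spurious first maxima), and
  because smoothing turns a sharp kink into a short curvature plateau,
  the plateau's midpoint — not its left edge — marks the threshold. The
  voltage is read from the raw trace at that index; the smoothed value is
  biased upward across an asymmetric kink.
* **Amplitude** is apex voltage minus threshold; **width** is the time
  between the rising and falling crossings of threshold + amplitude/2,
  with sub-sample linear interpolation at both crossings.
* **fAHP** is threshold minus the voltage exactly 5 ms after the
  post-apex downward threshold crossing (interpolated). A trace that
  returns to threshold and stays there yields 0.

On noiseless template spikes all four features are exact to within one
sample interval (time) or one per-sample voltage increment at the local
slope (voltage); this is asserted across 50 randomized templates.

### Ionic currents

Per voltage step: the Na⁺ peak is the most negative current within 10 ms
of step onset (clipped at ≤ 0; inward-negative convention), the fast K⁺
is the maximum within 10 ms of onset, and the slow K⁺ is the mean over
the final 5 ms of the step — a tail mean rather than a single end sample,
for noise robustness. All are divided by the cell capacitance (pA/pF).
The 10-ms windows and 5-ms tail are configurable; they operationalize
"right after the step" and "at the end of the 400 ms phase" where no
exact figure is standard. Group comparisons restrict to −20…0 mV (Na⁺)
and 40…80 mV (K⁺), run a one-way ANOVA per retained test potential, and
add a pooled row using each cell's window mean. Note that a sustained
outward plateau also raises the early-window maximum: the fast-K measure
is a window maximum of the total current, not a component amplitude.

### EPSC detection

The trace is box-smoothed over 1 ms; the baseline is a piecewise median
over 1-s blocks, linearly interpolated between block centers (equivalent
to a rolling median at the drift time scales that matter, at a fraction
of the cost); the noise scale is 1.4826 × MAD of the baseline-subtracted
smoothed trace. Events are negative deflections exceeding 4.5 noise SDs
with at least 5 ms separation and a prominence requirement of the same
magnitude, which prevents noise ripples riding on an event's decay tail
from re-triggering. The threshold was chosen for a near-zero
false-positive rate on noise-only traces (≈ 0.04 Hz at 20 kHz) while
typical events (tens of pA against sub-pA filtered noise) remain an order
of magnitude above it. Amplitudes are |baseline − trough| on the smoothed
trace, which attenuates a ~1 ms-rise event by a few percent — visible in
the calibration numbers and well inside the 10% acceptance band. The
event rate divides the count by the recording duration and counts silent
cells as 0; the mean amplitude is defined only over detected events.

## Calcium imaging

### Classification

For each ROI the lag-6 difference Δf(n) = f(n) − f(n−6) is computed
(0.6 s at 10 Hz) and normalized; an ROI whose maximum normalized |Δf|
exceeds 0.05 is an active neuron. The normalization reference is
configurable (`delta_norm`):

* `"recording"` (default): the largest peak-to-trough amplitude among all
  ROIs of the recording;
* `"trace"`: the ROI's own peak-to-trough amplitude;
* `"max"`: the ROI's own maximum value.

The default is the recording-wide amplitude because the per-trace variant
is scale-free: a noise-only ROI then normalizes its own noise by its own
noise range and always crosses the 0.05 threshold, so every inactive ROI
would be labeled a neuron. Against a recording-wide reference, noise-only
ROIs score near zero, slow astrocytic waves stay below threshold because
their rise spans far more than six frames, and fast transients (rise ≤ 2
frames) score near their full amplitude.

Non-neuronal ROIs are split by the fluorescence ratio Δf/f₀ =
(max − min)/min, the minimum serving as the baseline: an ROI below 10% of
the largest ratio among non-neuronal ROIs is inactive, the rest are
active astrocytes. Using all non-neuronal ROIs as the reference pool
resolves the circularity that the "most active astrocyte" is needed
before astrocytes are identified. Constant traces yield ratio 0 (never a
division error); non-positive baselines raise an error advising offset
correction. The lag statistic is invariant to affine gain and offset; the
ratio is gain-invariant but offset-sensitive — both properties are
asserted in the tests exactly in that form.

### Events, synchrony, spectra

Neuronal transients are counted with peak detection at prominence ≥ 20%
of the trace amplitude and ≥ 5 frames separation (both configurable; no
standard figure exists). The astrocyte summary averages the fluorescence
ratios of the three most active astrocytes; with fewer than three, all
are averaged and the count is reported; with none, the value is missing
with a warning rather than an error.

Synchrony: traces are moving-average filtered (5 frames), then Pearson
correlations are computed for every unordered ROI pair over every
35-frame window (stride 1) and summed into both ROIs' scores.
Zero-variance windows contribute 0 and are logged. ROIs are ranked by
summed score and the top-10 mean is reported both raw and normalized by
(n−1) × n_windows; the normalized score lies in [−1, 1] and equals 1 for
identical traces. Window length 35 follows the ~3.5 s convention; filter
length and stride are package choices.

PSD: Welch's averaged periodogram (segments of 256 frames, 50% overlap,
constant detrend), integrated by the trapezoidal rule over the full
frequency axis and over frequencies strictly above 0.1 Hz; the ratio
(full/high) is ≥ 1 by construction, approaches 1 when no power lies below
the cutoff, and is reported as +inf with a flag when the high band is
empty. Neurons are sorted by event count before the top-k mean. `top_k`
defaults to 10 but is exposed (including `--top-k` on the CLI) because
top-5 summaries are equally common in practice. Note the ratio as defined
*decreases* for faster-oscillating cells — whether that direction matches
a given scientific expectation is for the user to decide; the package
computes the stated quantity exactly.

## Enrichment network

DEG filtering is strict (< 0.05, > 1.1) on FDR and |log2FC|.
Overrepresentation of each gene set is scored with a one-sided
hypergeometric test against a user-supplied universe — the universe is a
required input because no principled default (expressed vs annotated
genes) exists — followed by Benjamini–Hochberg adjustment across sets.
Gene identifiers are case-sensitive strings; no aliasing or external
annotation is attempted. Nodes are sets with adjusted FDR < 0.05,
carrying set size, DEG hit count and FDR; edges connect pairs with
overlap coefficient ≥ 0.3 (inclusive) and carry the OC and shared-gene
count. Because the hypergeometric statistic is discrete, its null
p-values are super-uniform (conservative); the test suite checks validity
(P(p ≤ α) ≤ α) rather than exact uniformity.

## Statistics

Two-sample comparisons use the two-tailed Student t (pooled variance),
the Welch-corrected t, or the Mann–Whitney U with midrank ties — exact
null distribution when the smaller sample has ≤ 8 observations and no
ties, tie-corrected normal approximation otherwise (the switch is
configurable). One-way ANOVA computes F = MS_between/MS_within with
explicit handling of zero within-group variance: equal means give F = 0,
p = 1; separated means give F = ∞, p = 0; "zero" is judged against a
relative tolerance so that float cancellation on identical groups cannot
produce spurious F values. Summaries are mean ± SE with sample (n−1) SD.
Report text rounds half away from zero; printed tables that truncate
instead (61.5 → 61) are reproduced by emitting both raw and rounded
values so the convention is visible rather than hidden.

## Synthetic-data model

The generators exist to make every analysis stage falsifiable: each emits
a ground-truth record sufficient to score the downstream operation
without re-simulation, and all randomness flows through one seeded
generator per call.

* **Spikes** are a parametric piecewise-linear template (gentle 9-ms ramp
  to threshold, linear rise and fall of one width each — so FWHM equals
  the width parameter exactly — a 5-ms linear sag of the fAHP depth, and
  a linear recovery), not a conductance model. A kinked linear fall is
  used rather than an exponential one because an exponential never
  re-crosses threshold, leaving the return time and fAHP anchor
  ill-defined; testability beats realism here. Spike counts per step
  follow 1 + round(gain × steps-past-rheobase); spikes are placed
  non-overlapping and evenly within the step, and over-full steps raise
  an error.
* **Voltage-clamp sweeps** sum an inward transient (unit-peak shape
  peaking exactly at the Na latency), a fast-decaying outward
  exponential, and a sustained plateau, each scaled by per-voltage
  density maps (piecewise-linear by default) times capacitance. Ground
  truth stores the noiseless per-step measurements.
* **EPSC traces** are homogeneous Poisson trains of negative-going
  biexponential events (1 ms rise, 5 ms decay, unit-normalized peak) with
  Gaussian amplitudes (30 ± 5 pA) in Gaussian noise (2 pA), 60 s at
  20 kHz, 2 Hz by default.
* **Calcium populations** default to 15 neurons, 5 astrocytes and 5
  inactive ROIs over 1800 frames at 10 Hz — a typical field of view.
  Neurons fire 0.2 Hz Poisson transients (2-frame rise, 8-frame decay,
  amplitude half the 100 a.u. baseline). Astrocytes follow a raised
  cosine with a 60-s period: at period T the lag-6 statistic is bounded
  by sin(π·0.6/T), i.e. 0.031 at 60 s, safely below the 0.05 neuronal
  threshold once noise is added, whereas a 30-s period (0.063) would
  violate the classifier's own rule. Synchrony is injected via a common
  Poisson stream adopted per event with probability
  `shared_drive_fraction`, independent events making up the remaining
  rate — total rate is invariant to the knob. Noise is 0.3 a.u.
* **Gene sets** are built from pair-exclusive shared blocks so every
  pairwise overlap coefficient is realized exactly (targets must be
  integral multiples of 1/set_size; infeasible matrices raise). The DEG
  table controls the passing fraction either uniformly or with per-set
  overrepresentation against a background rate.

What the generators deliberately omit: conductance-based spike dynamics,
series-resistance and liquid-junction artifacts, calcium-indicator
kinetics, photobleaching, motion, and neuropil contamination. Passing
tests therefore demonstrate that the implementations compute their
definitions correctly and recover known structure under idealized noise —
not that the defaults are optimal for any particular rig or indicator.
Detector thresholds are exposed in `AnalysisConfig` for that reason.

## Problem sizes

Validation uses the full recording geometries (38 × 500 ms sweeps at
20 kHz; 1800-frame fluorescence matrices; 60-s EPSC traces) with ensemble
sizes of 20 seeds for calibration checks, 50 randomized templates for
feature recovery, and 600 null simulations per statistical test; these
sizes give comfortable margins for every bound asserted (e.g. binomial SE
≈ 0.009 on a 0.05 rejection rate at n = 600 against an accepted band of
0.03–0.07).

## Known limitations

* The evoked-spike detector is threshold-plus-refractory; bursting cells
  with incomplete repolarization above −10 mV would need a dV/dt-based
  criterion (the level is configurable but the criterion form is fixed).
* The EPSC detector assumes stationary noise and a drifting but slow
  baseline; seal instabilities faster than ~1 s will be misread.
* ABF import is a stub pending the optional `pyabf` dependency; CSV
  bundles and HDF5 containers are the native formats.
* The enrichment stage deliberately performs no identifier mapping; gene
  sets and DEG tables must share a namespace.
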