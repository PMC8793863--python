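# Methods

This note documents the models, estimators and numerical choices behind
`excessnet`, in the spirit of a methods section: what is computed, under
which assumptions, with which defaults, and what the synthetic studies do
and do not demonstrate.

## Signal model and preprocessing

Input epochs are multichannel iEEG segments directly preceding seizure
onset (clinically: 110–200 s at 512 or 1024 Hz, ~50–60 channels, with a
small fraction of artifact channels excluded by visual review). Channels
flagged as artifacts are carried but skipped by every computation, so
channel indexing into annotations stays stable.

Preprocessing re-references each sample against the median over
artifact-free channels and band-pass filters 0.5–150 Hz with a 4th-order
Butterworth design. Re-referencing precedes filtering, matching the
recording chain (referential montage during acquisition, re-reference
offline, then filter). Filtering is applied forward-backward
(`sosfiltfilt`): zero phase, so transient event timing is not shifted,
at the cost of doubling the effective attenuation order. A single causal
pass is available (`zero_phase=False`).

## Windowed mutual information

Dependence between channel pairs is quantified per 8-s window, shifted in
1-s steps from t = 0; a trailing remainder shorter than 8 s is discarded
(an integer duration D gives D − 7 windows).

The MI estimator is a plug-in over an equiquantal partition: each
signal's samples are ranked and split into B = 16 bins of (nearly) equal
occupancy, and MI = Σ p_kl log(p_kl/(p_k p_l)) is normalized by log B.
Equiquantal marginals make the bound tight: any strictly monotone
deterministic relation scores exactly 1, independent channels score near
0 (plug-in bias ≈ (B−1)²/(2N log B) ≈ 0.01 for N = 4096, far below the
surrogate-corrected threshold). B = 16 balances resolution against bias
for the 4096–8192 samples of one window.

## Multivariate IAAFT surrogates

The null hypothesis is "all interrelation is linear". Each window is
contrasted with surrogates that conserve, per channel, the exact value
distribution (rank remapping onto the original sorted values) and the
amplitude spectrum, and across channels the Pearson correlation matrix.
The construction draws one uniform phase offset per Fourier frequency and
adds it to *all* channels (conserving cross-channel phase differences,
hence the linear cross-structure; DC and Nyquist stay real), then refines
iteratively: the spectrum step re-imposes the original amplitude spectra
*and* the original cross-channel phase differences rotated by a common
per-frequency angle fitted to the current phases (a unit-circle least
squares fit); the amplitude step rank-remaps. The joint spectrum step is
essential — refining channels independently lets the conserved
correlation matrix drift and visibly inflates the false-positive level of
the excess test.

Iteration stops when the relative change of the per-channel L2 spectral
discrepancy falls below `tol` (default 1e-8) or after `max_iter`
(default 100) iterations, always ending on an amplitude step so value
conservation is exact. On the band-limited AR signals used throughout,
diagnostics plateau after roughly ten iterations (relative spectral
error ~2e-3, max |Δr| of the correlation matrices ~4e-3); the
Monte-Carlo studies therefore cap refinement at `max_iter=10`, far
inside the 0.05 contract bounds, and the single-ensemble contract check
runs at the defaults.

## The excess matrix and its calibration

For each pair, the excess element is
`max(0, MI_data − max_k MI_surr_k)` if the data exceed all `n_surr = 19`
surrogates, else exactly 0 — a one-sided max-rank test at
p ≤ 1/(n_surr+1) = 0.05 that also yields a graded magnitude (needed for
node strength; a z-score variant was rejected for its unbounded range).
Surrogate seeds derive deterministically from the epoch seed and window
index, so identical seeds reproduce matrices byte for byte. 99 surrogates
give p ≤ 0.01 where a stricter per-pair level is wanted.

Measured calibration on purely linear Gaussian pairs (r = 0.7, 8 s at
512 Hz): the rejection rate is slightly above nominal, ≈ 0.06–0.08
instead of 0.05, independent of refinement depth and of the coupling
strength. This mild anticonservativeness is a known finite-window
property of constrained-realization Fourier surrogates: the ensemble
freezes the *realized* amplitude spectra and cross-phases of the window,
removing a sampling-variance component that the data retain, and the
periodic (circular) signal model does not hold exactly for a windowed
segment. Within the ensemble the test is exchangeable (a surrogate
treated as data rejects at ≈ 0.03–0.05). Consequences for the pipeline
are benign — false positives add a near-uniform floor that epoch
averaging keeps an order of magnitude below planted-core strengths — but
per-pair p-values should be read as approximate.

## Node strength and largest-gap core detection

The epoch-averaged matrix is collapsed to node strengths (row means
excluding the diagonal, in [0, 1]). Channels are sorted by descending
strength, ties broken lexicographically for determinism. Adjacent gaps
are scanned on the linear scale (all entries) and on the log scale
(entries above ε = 1e-6 only, so zero-strength channels can never enter
the core); each scale proposes the prefix above its largest gap (first
maximum on ties, so an all-equal profile yields the single top channel).
If the scales disagree the smaller prefix wins — conservative, favouring
precision over recall. No entry above ε means an empty core.

## Channel-set prediction and outcome statistics

Every artifact-free channel of an epoch is labelled TP/FP/FN/TN for a
predictive→target set pairing. Counts are micro-pooled over events (sum
counts, then take ratios once) — pooling scores instead would weight
events equally regardless of extent. Because targets are small minorities
of channels, TN dominates; reported quantifiers are the TN-independent
precision, recall and F1 with the 0/0 → 0 convention (rank statistics
over epochs need defined values; empty-overlap epochs legitimately score
0). Event channels annotated on artifact channels are dropped with a
warning.

Outcome contrasts use two-sided Mann-Whitney U tests between the
favorable and unfavorable groups only (no-surgery patients are summarized
but never tested). For combined sample sizes ≤ 20 the p-value is exact by
full enumeration of group assignments over midrank-based U (valid under
ties, which are pervasive in precision/recall data); larger samples use
the normal approximation with tie and continuity correction. Quartiles
use linear interpolation (type 7). Bonferroni correction for the
six-pairing family gives 0.01/6 → 0.0017 (significance) and
0.05/6 → 0.0083 (trends), reported rounded to four decimals alongside
full precision. Event-type proportions are compared with Pearson
Chi-squared tests (2×k table, k−1 degrees of freedom, no continuity
correction).

## Synthetic data

The generator emulates the structure the pipeline must resolve, not the
biophysics of seizures:

- **Background**: independent AR(2) noise (poles 0.8/0.6), band-limited
  0.5–150 Hz, unit variance — red, EEG-like spectra.
- **Linear distractors**: a group sharing a common Gaussian source mixed
  to pairwise r = 0.7 (the surrogate correction must suppress these).
- **Planted core**: for each core pair one channel receives a private
  band-limited driver u linearly and the other receives the standardized
  even function u² − E[u²]; by symmetry the pair's Pearson correlation is
  0 while mutual information is substantial. `coupling_strength` is the
  variance of each coupling component relative to the channel's
  background (default 1.0); with a core of size k each channel carries
  k−1 components, so the effective per-pair SNR is
  SNR/(1 + (k−2)·SNR). A threshold kernel could be substituted; the
  quadratic kernel is the canonical correlation-free dependence.
- **Events**: Poisson times per type (default rates proportioned like
  the clinical corpus, ~60 events/min in aggregate), durations uniform
  within the clinical bounds (spike 20–69 ms, sharp wave 70–200 ms, slow
  wave 0.3–1 s, fast-oscillation burst 0.1–0.5 s of 35–120 Hz), affected
  channels enriched toward the SOZ/RBT (enrichment 0.8 by default).
  Waveform shapes (biphasic transient, half-sine, gated sinusoid) are
  invented; only the duration/frequency constraints are meaningful.
- **Cohorts**: the aligned scenario places a favorable patient's core and
  SOZ inside the RBT and an unfavorable patient's core disjoint from it;
  no-surgery patients lack an RBT; the misaligned scenario randomizes the
  RBT for null testing. Defaults mirror the clinical recording conditions
  (180 s, 50 channels, 512 Hz); identical seeds give byte-identical
  cohorts.

What passing synthetic tests shows: the estimator chain detects
correlation-free dependence, suppresses linear coupling at a known error
level, and propagates planted structure to the clinical-style report.
What it does not show: performance on real iEEG with non-stationarity,
volume conduction, montage effects, or genuinely physiological event
morphology. Notably, *injected* event waveforms shared across channels
create excess interrelation of their own (transient common signals are
highly non-Gaussian); the outcome-contrast study therefore generates
annotations without injecting waveforms, isolating the planted-coupling
pathway. With injection enabled, detected cores gravitate toward
event-rich channels — a realistic interaction, but a different question.

## Study sizes

The Monte-Carlo studies are scaled for a single CPU: 32-s epochs
(25 windows) of 8–10 channels with a planted core of 3 and a linear pair;
50 epochs for core recovery; 500 independent pairs for type-I
calibration; 8 epochs per outcome group for the end-to-end contrast.
With these sizes the full suite runs in minutes while the epoch-average
retains enough windows for the largest-gap rule to separate core from
background reliably; clinical-scale epochs (110–200 s) only increase the
averaging depth.

## Known limitations

- Per-pair significance is approximate (see calibration above); the
  excess magnitude, not the p-value, carries the downstream analysis.
- The MI estimator is undirected and lag-free; time-lagged or
  frequency-resolved interrelation is out of scope.
- The largest-gap rule assumes a gap exists; near-degenerate strength
  profiles yield a minimal (top-1) core by convention.
- EDF files are read (via mne); epochs are written only in the delimited
  matrix format.
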