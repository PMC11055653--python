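# Methods

This note documents the models, estimators and numerical choices
behind `thetalock`, and what the synthetic validation does and does
not establish about real recordings.

## Data model and behavioral epochs

A session consists of one LFP trace per brain area (S1BF, V2L, PER,
dHC), per-unit spike-time lists with spike-sorting QC metrics, and a
trial table for the self-paced two-alternative object-discrimination
task (modalities T/V/M). All times are seconds (float64), voltages
microvolts; analysis windows are half-open `[t0, t1)`.

Five 500 ms epochs are anchored to two task events per trial — sample
start (head enters the sampling area) and reward poke:

| epoch | window |
|---|---|
| object approach | `[t_sample_start − 0.5, t_sample_start)` |
| discrimination | `[t_sample_start, t_sample_start + 0.5)` |
| reward-site approach | `[t_reward_poke − 1.0, t_reward_poke − 0.5)` |
| outcome | `[t_reward_poke, t_reward_poke + 0.5)` |
| baseline | `[t_reward_poke + 6.0, t_reward_poke + 6.5)` (mid-ITI rest) |

Trials in which the animal withdrew from the sampling area within
200 ms are dropped entirely — the conservative scoping, since a
too-short sample invalidates the discrimination epoch and leaves the
trial's behavioral interpretation unclear.

Unit inclusion uses strict thresholds: SNR > 2.5, refractory
violations < 0.5 %, isolation distance > 5, session rate > 0.1 Hz.
Waveform classes: putative excitatory (trough-to-peak > 400 µs) vs
fast-spiking (< 400 µs), requiring ≥ 50 µV waveform amplitude; a
latency of exactly 400 µs is left unclassified because the split
defines only the two open intervals.

## Phase extraction

LFPs are decimated to 1 kHz with cascaded FIR anti-alias stages (no
stage exceeding a factor of 10), with any polarity inversion applied at
this step. The theta band is isolated with a 6–12 Hz 4th-order
Butterworth applied forward–backward (`sosfiltfilt`). Zero-phase
filtering is a deliberate choice: spike–phase pairing cannot tolerate
group delay, and the effective magnitude response (the squared
Butterworth response) still exceeds 30 dB stopband attenuation at 2 and
50 Hz. Phase and envelope come from the Hilbert analytic signal; phase
0 is the oscillation peak of a cosine, ±π the trough.

Spike phases interpolate the *complex* analytic signal linearly
between the two bracketing samples and then take angle/modulus —
interpolating the wrapped angle would be discontinuous at ±π. The
first and last 500 ms of a series are flagged invalid (filter and
Hilbert end effects), as are zero-amplitude samples where phase is
undefined; spikes landing on invalid samples are dropped and counted.

## Circular statistics

The Rayleigh test uses Z = nR̄² with the standard series approximation
of the p-value (clipped to [0, 1]); `pingouin`'s closed-form variant
serves as an independent cross-check in the tests.

The pairwise phase consistency is computed through the identity
`PPC = (|Σe^{iθ}|² − n) / (n(n−1))`, which the tests verify against the
explicit O(n²) pairwise-cosine sum to 1e−12. PPC is unbiased under
uniformity (unlike R̄², whose expectation is 1/n), which is what makes
the 200 ms sliding windows workable at low spike counts. When trial
labels are available the pipeline defaults to the between-trials
variant — the average cosine over pairs from *different* trials —
because within-trial bursts contribute many near-identical phases that
inflate the pooled estimator; the pooled form is used where no trial
structure exists (and in permutation nulls, whose draws have no trial
identity).

## Sliding-window inference

Per cell, spike phases are collected across trials in 200 ms windows
stepped by 10 ms over −0.5…+1.5 s around sample start. The null for a
bin with N spikes is the PPC of N phases drawn *without replacement*
from the reservoir of all valid LFP phase samples (at LFP resolution)
in the analysis window across trials; 500 draws, p = exceedance
rank / 500, with ties counted against significance and the p-value
floored at 1/500. Because the null inherits the empirical phase
distribution, the test stays calibrated when the theta cycle is
asymmetric and the phase histogram nonuniform — verified by the
sawtooth false-positive control.

Multiple comparisons over the ~181 bins use a run-length criterion:
only maximal runs of ≥ 10 consecutive bins with p < 0.01 count
(10 bins × 10 ms = 100 ms). Cluster duration is run length × step —
the window overhang is not added, keeping the bins↔milliseconds
equivalence exact — and a cell's locking duration sums all its
clusters (a longest-cluster mode is exposed as an option). Cells with
fewer than 50 spikes in any epoch across the session are excluded
before this analysis.

## Per-epoch entrainment and reference LFPs

A cell is entrained in an epoch when the Rayleigh test on its pooled
spike phases rejects at α = 0.05. For the discrimination epoch a cell
counts as entrained if it is entrained in at least one of the three
modality conditions. Reference phase series must come from a different
tetrode than the cell; when several channels are eligible the one with
the highest theta/broadband Welch power ratio is chosen — a
deterministic surrogate for manual channel curation. Population
fractions carry 95 % percentile bootstrap CIs (1,000 resamples of the
cell population); two fractions differ when their CIs do not overlap.
Cells are also labelled same-area-only / dHC-only / both, with a
Wilcoxon signed-rank test on the per-cell PPC pairs.

## Theta-power deciles

Non-overlapping 1 s segments per trial cover −2…+10 s around sample
start (segments colliding with the previous trial are dropped).
Segment theta power is the mean squared Hilbert envelope of the
theta-filtered trace — the natural envelope-based reading of
"theta-band filtered LFP power". Segments are ranked into deciles with
ties broken by start time; a cell is classed increase/decrease when
the 95 % bootstrap CIs (1,000 resamples) of its first- and last-decile
mean firing rates do not overlap.

## Modality selectivity

Spike phases in the discrimination windows are grouped by trial
modality; each modality's PPC is tested against 500 permutation draws
of N_spikes phases without repetition from the pooled sampling-epoch
phases, significant at p < 0.05 (the threshold is configurable).
Classes: T-only (sig T, not V), V-only (sig V, not T), T&V (both),
M-only (sig M alone); cells significant in no condition are "none".
Class fractions get 99 % bootstrap CIs, significant when the lower
bound exceeds zero. Two confound controls: (i) spike-count-matched PPC
— every modality subsampled to the smallest modality's spike count,
averaged over 100 repetitions (the repetition count is a package
choice; the average stabilizes well before 100) — removing rate
effects; (ii) per-modality spike-triggered theta envelope compared by
Kruskal–Wallis, plus the across-cell Pearson correlation between mean
amplitude and PPC.

One subtlety the validation surfaced: phase-locked spikes sample the
envelope non-uniformly, so the amplitude negative control requires
locking strength matched across conditions, not merely identical LFP
statistics.

## Spectra and coherence

Time–frequency power uses 7-cycle Morlet wavelets (via MNE, with dB
baseline correction against the baseline-epoch samples). IRASA
separates the aperiodic 1/f component by resampling the signal by
factors h and 1/h (h ∈ {1.10, 1.15, …, 1.90}, rational approximations
for polyphase resampling), taking the geometric mean of each pair's
Welch PSD and the median across factors; the oscillatory residual is
PSD − aperiodic. Epoch power contrasts use a per-frequency Friedman
test across the five epochs (p < 0.01) gating one-sided Wilcoxon
signed-rank tests of each epoch against baseline (p < 0.01, Bonferroni
over epochs).

The dWPLI forms per-epoch time-averaged Morlet cross-spectra (the same
estimator family as the TFR) and combines their imaginary parts as

    dWPLI = [(Σᵢ Im Xᵢ)² − Σᵢ (Im Xᵢ)²] / [(Σᵢ |Im Xᵢ|)² − Σᵢ (Im Xᵢ)²].

Zero-lag (volume-conducted) coupling has a real cross-spectrum and
contributes nothing; when all imaginary parts vanish the denominator is
≤ 0 and the value is reported as 0 with a zero-lag flag. The
permutation null re-pairs x-epochs with permuted y-epochs — preserving
each signal's spectrum while destroying their phase relation — which is
the scheme chosen among the possible readings of "shuffling the LFP
phases" (a sample-wise scramble would also whiten each signal's
spectrum); 500 permutations, p floored at 1/500. Note the 7-cycle
wavelet at 8 Hz spans ~1.4 s, so coherence epochs must be ≥ 2 s; the
pipeline uses 2 s trial segments around sample start.

## Synthetic sessions and what they show

The generator emulates: multi-area LFP as epoch-gated theta (default
8 Hz) with per-epoch amplitudes (crossfaded over 100 ms at window
edges via boxcar smoothing) plus 1/f^α background noise (spectral
shaping, α = 1 by default); an optional monotone cubic-easing phase
warp producing sawtooth-shaped cycles with one cycle per period; and a
configurable constant phase lag per area. Spike trains are
inhomogeneous Poisson with intensity
`r · exp(κ(t)·cos(φ(t) − µ)) / I₀(κ(t))`, where κ(t) is selected by the
current epoch and trial modality; the I₀ normalization keeps the
time-averaged rate at r, and thinning against the global intensity
bound `r·exp(κmax)/I₀(κmax)` (times any modality rate factor) makes the
simulation exact with no discretization bias. Spike generation reads
the *noiseless* theta phase evaluated in continuous time; the analysis
must re-estimate phase from the noisy trace, which is what makes
recovery tests meaningful.

Default study conditions: 20 trials per modality (60 trials), 12 s
inter-trial interval, self-paced run times of 2.5–4 s, per-modality
correct-response probabilities 0.72/0.72/0.84, theta at 8 Hz over
15 µV 1/f noise, base rates 5–10 Hz. A fixed seed yields byte-identical
bundles; all pipeline stages draw named sub-seeds from one master seed.

What the synthetic data does **not** emulate: spike waveforms (QC
metrics are carried, not simulated), non-stationary theta frequency,
cross-frequency coupling, behavior-correlated movement artifacts,
volume conduction mixtures beyond a shared/lagged theta component, and
refractory structure in spike trains. Passing the validation therefore
establishes the *statistical correctness* of the estimators and the
calibration of the permutation/bootstrap inference under the stated
model — not that real recordings satisfy that model.

## Validation problem sizes

The canned experiments (`thetalock.validation`, rerun by
`scripts/acceptance.py`) use: 100 random samples (n ≤ 200) for the
PPC oracle; 5,000 × n=20 uniform samples for unbiasedness; 10,000 von
Mises draws for the Bessel-ratio check; 2,000 × n=100 samples for
Rayleigh type-I; 200 κ=0 units per theta shape for the sliding-window
false-positive control; 50 κ=3 units for transient localization; 100
epochs for the dWPLI lag constructions and 200 runs for its type-I
rate; 160 units (40 per truth class, κ=2) for modality recovery and 40
units for the spike-matching control; 100 + 100 units for the decile
classification; and 500 trials per modality for the behavioral
simulation. These sizes give binomial standard errors comfortably
inside the asserted bounds while keeping the full suite desk-scale.

## Known limitations

- The Rayleigh p-value is a series approximation; for n < 10 its tail
  behavior is approximate (the permutation tests do not rely on it).
- IRASA's aperiodic estimate inherits Welch estimation noise; the
  residual is only as smooth as the underlying PSD estimate.
- The epoch re-pairing dWPLI null requires epochs to be exchangeable;
  strong nonstationarity across epochs would violate it.
- `segment_epochs` assumes trials are far enough apart that baseline
  windows do not collide with the next trial; the generator enforces
  ITI ≥ 6.5 s for the same reason.
- The reference-channel auto-selection is a deterministic surrogate
  for manual curation and may differ from an expert's choice on real
  data with artifacts.
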