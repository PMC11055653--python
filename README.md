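# thetalock

Spike–LFP theta phase-entrainment analysis for multi-area rodent
electrophysiology, with a ground-truth session simulator.

During sensory discrimination, hippocampal theta oscillations (6–12 Hz)
entrain spiking not only in the hippocampus but also in sensory
neocortex, transiently and selectively for the stimulus modality being
processed. Quantifying this requires statistics that behave at low
spike counts and under asymmetric ("sawtooth") theta cycles. This
package implements that analysis chain for session data from a
self-paced tactile/visual/multimodal object-discrimination task:

- **Theta phase extraction** — decimation to 1 kHz, 6–12 Hz 4th-order
  zero-phase Butterworth, Hilbert analytic signal; spike phases by
  complex interpolation onto spike times.
- **Circular statistics** — Rayleigh test of uniformity and the
  pairwise phase consistency

  PPC = 2/(N(N−1)) · Σ_{j<k} cos(θ_j − θ_k),

  an unbiased estimator of the squared population resultant
  (for a von Mises phase distribution with concentration κ its
  population value is (I₁(κ)/I₀(κ))²), plus a between-trials variant
  that removes within-burst bias.
- **Sliding-window inference** — PPC in 200 ms windows stepped by
  10 ms over −0.5…+1.5 s around sample onset; each bin tested against
  500 permutations drawing N_spikes phases from the session's LFP phase
  reservoir (valid under nonuniform phase histograms); significance
  requires ≥10 consecutive bins at p < 0.01 (= 100 ms), and locking
  duration sums the significant spans.
- **Per-epoch entrainment** — Rayleigh flags per behavioral epoch
  (baseline, object approach, discrimination, reward-site approach,
  outcome; 500 ms windows each) against same-area and hippocampal
  reference LFPs, with bootstrap CIs on population fractions.
- **Modality selectivity** — per-modality PPC with a permutation null,
  classification into T-only / V-only / T&V / M-only, spike-count
  matching and spike-triggered theta-amplitude confound controls.
- **Spectral tools** — 7-cycle Morlet TFR with dB baseline correction,
  IRASA 1/f separation, Friedman-gated epoch power statistics, and the
  debiased weighted phase lag index (dWPLI) with an epoch re-pairing
  permutation test.
- **Synthetic sessions** (`thetalock.synthetic`) — epoch-gated theta +
  1/f LFP (optionally sawtooth-warped), von Mises phase-locked
  inhomogeneous Poisson spike trains simulated exactly by thinning,
  and the full self-paced trial structure, all with a ground-truth
  sidecar and byte-identical reproducibility under a fixed seed.

## Worked example

Simulate a session with hippocampal cells locked in every epoch and
sensory-cortex cells locked only while sampling their preferred
modality, then run the full analysis:

```bash
thetalock simulate --preset selective --seed 1 --out session/
thetalock analyze --session session/ --out results/ --seed 2
thetalock report --results results/
```

The report prints (seed-exact output from the commands above):

```
locking duration: 741 +/- 625 ms (n=12)
reference                epoch  fraction   ci_low  ci_high  n
      dHC             baseline  0.000000 0.000000 0.000000  9
      dHC       discrimination  1.000000 1.000000 1.000000  9
      ...
same_area       discrimination  1.000000 1.000000 1.000000 12
same_area              outcome  0.333333 0.083333 0.583333 12
```

Reading this: all 12 included units are phase entrained by their
same-area LFP during the 500 ms discrimination epoch (fraction 1.0,
bootstrap 95% CI [1, 1]), while only a chance-level minority is flagged
in other epochs; locking durations average ~0.74 s because the preset's
hippocampal cells are locked throughout the trial while the sensory
cells lock transiently. `results/` also contains tidy CSV tables
(per-bin sliding PPC, clusters, modality classes, power deciles, dWPLI)
and a `summary.json` with the full parameter provenance.

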