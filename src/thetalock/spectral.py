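"""Spectral power and LFP-LFP coherence.

Time-frequency power uses a 7-cycle Morlet wavelet transform; power
spectra are separated into an aperiodic 1/f component and oscillatory
residual with the IRASA resampling method; epoch power contrasts use a
Friedman gate with post hoc Wilcoxon tests; between-area coupling uses
the debiased weighted phase lag index (dWPLI) with an epoch re-pairing
permutation null.

The dWPLI weights cross-spectral terms by the magnitude of their
imaginary part, so purely zero-lag (volume-conducted) coupling, whose
cross-spectrum is real, contributes nothing; the debiasing removes the
positive finite-sample bias of the squared estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .core_io import LfpTrace

__all__ = [
    "Tfr",
    "CoherenceResult",
    "morlet_tfr",
    "morlet_coefficients",
    "irasa_corrected_psd",
    "epoch_power_test",
    "theta_peak_frequency",
    "dwpli",
    "debiased_wpli",
]

DEFAULT_IRASA_FACTORS = tuple(np.round(np.arange(1.1, 1.95, 0.05), 2))
N_CYCLES = 7.0


@dataclass(frozen=True)
class Tfr:
    """Morlet time-frequency power, optionally baseline-corrected (dB)."""

    freqs: np.ndarray  # Hz
    times: np.ndarray  # s
    power: np.ndarray  # (n_freqs, n_times), uV^2
    baseline_db: np.ndarray | None = None


def morlet_coefficients(
    samples: np.ndarray, fs: float, freqs: Sequence[float], n_cycles: float = N_CYCLES
) -> np.ndarray:
    """Complex Morlet wavelet coefficients, shape (n_freqs, n_times)."""
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2.0) or np.any(freqs <= 0):
        raise ValueError(f"freqs must lie in (0, {fs / 2}) Hz")
    data = np.asarray(samples, dtype=float)[np.newaxis, np.newaxis, :]
    out = tfr_array_morlet(
        data, sfreq=fs, freqs=freqs, n_cycles=n_cycles, output="complex", verbose=False
    )
    return out[0, 0]


def morlet_tfr(
    trace: LfpTrace,
    freqs: Sequence[float],
    n_cycles: float = N_CYCLES,
    baseline_windows: Sequence[tuple[float, float]] | None = None,
) -> Tfr:
    """7-cycle Morlet time-frequency power of one trace.

    When ``baseline_windows`` (list of [t0, t1) in seconds) is given,
    ``baseline_db = 10 log10(P / mean P over the baseline samples)``
    per frequency is attached.
    """
    coeffs = morlet_coefficients(trace.samples, trace.fs, freqs, n_cycles)
    power = np.abs(coeffs) ** 2
    times = np.arange(trace.samples.size) / trace.fs
    baseline_db = None
    if baseline_windows is not None:
        mask = np.zeros(times.size, dtype=bool)
        for t0, t1 in baseline_windows:
            mask |= (times >= t0) & (times < t1)
        if not mask.any():
            raise ValueError("baseline windows cover no samples")
        ref = power[:, mask].mean(axis=1, keepdims=True)
        baseline_db = 10.0 * np.log10(power / ref)
    return Tfr(
        freqs=np.asarray(freqs, float), times=times, power=power, baseline_db=baseline_db
    )


# ---------------------------------------------------------------------------
# IRASA 1/f separation
# ---------------------------------------------------------------------------


def irasa_corrected_psd(
    trace: LfpTrace,
    factors: Sequence[float] = DEFAULT_IRASA_FACTORS,
    fmax: float = 100.0,
    nperseg_s: float = 2.0,
) -> dict[str, np.ndarray]:
    """Separate a PSD into aperiodic (1/f) and oscillatory parts.

    For each resampling factor h the signal is resampled by h and by
    1/h; narrowband oscillatory peaks land at shifted frequencies in
    the two resampled spectra while the scale-free 1/f background is
    (to first order) invariant, so the geometric mean of each pair and
    the median across factors estimate the aperiodic component.

    Returns ``{"freqs", "psd", "aperiodic", "oscillatory"}``; the
    oscillatory residual is ``psd - aperiodic``.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 1.0):
        raise ValueError("IRASA factors must be > 1")
    x = trace.samples.astype(float)
    fs = trace.fs
    nperseg = int(round(nperseg_s * fs))
    if x.size < nperseg:
        raise ValueError("trace shorter than one PSD segment (>= 2 s required)")
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg)
    keep = freqs <= fmax
    freqs, psd = freqs[keep], psd[keep]
    resampled_psds = []
    for h in factors:
        frac = Fraction(h).limit_denominator(50)
        up, down = frac.numerator, frac.denominator
        pair = []
        for u, d in ((up, down), (down, up)):
            y = signal.resample_poly(x, u, d)
            _, p = signal.welch(y, fs=fs, nperseg=nperseg)
            pair.append(p[keep])
        resampled_psds.append(np.sqrt(pair[0] * pair[1]))
    aperiodic = np.median(resampled_psds, axis=0)
    return {
        "freqs": freqs,
        "psd": psd,
        "aperiodic": aperiodic,
        "oscillatory": psd - aperiodic,
    }


# ---------------------------------------------------------------------------
# per-epoch power statistics
# ---------------------------------------------------------------------------


def epoch_power_test(
    psd: np.ndarray,
    epoch_labels: Sequence[str],
    baseline_label: str = "baseline",
    alpha: float = 0.01,
) -> dict[str, np.ndarray]:
    """Per-frequency epoch-vs-baseline power statistics across sessions.

    ``psd`` has shape (n_sessions, n_epochs, n_freqs).  Per frequency a
    Friedman test across epochs (repeated measures over sessions) at
    ``alpha`` gates one-sided Wilcoxon signed-rank tests of each
    non-baseline epoch against baseline, Bonferroni-corrected over the
    tested epochs.  Returns the Friedman p per frequency and a boolean
    significance matrix (n_epochs-1, n_freqs) plus the raw Wilcoxon p.
    """
    psd = np.asarray(psd, dtype=float)
    if psd.ndim != 3:
        raise ValueError("psd must be (n_sessions, n_epochs, n_freqs)")
    n_sessions, n_epochs, n_freqs = psd.shape
    if n_epochs < 3:
        raise ValueError("need >= 3 epochs for the Friedman test")
    if n_sessions < 6:
        raise ValueError("need >= 6 sessions for repeated-measures testing")
    labels = list(epoch_labels)
    if len(labels) != n_epochs or baseline_label not in labels:
        raise ValueError("epoch_labels must match psd and contain the baseline")
    b = labels.index(baseline_label)
    others = [i for i in range(n_epochs) if i != b]
    friedman_p = np.ones(n_freqs)
    wilcoxon_p = np.ones((len(others), n_freqs))
    for f in range(n_freqs):
        friedman_p[f] = stats.friedmanchisquare(
            *[psd[:, e, f] for e in range(n_epochs)]
        ).pvalue
        if friedman_p[f] < alpha:
            for k, e in enumerate(others):
                diff = psd[:, e, f] - psd[:, b, f]
                if np.allclose(diff, 0):
                    wilcoxon_p[k, f] = 1.0
                else:
                    wilcoxon_p[k, f] = stats.wilcoxon(
                        diff, alternative="greater"
                    ).pvalue
    significant = (wilcoxon_p < alpha / len(others)) & (friedman_p < alpha)
    return {
        "friedman_p": friedman_p,
        "wilcoxon_p": wilcoxon_p,
        "significant": significant,
        "epochs_tested": np.array([labels[i] for i in others]),
    }


def theta_peak_frequency(
    power: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] = (6.0, 12.0),
    n_boot: int = 1000,
    ci: float = 0.99,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Trial-averaged in-band peak frequency over time with bootstrap CI.

    ``power`` has shape (n_trials, n_freqs, n_times).  Per time bin the
    argmax frequency within the band is taken per trial and averaged;
    the CI comes from resampling trials with replacement.
    """
    rng = rng or np.random.default_rng()
    power = np.asarray(power, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"no frequency rows inside band {band}")
    band_freqs = freqs[in_band]
    peak_per_trial = band_freqs[np.argmax(power[:, in_band, :], axis=1)]  # (trials, times)
    mean_peak = peak_per_trial.mean(axis=0)
    n_trials = power.shape[0]
    draws = rng.integers(0, n_trials, size=(n_boot, n_trials))
    boot_means = peak_per_trial[draws].mean(axis=1)  # (n_boot, times)
    lo, hi = np.percentile(
        boot_means, [50 * (1 - ci), 100 - 50 * (1 - ci)], axis=0
    )
    return {"peak": mean_peak, "ci_low": lo, "ci_high": hi}


# ---------------------------------------------------------------------------
# debiased WPLI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoherenceResult:
    freqs: np.ndarray
    dwpli: np.ndarray  # per frequency
    p: np.ndarray  # permutation p per frequency
    null_mean: np.ndarray
    null_sd: np.ndarray
    zero_lag_flag: np.ndarray  # True where the denominator vanished


def debiased_wpli(imag_cross: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Debiased WPLI from per-epoch imaginary cross-spectra.

    ``imag_cross`` has shape (..., n_epochs); the estimator is

        dWPLI = [ (sum Im X)^2 - sum (Im X)^2 ]
                / [ (sum |Im X|)^2 - sum (Im X)^2 ]

    Returns (dwpli, degenerate_mask); where the denominator is <= 0
    (all imaginary parts effectively zero) the value is reported as 0
    and flagged.
    """
    im = np.asarray(imag_cross, dtype=float)
    s = im.sum(axis=-1)
    s_abs = np.abs(im).sum(axis=-1)
    s_sq = (im**2).sum(axis=-1)
    num = s**2 - s_sq
    den = s_abs**2 - s_sq
    degenerate = den <= 0
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~degenerate)
    return out, degenerate


def dwpli(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    fs: float,
    freqs: Sequence[float],
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
    n_cycles: float = N_CYCLES,
) -> CoherenceResult:
    """Debiased WPLI between two channels across epochs, with permutation test.

    ``x_epochs``/``y_epochs`` are (n_epochs, n_times) arrays of
    simultaneously recorded segments.  Per epoch and frequency the
    time-averaged Morlet cross-spectrum is formed; its imaginary parts
    across epochs feed the debiased WPLI.  The null re-pairs x-epochs
    with permuted y-epochs (preserving each signal's spectrum while
    destroying their phase relation); ``p`` is the exceedance rank over
    ``n_perm`` permutations, floored at 1/n_perm.
    """
    from mne.time_frequency import tfr_array_morlet

    rng = rng or np.random.default_rng()
    x = np.asarray(x_epochs, dtype=float)
    y = np.asarray(y_epochs, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("x_epochs and y_epochs must be equal (n_epochs, n_times)")
    n_epochs = x.shape[0]
    if n_epochs < 10:
        raise ValueError("need >= 10 epochs for dWPLI")
    freqs = np.asarray(freqs, dtype=float)
    data = np.stack([x, y], axis=1)  # (n_epochs, 2, n_times)
    coeffs = tfr_array_morlet(
        data, sfreq=fs, freqs=freqs, n_cycles=n_cycles, output="complex", verbose=False
    )  # (n_epochs, 2, n_freqs, n_times)
    cx, cy = coeffs[:, 0], coeffs[:, 1]
    # all-pairs cross-spectra C[f, i, j] = <x_i conj(y_j)>_t
    n_times = cx.shape[-1]
    cross_all = np.einsum("ift,jft->fij", cx, np.conj(cy)) / n_times
    im_all = cross_all.imag  # (n_freqs, n_epochs, n_epochs)
    diag = np.einsum("fii->fi", im_all)
    emp, degenerate = debiased_wpli(diag)
    null = np.empty((n_perm, freqs.size))
    for k in range(n_perm):
        perm = rng.permutation(n_epochs)
        null[k], _ = debiased_wpli(im_all[:, np.arange(n_epochs), perm])
    exceed = (null >= emp[np.newaxis, :]).sum(axis=0)
    p = np.maximum(exceed, 1) / n_perm
    return CoherenceResult(
        freqs=freqs,
        dwpli=emp,
        p=p,
        null_mean=null.mean(axis=0),
        null_sd=null.std(axis=0),
        zero_lag_flag=degenerate,
    )
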