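"""Per-epoch phase entrainment and theta-power modulation of firing.

A unit is "entrained" in a behavioral epoch when the Rayleigh test
rejects uniformity of its spike-triggered phase distribution
(alpha = 0.05), computed against both the same-area LFP and the dorsal
hippocampal (dHC) reference; the reference LFP must come from a
different tetrode than the one the unit was recorded on.  Population
fractions carry bootstrap confidence intervals (resampling cells with
replacement), and fractions are called different when the intervals do
not overlap.

The theta-power decile analysis asks whether a cell's firing rate
covaries with theta amplitude independent of phase: the session is cut
into 1 s segments around each trial, segments are ranked into deciles
of theta power (mean squared Hilbert envelope), and the first- and
last-decile firing rates are compared by bootstrap CI overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circstats import PhaseSample, ppc_between_trials, ppc_pooled, rayleigh_test
from .core_io import EPOCHS, EpochWindow, LfpTrace, SpikeTrain
from .phase import PhaseSeries, spike_phases

logger = logging.getLogger("thetalock")

ALPHA_ENTRAINMENT = 0.05

__all__ = [
    "EpochStats",
    "EntrainmentFlags",
    "DecileModulation",
    "select_reference_channel",
    "entrainment_flags",
    "fraction_entrained_ci",
    "compare_fractions",
    "reference_preference",
    "rate_by_power_deciles",
]


@dataclass(frozen=True)
class EpochStats:
    n_spikes: int
    rayleigh_p: float  # 1.0 when undefined (too few spikes)
    ppc: float  # nan when undefined
    entrained: bool


@dataclass(frozen=True)
class EntrainmentFlags:
    """Per-unit entrainment per (epoch, reference)."""

    unit_id: str
    stats: dict[str, dict[str, EpochStats]]  # reference -> epoch -> stats

    def entrained(self, reference: str, epoch: str) -> bool:
        return self.stats[reference][epoch].entrained


def select_reference_channel(
    traces: Iterable[LfpTrace],
    exclude_tetrode: str | None = None,
    theta_band: tuple[float, float] = (6.0, 12.0),
    broad_band: tuple[float, float] = (1.0, 100.0),
) -> LfpTrace:
    """Pick the reference LFP channel with the strongest theta rhythm.

    Deterministic surrogate for manual channel curation: among channels
    not on ``exclude_tetrode``, choose the one with the highest ratio
    of theta-band to broadband Welch power (ties by channel id).
    """
    from scipy.signal import welch

    best: tuple[float, str, LfpTrace] | None = None
    for trace in traces:
        if exclude_tetrode is not None and trace.tetrode_id == exclude_tetrode:
            continue
        nperseg = min(int(4 * trace.fs), trace.samples.size)
        f, p = welch(trace.samples, fs=trace.fs, nperseg=nperseg)
        theta = p[(f >= theta_band[0]) & (f <= theta_band[1])].sum()
        broad = p[(f >= broad_band[0]) & (f <= broad_band[1])].sum()
        score = theta / broad if broad > 0 else 0.0
        key = (score, trace.channel_id)
        if best is None or key > (best[0], best[1]):
            best = (score, trace.channel_id, trace)
    if best is None:
        raise ValueError("no eligible reference channel (different tetrode required)")
    return best[2]


def _epoch_phase_sample(
    series: PhaseSeries,
    unit: SpikeTrain,
    windows: Sequence[EpochWindow],
) -> PhaseSample:
    sp = spike_phases(series, unit)
    phases, trial_ids = [], []
    for w in windows:
        m = (sp.times >= w.t0) & (sp.times < w.t1)
        phases.append(sp.phase[m])
        trial_ids.append(np.full(int(m.sum()), w.trial_id))
    if not phases:
        return PhaseSample(np.empty(0), np.empty(0, dtype=int))
    return PhaseSample(np.concatenate(phases), np.concatenate(trial_ids))


def _ppc_of(sample: PhaseSample) -> float:
    """Between-trials PPC when >= 2 trials have spikes, else pooled."""
    if sample.n < 2:
        return float("nan")
    if sample.trial_ids is not None and np.unique(sample.trial_ids).size >= 2:
        return ppc_between_trials(sample)
    return ppc_pooled(sample)


def entrainment_flags(
    unit: SpikeTrain,
    references: Mapping[str, PhaseSeries],
    windows: Sequence[EpochWindow],
    trials: pd.DataFrame | None = None,
    alpha: float = ALPHA_ENTRAINMENT,
) -> EntrainmentFlags:
    """Rayleigh entrainment flags and PPC per (epoch, reference).

    Spike phases are pooled over every window of an epoch across the
    session.  For the discrimination epoch the unit counts as entrained
    if it is entrained in at least one of the three stimulus-modality
    conditions (requires ``trials`` to group windows by modality); the
    reported p is the smallest per-modality p in that case.

    Raises if any reference series shares the unit's tetrode.
    """
    for name, series in references.items():
        if series.tetrode_id is not None and series.tetrode_id == unit.tetrode_id:
            raise ValueError(
                f"reference {name!r} is on the unit's own tetrode {unit.tetrode_id}"
            )
    modality_by_trial = (
        dict(zip(trials["trial_id"], trials["modality"])) if trials is not None else None
    )
    out: dict[str, dict[str, EpochStats]] = {}
    for name, series in references.items():
        per_epoch: dict[str, EpochStats] = {}
        for epoch in EPOCHS:
            epoch_windows = [w for w in windows if w.epoch == epoch]
            sample = _epoch_phase_sample(series, unit, epoch_windows)
            if sample.n == 0:
                per_epoch[epoch] = EpochStats(0, 1.0, float("nan"), False)
                continue
            ray = rayleigh_test(sample)
            entrained = ray.p < alpha
            p = ray.p
            if epoch == "discrimination" and modality_by_trial is not None:
                p_mods = []
                for modality in ("T", "V", "M"):
                    wins = [
                        w
                        for w in epoch_windows
                        if modality_by_trial.get(w.trial_id) == modality
                    ]
                    sub = _epoch_phase_sample(series, unit, wins)
                    if sub.n >= 2:
                        p_mods.append(rayleigh_test(sub).p)
                if p_mods:
                    p = min(p_mods)
                    entrained = p < alpha
            per_epoch[epoch] = EpochStats(
                n_spikes=sample.n,
                rayleigh_p=p,
                ppc=_ppc_of(sample),
                entrained=bool(entrained),
            )
        out[name] = per_epoch
    return EntrainmentFlags(unit_id=unit.unit_id, stats=out)


def fraction_entrained_ci(
    entrained: Sequence[bool],
    n_boot: int = 1000,
    ci: float = 0.95,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Fraction of entrained cells with a percentile bootstrap CI.

    Resamples the cell population with replacement ``n_boot`` times.
    """
    rng = rng or np.random.default_rng()
    flags = np.asarray(entrained, dtype=float)
    n = flags.size
    if n == 0:
        raise ValueError("empty population")
    frac = float(flags.mean())
    draws = flags[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
    lo, hi = np.percentile(draws, [50 * (1 - ci), 100 - 50 * (1 - ci)])
    return {"fraction": frac, "ci_low": float(lo), "ci_high": float(hi), "n": n}


def compare_fractions(a: Mapping[str, float], b: Mapping[str, float]) -> dict:
    """Non-overlap verdict between two bootstrap fraction CIs."""
    different = a["ci_high"] < b["ci_low"] or b["ci_high"] < a["ci_low"]
    return {
        "different": bool(different),
        "delta": a["fraction"] - b["fraction"],
    }


def reference_preference(
    flags: Sequence[EntrainmentFlags],
    epoch: str = "discrimination",
    same_key: str = "same_area",
    dhc_key: str = "dHC",
) -> dict:
    """Classify units by which reference LFP entrains them.

    Categories per unit: ``same_only``, ``dHC_only``, ``both`` (units
    entrained by neither are left out).  Among units entrained on
    either reference, the per-unit PPC pair (same-area vs dHC) is
    compared with a Wilcoxon signed-rank test.
    """
    categories: dict[str, str] = {}
    pairs: list[tuple[float, float]] = []
    for f in flags:
        same = f.entrained(same_key, epoch)
        dhc = f.entrained(dhc_key, epoch)
        if not (same or dhc):
            continue
        categories[f.unit_id] = (
            "both" if (same and dhc) else ("same_only" if same else "dHC_only")
        )
        ppc_same = f.stats[same_key][epoch].ppc
        ppc_dhc = f.stats[dhc_key][epoch].ppc
        if np.isfinite(ppc_same) and np.isfinite(ppc_dhc):
            pairs.append((ppc_same, ppc_dhc))
    counts = {
        k: sum(1 for v in categories.values() if v == k)
        for k in ("same_only", "dHC_only", "both")
    }
    p = float("nan")
    if len(pairs) >= 6:
        a, b = np.array(pairs).T
        if not np.allclose(a, b):
            p = float(stats.wilcoxon(a, b).pvalue)
    return {"category": categories, "counts": counts, "wilcoxon_p": p}


@dataclass(frozen=True)
class DecileModulation:
    unit_id: str
    power_per_decile: np.ndarray  # mean segment theta power per decile
    rate_per_decile: np.ndarray  # Hz
    normalized_rate: np.ndarray  # rate / session mean rate over segments
    ci_first: tuple[float, float]
    ci_last: tuple[float, float]
    cls: str  # increase / decrease / none
    n_segments: int


def rate_by_power_deciles(
    unit: SpikeTrain,
    series: PhaseSeries,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-2.0, 10.0),
    segment_len: float = 1.0,
    n_boot: int = 1000,
    ci: float = 0.95,
    rng: np.random.Generator | None = None,
) -> DecileModulation:
    """Firing-rate modulation by theta power, in power deciles.

    Non-overlapping 1 s segments are laid out per trial over
    [-2, +10] s around sample start; each segment's theta power is the
    mean squared Hilbert envelope of the theta-filtered same-area LFP.
    Segments are ranked into deciles over the full session (ties broken
    by segment start time); a cell is classed ``increase``/``decrease``
    if the bootstrap 95% CIs of the first- and last-decile mean firing
    rates do not overlap.
    """
    rng = rng or np.random.default_rng()
    starts: list[float] = []
    prev_end = -np.inf
    for _, row in trials.sort_values("t_sample_start").iterrows():
        t0 = row["t_sample_start"] + window[0]
        t1 = row["t_sample_start"] + window[1]
        for s in np.arange(t0, t1 - segment_len + 1e-9, segment_len):
            if s < prev_end:
                logger.info(
                    "trial %d: segment at %.2f s overlaps previous trial; dropped",
                    row["trial_id"],
                    s,
                )
                continue
            if s < series.t[0] or s + segment_len > series.t[-1]:
                continue
            starts.append(float(s))
            prev_end = s + segment_len
    starts_arr = np.asarray(starts)
    n_seg = starts_arr.size
    if n_seg < 30:
        raise ValueError(f"need >= 30 segments, got {n_seg}")
    env2 = np.abs(series.analytic) ** 2
    power = np.empty(n_seg)
    rate = np.empty(n_seg)
    for i, s in enumerate(starts_arr):
        i0 = int(round((s - series.t[0]) * series.fs))
        i1 = i0 + int(round(segment_len * series.fs))
        power[i] = env2[i0:i1].mean()
        rate[i] = np.count_nonzero(
            (unit.times >= s) & (unit.times < s + segment_len)
        ) / segment_len
    # stable decile partition: rank by (power, start time)
    order = np.lexsort((starts_arr, power))
    decile_groups = np.array_split(order, 10)
    rate_per_decile = np.array([rate[g].mean() for g in decile_groups])
    power_per_decile = np.array([power[g].mean() for g in decile_groups])
    mean_rate = rate.mean()
    normalized = rate_per_decile / mean_rate if mean_rate > 0 else rate_per_decile * np.nan

    def boot_ci(group: np.ndarray) -> tuple[float, float]:
        vals = rate[group]
        draws = vals[rng.integers(0, vals.size, size=(n_boot, vals.size))].mean(axis=1)
        lo, hi = np.percentile(draws, [50 * (1 - ci), 100 - 50 * (1 - ci)])
        return float(lo), float(hi)

    ci_first = boot_ci(decile_groups[0])
    ci_last = boot_ci(decile_groups[-1])
    if ci_first[1] < ci_last[0]:
        cls = "increase"
    elif ci_last[1] < ci_first[0]:
        cls = "decrease"
    else:
        cls = "none"
    return DecileModulation(
        unit_id=unit.unit_id,
        power_per_decile=power_per_decile,
        rate_per_decile=rate_per_decile,
        normalized_rate=normalized,
        ci_first=ci_first,
        ci_last=ci_last,
        cls=cls,
        n_segments=n_seg,
    )
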