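"""Modality selectivity of phase entrainment in the discrimination epoch.

Spike-triggered phases during the 500 ms sensory-discrimination window
are grouped by the trial's stimulus modality (tactile T, visual V,
multimodal M).  Per modality, the PPC is tested against a 500-draw
permutation null built from all LFP phases in the sampling epochs
(drawn without repetition), and cells are classified by their
significance pattern:

* T_only  : significant in T, not in V
* V_only  : significant in V, not in T
* T_and_V : significant in both T and V
* M_only  : significant in M only
* none    : not entrained in any condition (excluded from fractions)

Two confound controls accompany the classification: a spike-count
matched PPC (each modality subsampled to the smallest modality's spike
count, removing firing-rate differences), and the spike-triggered
theta amplitude per modality (removing theta-power differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circstats import ppc_from_resultant, ppc_pooled
from .core_io import MODALITIES, EpochWindow, SpikeTrain
from .phase import PhaseSeries, spike_phases
from .sliding import sample_without_replacement

__all__ = [
    "ModalityStats",
    "ModalityResult",
    "modality_significance",
    "classify_modality",
    "fraction_per_class_ci",
    "modality_ppc_compare",
    "spike_matched_ppc",
    "amplitude_controls",
]

ALPHA_MODALITY = 0.05  # per-modality PPC permutation threshold
CLASSES = ("T_only", "V_only", "T_and_V", "M_only", "none")


@dataclass(frozen=True)
class ModalityStats:
    n_spikes: int
    ppc: float
    p: float
    significant: bool
    testable: bool
    mean_amplitude: float  # spike-triggered theta envelope (uV)


@dataclass(frozen=True)
class ModalityResult:
    unit_id: str
    per_modality: dict[str, ModalityStats]
    cls: str
    spike_matched_ppc: dict[str, float]


def _discrimination_phases(
    series: PhaseSeries,
    unit: SpikeTrain,
    windows: Sequence[EpochWindow],
    modality_by_trial: Mapping[int, str],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(phases, amplitudes) of discrimination-epoch spikes per modality."""
    sp = spike_phases(series, unit)
    out: dict[str, tuple[list, list]] = {m: ([], []) for m in MODALITIES}
    for w in windows:
        if w.epoch != "discrimination":
            continue
        modality = modality_by_trial.get(w.trial_id)
        if modality not in out:
            continue
        m = (sp.times >= w.t0) & (sp.times < w.t1)
        out[modality][0].append(sp.phase[m])
        out[modality][1].append(sp.amplitude[m])
    return {
        m: (
            np.concatenate(ph) if ph else np.empty(0),
            np.concatenate(am) if am else np.empty(0),
        )
        for m, (ph, am) in out.items()
    }


def _sampling_epoch_reservoir(
    series: PhaseSeries, windows: Sequence[EpochWindow]
) -> np.ndarray:
    chunks = [
        np.angle(series.analytic[series.restrict(w.t0, w.t1)])
        for w in windows
        if w.epoch == "discrimination"
    ]
    if not chunks:
        raise ValueError("no discrimination windows for the phase reservoir")
    reservoir = np.concatenate(chunks)
    if reservoir.size == 0:
        raise ValueError("empty sampling-epoch phase reservoir")
    return reservoir


def modality_significance(
    unit: SpikeTrain,
    series: PhaseSeries,
    windows: Sequence[EpochWindow],
    trials: pd.DataFrame,
    n_perm: int = 500,
    alpha: float = ALPHA_MODALITY,
    rng: np.random.Generator | None = None,
    n_match_reps: int = 100,
) -> ModalityResult:
    """Per-modality PPC, permutation p and selectivity class of one unit.

    The null draws, per permutation, N_spikes phases without repetition
    from the pooled sampling-epoch LFP phases; p is the exceedance rank
    over ``n_perm`` draws (floored at 1/n_perm).  Modalities with < 2
    spikes are marked untestable.  Spike-matched PPCs (mean over
    ``n_match_reps`` subsamples at the smallest testable modality's
    spike count) are attached.
    """
    rng = rng or np.random.default_rng()
    modality_by_trial = dict(zip(trials["trial_id"], trials["modality"]))
    grouped = _discrimination_phases(series, unit, windows, modality_by_trial)
    reservoir = _sampling_epoch_reservoir(series, windows)
    z_res = np.exp(1j * reservoir)
    per_modality: dict[str, ModalityStats] = {}
    for m in MODALITIES:
        phases, amps = grouped[m]
        n = phases.size
        mean_amp = float(amps.mean()) if n else float("nan")
        if n < 2:
            per_modality[m] = ModalityStats(n, float("nan"), 1.0, False, False, mean_amp)
            continue
        emp = ppc_pooled(phases)
        idx = sample_without_replacement(rng, reservoir.size, n_perm, n)
        null = ppc_from_resultant(np.abs(z_res[idx].sum(axis=1)), n)
        p = max(int((null >= emp).sum()), 1) / n_perm
        per_modality[m] = ModalityStats(n, float(emp), float(p), p < alpha, True, mean_amp)
    cls = classify_modality({m: s.significant for m, s in per_modality.items()},
                            {m: s.testable for m, s in per_modality.items()})
    matched = spike_matched_ppc(
        {m: grouped[m][0] for m in MODALITIES}, rng=rng, n_reps=n_match_reps
    )
    return ModalityResult(
        unit_id=unit.unit_id, per_modality=per_modality, cls=cls,
        spike_matched_ppc=matched,
    )


def classify_modality(
    significant: Mapping[str, bool], testable: Mapping[str, bool] | None = None
) -> str:
    """Selectivity class from the per-modality significance pattern."""
    if testable is not None and not all(testable.get(m, False) for m in MODALITIES):
        return "none"
    t, v, m = (bool(significant.get(k, False)) for k in MODALITIES)
    if t and v:
        return "T_and_V"
    if t:
        return "T_only"
    if v:
        return "V_only"
    if m:
        return "M_only"
    return "none"


def fraction_per_class_ci(
    classes: Sequence[str],
    n_boot: int = 1000,
    ci: float = 0.99,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Class fractions with 99% bootstrap CIs and nonzero verdicts.

    Fractions are taken over all classified units (including ``none``);
    a class is significant when its CI lower bound exceeds zero.
    """
    rng = rng or np.random.default_rng()
    arr = np.asarray(classes)
    n = arr.size
    if n == 0:
        raise ValueError("empty population")
    draws = arr[rng.integers(0, n, size=(n_boot, n))]
    rows = []
    for cls in CLASSES:
        frac = float((arr == cls).mean())
        boot = (draws == cls).mean(axis=1)
        lo, hi = np.percentile(boot, [50 * (1 - ci), 100 - 50 * (1 - ci)])
        rows.append(
            {
                "class": cls,
                "fraction": frac,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "significant": bool(lo > 0),
            }
        )
    return pd.DataFrame(rows)


def spike_matched_ppc(
    phases_by_modality: Mapping[str, np.ndarray],
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """PPC per modality at a matched spike count.

    Every modality is subsampled (without replacement) to the spike
    count of the modality with the fewest spikes; the PPC is averaged
    over ``n_reps`` subsample repetitions, removing any effect of
    firing-rate differences between modalities.
    """
    rng = rng or np.random.default_rng()
    sizes = {m: np.asarray(p).size for m, p in phases_by_modality.items()}
    n_min = min(sizes.values())
    out: dict[str, float] = {}
    if n_min < 2:
        return {m: float("nan") for m in phases_by_modality}
    for m, phases in phases_by_modality.items():
        z = np.exp(1j * np.asarray(phases, dtype=float))
        if z.size == n_min:
            out[m] = float(ppc_from_resultant(np.abs(z.sum()), n_min))
            continue
        idx = sample_without_replacement(rng, z.size, n_reps, n_min)
        vals = ppc_from_resultant(np.abs(z[idx].sum(axis=1)), n_min)
        out[m] = float(vals.mean())
    return out


def modality_ppc_compare(
    ppc_by_modality: pd.DataFrame, alpha: float = 0.01
) -> dict:
    """Omnibus + post hoc comparison of per-unit PPC across modalities.

    ``ppc_by_modality`` is (units x {T, V, M}) over entrained units.
    A Kruskal-Wallis omnibus test gates one-sided Wilcoxon signed-rank
    post hoc pairs at ``alpha``.  Returns the omnibus p and, per pair,
    the better modality and its p-value.
    """
    if len(ppc_by_modality) < 10:
        raise ValueError("need >= 10 units")
    cols = [c for c in MODALITIES if c in ppc_by_modality.columns]
    data = {c: ppc_by_modality[c].to_numpy(dtype=float) for c in cols}
    groups = [v[np.isfinite(v)] for v in data.values()]
    omnibus_p = float(stats.kruskal(*groups).pvalue)
    posthoc = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x, y = data[a], data[b]
            keep = np.isfinite(x) & np.isfinite(y)
            x, y = x[keep], y[keep]
            if x.size < 2 or np.allclose(x, y) or omnibus_p >= alpha:
                posthoc[f"{a}_vs_{b}"] = {"p": 1.0, "greater": None, "significant": False}
                continue
            direction = a if np.median(x - y) > 0 else b
            p = float(
                stats.wilcoxon(
                    x, y, alternative="greater" if direction == a else "less"
                ).pvalue
            )
            posthoc[f"{a}_vs_{b}"] = {
                "p": p,
                "greater": direction,
                "significant": p < alpha,
            }
    return {"omnibus_p": omnibus_p, "posthoc": posthoc}


def amplitude_controls(
    results: Sequence[ModalityResult],
    amplitudes_by_unit: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    alpha: float = 0.01,
) -> dict:
    """Theta-amplitude confound checks for the modality comparison.

    Per unit (when raw spike-triggered amplitudes are supplied): a
    Kruskal-Wallis test of amplitude across modalities at ``alpha``.
    Across units: Pearson correlation between the mean spike-triggered
    theta amplitude and the PPC, per modality.
    """
    per_unit_p: dict[str, float] = {}
    if amplitudes_by_unit:
        for unit_id, by_mod in amplitudes_by_unit.items():
            groups = [np.asarray(v) for v in by_mod.values() if np.asarray(v).size >= 2]
            if len(groups) >= 2:
                per_unit_p[unit_id] = float(stats.kruskal(*groups).pvalue)
    correlations: dict[str, dict[str, float]] = {}
    for m in MODALITIES:
        amp = np.array([r.per_modality[m].mean_amplitude for r in results])
        ppc = np.array([r.per_modality[m].ppc for r in results])
        keep = np.isfinite(amp) & np.isfinite(ppc)
        if keep.sum() >= 3 and np.ptp(amp[keep]) > 0 and np.ptp(ppc[keep]) > 0:
            r, p = stats.pearsonr(amp[keep], ppc[keep])
            correlations[m] = {"r": float(r), "p": float(p)}
        else:
            correlations[m] = {"r": float("nan"), "p": float("nan")}
    n_sig = sum(1 for p in per_unit_p.values() if p < alpha)
    return {
        "per_unit_kruskal_p": per_unit_p,
        "n_units_amplitude_differs": n_sig,
        "amplitude_ppc_correlation": correlations,
    }
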