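"""Synthetic session generator with known ground truth.

Every stage of the analysis pipeline is validated against sessions in
which the answer is known by construction:

* the LFP of each area is an epoch-gated theta oscillation (default
  8 Hz) riding on 1/f^alpha background noise; theta amplitude is set
  per behavioral epoch (ramped over 100 ms at window edges) and the
  theta cycle can be warped into an asymmetric "sawtooth" shape;
* spike trains are inhomogeneous Poisson processes whose intensity is
  von Mises phase modulation of a base rate,

      lambda(t) = r * exp(kappa(t) * cos(phi(t) - mu)) / I0(kappa(t)),

  where phi(t) is the *noiseless* theta phase (the generator knows the
  true phase; the pipeline must re-estimate it from the noisy trace)
  and kappa(t) is selected by the current behavioral epoch and the
  trial's stimulus modality.  The I0 normalization keeps the
  time-averaged rate at the base rate.  Exact simulation by thinning.
* trials follow the self-paced task structure (sample start at the
  object, reward poke, long inter-trial interval from which the
  baseline epoch is sampled), with per-modality correct-response
  probabilities.

A fixed seed yields a byte-identical session bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import i0

from .circstats import wrap_phase
from .core_io import (
    AREAS,
    EPOCHS,
    MODALITIES,
    EpochWindow,
    LfpTrace,
    SessionBundle,
    SpikeTrain,
    UnitMetrics,
    segment_epochs,
)

__all__ = [
    "LfpGenParams",
    "GroundTruth",
    "SessionGenConfig",
    "GenLfp",
    "gen_trials",
    "gen_lfp",
    "gen_spike_train",
    "gen_session",
]

DEFAULT_AMP_BY_EPOCH = {
    "default": 30.0,
    "baseline": 25.0,
    "object_approach": 40.0,
    "discrimination": 50.0,
    "reward_site_approach": 40.0,
    "outcome": 30.0,
}


@dataclass(frozen=True)
class LfpGenParams:
    """Parameters of the synthetic LFP of one area.

    ``amp_by_epoch`` maps behavioral epochs to theta amplitude (uV);
    the ``"default"`` key applies outside any epoch window.
    ``sawtooth_skew`` in [0, 1) warps each theta cycle monotonically
    (0 = pure sinusoid), compressing the ascending flank as observed
    in hippocampal theta.  ``amp_scale_by_modality`` optionally scales
    the theta amplitude within the epoch windows of trials of a given
    modality (used by the amplitude-confound controls).
    """

    theta_freq: float = 8.0  # Hz
    amp_by_epoch: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMP_BY_EPOCH)
    )
    pink_noise_sd: float = 15.0  # uV
    pink_exponent: float = 1.0  # 1/f^alpha
    sawtooth_skew: float = 0.0
    fs: float = 1000.0
    amp_scale_by_modality: Mapping[str, float] = field(default_factory=dict)
    ramp: float = 0.1  # s, amplitude crossfade at epoch-window edges
    phase_lag: float = 0.0  # rad, constant offset of the theta phase

    def __post_init__(self) -> None:
        if self.fs < 250.0:
            raise ValueError("fs must be >= 250 Hz (>= 20 samples per theta cycle)")
        if not (0.0 <= self.sawtooth_skew < 1.0):
            raise ValueError("sawtooth_skew must be in [0, 1)")
        if any(v < 0 for v in self.amp_by_epoch.values()):
            raise ValueError("amplitudes must be >= 0")
        if "default" not in self.amp_by_epoch:
            raise ValueError("amp_by_epoch requires a 'default' entry")


@dataclass(frozen=True)
class GroundTruth:
    """True phase-locking parameters of one synthetic unit.

    ``kappa`` maps epoch -> modality -> von Mises concentration; the
    special modality key ``"*"`` applies to every modality.  Epochs
    absent from the map, and time outside any epoch window, use
    ``kappa_outside``.
    """

    unit_id: str
    area: str
    mu: float  # preferred phase (rad)
    base_rate: float  # Hz
    kappa: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    kappa_outside: float = 0.0
    #: multiplicative rate factor inside epoch windows of trials of a
    #: modality (models rate changes confounded with stimulus condition)
    rate_scale_by_modality: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        for epoch, by_mod in self.kappa.items():
            if epoch not in EPOCHS:
                raise ValueError(f"unknown epoch {epoch!r} in kappa map")
            for k in by_mod.values():
                if k < 0:
                    raise ValueError("kappa must be >= 0")
        if self.kappa_outside < 0:
            raise ValueError("kappa must be >= 0")
        if any(v < 0 for v in self.rate_scale_by_modality.values()):
            raise ValueError("rate scales must be >= 0")

    def kappa_for(self, epoch: str | None, modality: str | None) -> float:
        if epoch is None or epoch not in self.kappa:
            return self.kappa_outside
        by_mod = self.kappa[epoch]
        if modality is not None and modality in by_mod:
            return float(by_mod[modality])
        if "*" in by_mod:
            return float(by_mod["*"])
        return self.kappa_outside

    def max_kappa(self) -> float:
        values = [self.kappa_outside]
        for by_mod in self.kappa.values():
            values.extend(by_mod.values())
        return float(max(values))

    def to_json(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "area": self.area,
            "mu": self.mu,
            "base_rate": self.base_rate,
            "kappa": {e: dict(m) for e, m in self.kappa.items()},
            "kappa_outside": self.kappa_outside,
            "rate_scale_by_modality": dict(self.rate_scale_by_modality),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        return cls(
            unit_id=obj["unit_id"],
            area=obj["area"],
            mu=obj["mu"],
            base_rate=obj["base_rate"],
            kappa=obj.get("kappa", {}),
            kappa_outside=obj.get("kappa_outside", 0.0),
            rate_scale_by_modality=obj.get("rate_scale_by_modality", {}),
        )


@dataclass(frozen=True)
class SessionGenConfig:
    """Layout of a synthetic session.

    Timing ranges emulate the self-paced task: the animal reaches the
    sampling area (sample start), samples the object, runs to a reward
    port (reward poke) and then waits out a long inter-trial interval.
    """

    n_trials_per_modality: int = 20
    seed: int = 0
    units: Sequence[GroundTruth] = ()
    areas: Sequence[str] = AREAS
    lfp_params: Mapping[str, LfpGenParams] = field(default_factory=dict)
    run_range: tuple[float, float] = (2.5, 4.0)  # sample start -> reward poke
    iti: float = 12.0  # s after reward poke before next approach
    approach_range: tuple[float, float] = (1.0, 2.0)
    withdrawal_range: tuple[float, float] = (0.3, 0.7)
    p_correct: Mapping[str, float] = field(
        default_factory=lambda: {"T": 0.72, "V": 0.72, "M": 0.84}
    )
    t_first: float = 3.0  # first sample start (keeps windows off the edge)
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.run_range[0] > self.run_range[1] or self.run_range[0] <= 1.5:
            raise ValueError(
                "run_range must be increasing and > 1.5 s so epoch windows "
                "within a trial cannot overlap"
            )
        if self.iti < 6.5:
            raise ValueError("iti must be >= 6.5 s to contain the baseline window")


def gen_trials(config: SessionGenConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate the trial table of a self-paced session."""
    modalities = np.repeat(list(MODALITIES), config.n_trials_per_modality)
    rng.shuffle(modalities)
    rows = []
    t_sample = config.t_first
    for i, modality in enumerate(modalities):
        run = rng.uniform(*config.run_range)
        t_poke = t_sample + run
        obj = rng.choice(["A", "B"])
        correct = bool(rng.random() < config.p_correct.get(modality, 0.5))
        # object A -> left when correct (arbitrary fixed coupling)
        side_for_obj = {"A": "L", "B": "R"}[obj]
        side = side_for_obj if correct else {"L": "R", "R": "L"}[side_for_obj]
        rows.append(
            {
                "trial_id": i,
                "modality": modality,
                "object": obj,
                "response_side": side,
                "correct": correct,
                "t_sample_start": t_sample,
                "t_reward_poke": t_poke,
                "withdrawal_latency": rng.uniform(*config.withdrawal_range),
            }
        )
        t_sample = t_poke + config.iti + rng.uniform(*config.approach_range)
    return pd.DataFrame(rows)


def session_duration(trials: pd.DataFrame, config: SessionGenConfig) -> float:
    return float(trials["t_reward_poke"].iloc[-1] + config.iti)


@dataclass(frozen=True)
class GenLfp:
    """A generated LFP trace together with its noiseless ground truth."""

    trace: LfpTrace
    true_phase: np.ndarray  # rad, phase of the noiseless theta component
    theta_amp: np.ndarray  # uV, amplitude envelope used
    params: LfpGenParams | None = None

    @property
    def t(self) -> np.ndarray:
        return self.trace.times

    def true_phase_at(self, times: np.ndarray) -> np.ndarray:
        """Exact (continuous-time) theta phase at arbitrary times."""
        if self.params is None:
            idx = np.clip(
                np.round(np.asarray(times) * self.trace.fs).astype(int),
                0,
                self.true_phase.size - 1,
            )
            return self.true_phase[idx]
        p = self.params
        cycle = (p.theta_freq * np.asarray(times, float) + p.phase_lag / (2 * np.pi)) % 1.0
        return wrap_phase(2.0 * np.pi * _sawtooth_warp(cycle, p.sawtooth_skew))


def _sawtooth_warp(u: np.ndarray, skew: float) -> np.ndarray:
    """Monotone cubic-easing warp of the cycle fraction u in [0, 1).

    skew = 0 is the identity; larger skew compresses the early
    (ascending) flank of the cycle while keeping one cycle per period.
    """
    return (1.0 - skew) * u + skew * u * u * (3.0 - 2.0 * u)


def _epoch_amplitude(
    params: LfpGenParams,
    trials: pd.DataFrame,
    n: int,
) -> np.ndarray:
    fs = params.fs
    amp = np.full(n, float(params.amp_by_epoch["default"]))
    modality_by_trial = dict(zip(trials["trial_id"], trials["modality"]))
    for w in segment_epochs(trials, session_end=n / fs):
        value = float(params.amp_by_epoch.get(w.epoch, params.amp_by_epoch["default"]))
        scale = float(
            params.amp_scale_by_modality.get(modality_by_trial.get(w.trial_id), 1.0)
            or 1.0
        )
        i0_, i1_ = int(round(w.t0 * fs)), int(round(w.t1 * fs))
        amp[max(i0_, 0) : min(i1_, n)] = value * scale
    # 100 ms boxcar smoothing yields linear ramps at window edges
    k = max(int(round(params.ramp * fs)), 1)
    kernel = np.ones(k) / k
    return np.convolve(amp, kernel, mode="same")


def _pink_noise(
    n: int, fs: float, sd: float, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^alpha Gaussian noise via spectral shaping, scaled to sd."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    x *= sd / x.std()
    return x


def gen_lfp(
    params: LfpGenParams,
    trials: pd.DataFrame,
    duration: float,
    seed: int | np.random.Generator,
    area: str = "dHC",
    channel_id: str = "ch0",
    tetrode_id: str = "tt_lfp",
) -> GenLfp:
    """Generate one area's LFP trace and its true theta phase.

    The trace is ``amp(t) * cos(phi(t)) + pink noise``; ``phi`` advances
    linearly at the theta frequency and is optionally warped into a
    sawtooth cycle shape.  ``amp(t)`` is the epoch-gated envelope.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = params.fs
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    cycle = (params.theta_freq * t + params.phase_lag / (2.0 * np.pi)) % 1.0
    warped = _sawtooth_warp(cycle, params.sawtooth_skew)
    true_phase = wrap_phase(2.0 * np.pi * warped)
    amp = _epoch_amplitude(params, trials, n)
    theta = amp * np.cos(2.0 * np.pi * warped)
    noise = _pink_noise(n, fs, params.pink_noise_sd, params.pink_exponent, rng)
    trace = LfpTrace(
        samples=theta + noise,
        fs=fs,
        area=area,
        channel_id=channel_id,
        tetrode_id=tetrode_id,
    )
    return GenLfp(trace=trace, true_phase=true_phase, theta_amp=amp, params=params)


def _epoch_modality_lookup(
    trials: pd.DataFrame, duration: float
) -> tuple[np.ndarray, list[tuple[str | None, str | None]]]:
    """Sorted window edges and (epoch, modality) label per interval."""
    windows = segment_epochs(trials, session_end=duration)
    modality_by_trial = dict(zip(trials["trial_id"], trials["modality"]))
    edges: list[float] = []
    labels: list[tuple[str | None, str | None]] = []
    for w in sorted(windows, key=lambda w: w.t0):
        edges.extend([w.t0, w.t1])
        labels.append((w.epoch, modality_by_trial.get(w.trial_id)))
    return np.asarray(edges), labels


def gen_spike_train(
    lfp: GenLfp,
    truth: GroundTruth,
    trials: pd.DataFrame,
    seed: int | np.random.Generator,
    tetrode_id: str | None = None,
) -> SpikeTrain:
    """Simulate a phase-locked spike train by thinning.

    Candidate spikes are drawn as a homogeneous Poisson process at the
    intensity bound ``lambda_max = r * exp(k_max) / I0(k_max)`` and
    accepted with probability ``lambda(t) / lambda_max``, which
    simulates the inhomogeneous process exactly (no discretization
    bias).  The phase used is the generator's noiseless theta phase.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = lfp.trace.duration
    k_max = truth.max_kappa()
    scale_max = max([1.0, *truth.rate_scale_by_modality.values()])
    lam_max = scale_max * truth.base_rate * np.exp(k_max) / i0(k_max)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    phi = lfp.true_phase_at(cand)
    # kappa at candidate times from the epoch-window lookup
    edges, labels = _epoch_modality_lookup(trials, duration)
    kappa = np.full(cand.size, truth.kappa_outside)
    scale = np.ones(cand.size)
    if edges.size:
        pos = np.searchsorted(edges, cand, side="right")
        inside = pos % 2 == 1  # odd -> within a window
        win_idx = (pos[inside] - 1) // 2
        kappa[inside] = [
            truth.kappa_for(labels[j][0], labels[j][1]) for j in win_idx
        ]
        if truth.rate_scale_by_modality:
            scale[inside] = [
                truth.rate_scale_by_modality.get(labels[j][1], 1.0) for j in win_idx
            ]
    lam = scale * truth.base_rate * np.exp(kappa * np.cos(phi - truth.mu)) / i0(kappa)
    accept = rng.uniform(0.0, lam_max, size=cand.size) < lam
    times = cand[accept]
    times = times[np.insert(np.diff(times) > 0, 0, True)]  # guard exact ties
    return SpikeTrain(
        unit_id=truth.unit_id,
        area=truth.area,
        tetrode_id=tetrode_id or f"{truth.area}_tt_unit",
        times=times,
        metrics=UnitMetrics(
            snr=5.0,
            refractory_violation_fraction=0.001,
            isolation_distance=20.0,
            session_rate=max(times.size / duration, 0.2),
            peak_amplitude=120.0,
            trough_to_peak=520.0,
        ),
    )


def gen_session(config: SessionGenConfig) -> SessionBundle:
    """Generate a full session bundle with a ground-truth sidecar.

    Each requested area receives one LFP channel (tetrode id
    ``<area>_tt_lfp``); units carry a different tetrode id
    (``<area>_tt_unit``) so the different-tetrode reference rule can be
    exercised.  The same seed reproduces the bundle exactly.
    """
    root = np.random.SeedSequence(config.seed)
    trial_seq, lfp_seq, spike_seq = root.spawn(3)
    rng_trials = np.random.default_rng(trial_seq)
    trials = gen_trials(config, rng_trials)
    duration = session_duration(trials, config)

    lfp: dict[str, LfpTrace] = {}
    gen_by_area: dict[str, GenLfp] = {}
    for area, child in zip(config.areas, lfp_seq.spawn(len(config.areas))):
        params = config.lfp_params.get(area, LfpGenParams(fs=config.fs))
        g = gen_lfp(
            params,
            trials,
            duration,
            np.random.default_rng(child),
            area=area,
            channel_id=f"{area}_ch0",
            tetrode_id=f"{area}_tt_lfp",
        )
        lfp[area] = g.trace
        gen_by_area[area] = g

    units: list[SpikeTrain] = []
    for truth, child in zip(config.units, spike_seq.spawn(max(len(config.units), 1))):
        if truth.area not in gen_by_area:
            raise ValueError(f"unit {truth.unit_id} assigned to missing area {truth.area}")
        units.append(
            gen_spike_train(
                gen_by_area[truth.area],
                truth,
                trials,
                np.random.default_rng(child),
                tetrode_id=f"{truth.area}_tt_unit",
            )
        )

    truth_json = {
        "seed": config.seed,
        "units": [u.to_json() for u in config.units],
    }
    return SessionBundle(lfp=lfp, units=units, trials=trials, truth=truth_json)
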