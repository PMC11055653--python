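"""Data model and session-bundle IO.

A *session bundle* is a directory of plain-text files describing one
recording session of the self-paced multisensory (tactile/visual/
multimodal) object-discrimination task:

``lfp_<area>.csv``
    one LFP voltage column (microvolts) per recorded area, with a JSON
    sidecar ``lfp_<area>.json`` holding sampling rate, channel/tetrode
    ids and a polarity flag;
``spikes.csv``
    long table of (unit_id, t_s) spike times;
``units.csv``
    unit metadata and spike-sorting QC metrics;
``trials.csv``
    trial table (modality, object, choice, correctness, event stamps);
``truth.json`` (optional)
    simulation ground truth written by :mod:`thetalock.synthetic`.

Everything is seconds / microvolts, float64; epoch windows are
half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("thetalock")

AREAS = ("S1BF", "V2L", "PER", "dHC")
MODALITIES = ("T", "V", "M")
EPOCHS = (
    "baseline",
    "object_approach",
    "discrimination",
    "reward_site_approach",
    "outcome",
)

#: analysis window length for every behavioral epoch (s)
EPOCH_LEN = 0.5
#: minimum head-fixation time at the sampling area; shorter trials are dropped
MIN_WITHDRAWAL_LATENCY = 0.2

# spike-sorting inclusion thresholds (all strict inequalities)
QC_MIN_SNR = 2.5
QC_MAX_REFRACTORY_VIOLATION = 0.005
QC_MIN_ISOLATION_DISTANCE = 5.0
QC_MIN_SESSION_RATE = 0.1  # Hz

# waveform-based cell-type split
MIN_WAVEFORM_AMPLITUDE = 50.0  # uV, below -> unclassified
TROUGH_TO_PEAK_SPLIT = 400.0  # us; > PE, < FS, == unclassified

TRIAL_COLUMNS = [
    "trial_id",
    "modality",
    "object",
    "response_side",
    "correct",
    "t_sample_start",
    "t_reward_poke",
    "withdrawal_latency",
]


class ValidationError(ValueError):
    """A session bundle violated a structural invariant."""


@dataclass(frozen=True)
class LfpTrace:
    """Uniformly sampled LFP voltage series for one channel."""

    samples: np.ndarray  # uV
    fs: float  # Hz
    area: str
    channel_id: str
    tetrode_id: str
    inverted: bool = False

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValidationError("LFP trace must be a 1-D series of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("LFP samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class UnitMetrics:
    """Spike-sorting quality metrics for one unit."""

    snr: float
    refractory_violation_fraction: float
    isolation_distance: float
    session_rate: float  # Hz
    peak_amplitude: float  # uV
    trough_to_peak: float  # us

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValidationError(f"UnitMetrics.{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s, strictly ascending) of one single unit."""

    unit_id: str
    area: str
    tetrode_id: str
    times: np.ndarray
    metrics: UnitMetrics | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"spike times of unit {self.unit_id} are not strictly ascending"
            )
        object.__setattr__(self, "times", times)

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class EpochWindow:
    """Half-open 500 ms analysis window [t0, t1) of one behavioral epoch."""

    trial_id: int
    epoch: str
    t0: float
    t1: float

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise ValidationError(f"unknown epoch {self.epoch!r}")
        if not np.isclose(self.t1 - self.t0, EPOCH_LEN):
            raise ValidationError("epoch windows must be 0.5 s long")


@dataclass
class SessionBundle:
    """One session: LFP per area, spike trains, trial table, optional truth."""

    lfp: dict[str, LfpTrace]
    units: list[SpikeTrain]
    trials: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self) -> None:
        validate_trials(self.trials)

    @property
    def duration(self) -> float:
        return max(t.duration for t in self.lfp.values())

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


def validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trials table missing columns {missing}")
    if trials["trial_id"].duplicated().any():
        dupes = trials.loc[trials["trial_id"].duplicated(), "trial_id"].tolist()
        raise ValidationError(f"duplicate trial_id values: {dupes}")
    bad = trials["t_sample_start"] >= trials["t_reward_poke"]
    if bad.any():
        raise ValidationError(
            f"t_sample_start >= t_reward_poke in trials {trials.loc[bad, 'trial_id'].tolist()}"
        )


# ---------------------------------------------------------------------------
# session bundle IO
# ---------------------------------------------------------------------------


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a session bundle to a directory of CSV/JSON files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for area, trace in bundle.lfp.items():
        pd.DataFrame({"microvolts": trace.samples}).to_csv(
            path / f"lfp_{area}.csv", index=False
        )
        meta = {
            "fs": trace.fs,
            "area": trace.area,
            "channel_id": trace.channel_id,
            "tetrode_id": trace.tetrode_id,
            "inverted": trace.inverted,
        }
        (path / f"lfp_{area}.json").write_text(json.dumps(meta, indent=1))
    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(
                [np.repeat(u.unit_id, u.n_spikes) for u in bundle.units]
            )
            if bundle.units
            else np.array([], dtype=str),
            "t_s": np.concatenate([u.times for u in bundle.units])
            if bundle.units
            else np.array([], dtype=float),
        }
    )
    spikes.to_csv(path / "spikes.csv", index=False)
    units_rows = []
    for u in bundle.units:
        row = {"unit_id": u.unit_id, "area": u.area, "tetrode_id": u.tetrode_id}
        if u.metrics is not None:
            row.update(asdict(u.metrics))
        units_rows.append(row)
    pd.DataFrame(
        units_rows,
        columns=["unit_id", "area", "tetrode_id", *UnitMetrics.__dataclass_fields__],
    ).to_csv(path / "units.csv", index=False)
    bundle.trials.to_csv(path / "trials.csv", index=False)
    if bundle.truth is not None:
        (path / "truth.json").write_text(json.dumps(bundle.truth, indent=1))
    return path


def read_session(path: str | Path) -> SessionBundle:
    """Read a session bundle written by :func:`write_session`.

    Raises a :class:`ValidationError` naming any missing file, and
    re-validates every structural invariant (ascending spike times,
    unique trial ids, sample start before reward poke).
    """
    path = Path(path)
    for required in ("spikes.csv", "units.csv", "trials.csv"):
        if not (path / required).exists():
            raise ValidationError(f"session bundle at {path} is missing {required}")
    lfp: dict[str, LfpTrace] = {}
    for meta_file in sorted(path.glob("lfp_*.json")):
        csv_file = meta_file.with_suffix(".csv")
        if not csv_file.exists():
            raise ValidationError(f"session bundle is missing {csv_file.name}")
        meta = json.loads(meta_file.read_text())
        samples = pd.read_csv(csv_file, float_precision="round_trip")["microvolts"].to_numpy(dtype=float)
        lfp[meta["area"]] = LfpTrace(
            samples=samples,
            fs=float(meta["fs"]),
            area=meta["area"],
            channel_id=meta["channel_id"],
            tetrode_id=meta["tetrode_id"],
            inverted=bool(meta["inverted"]),
        )
    if not lfp:
        raise ValidationError(f"session bundle at {path} contains no lfp_<area> files")
    units_df = pd.read_csv(
        path / "units.csv", dtype={"unit_id": str}, float_precision="round_trip"
    )
    spikes_df = pd.read_csv(
        path / "spikes.csv", dtype={"unit_id": str}, float_precision="round_trip"
    )
    units: list[SpikeTrain] = []
    metric_names = list(UnitMetrics.__dataclass_fields__)
    for _, row in units_df.iterrows():
        times = spikes_df.loc[
            spikes_df["unit_id"] == row["unit_id"], "t_s"
        ].to_numpy(dtype=float)
        metrics = None
        if all(name in row and pd.notna(row[name]) for name in metric_names):
            metrics = UnitMetrics(**{name: float(row[name]) for name in metric_names})
        units.append(
            SpikeTrain(
                unit_id=str(row["unit_id"]),
                area=str(row["area"]),
                tetrode_id=str(row["tetrode_id"]),
                times=times,
                metrics=metrics,
            )
        )
    trials = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    truth = None
    if (path / "truth.json").exists():
        truth = json.loads((path / "truth.json").read_text())
    return SessionBundle(lfp=lfp, units=units, trials=trials, truth=truth)


# ---------------------------------------------------------------------------
# unit QC and cell-type classification
# ---------------------------------------------------------------------------


def qc_filter_units(
    metrics_by_unit: Mapping[str, UnitMetrics | None],
) -> list[str]:
    """Apply the spike-sorting inclusion criteria.

    A unit is kept iff snr > 2.5, refractory violations < 0.5%,
    isolation distance > 5 and whole-session rate > 0.1 Hz (all strict).
    Units with missing metrics are excluded with a logged reason.
    """
    included = []
    for unit_id, m in metrics_by_unit.items():
        if m is None:
            logger.info("unit %s excluded from QC: metrics missing", unit_id)
            continue
        if (
            m.snr > QC_MIN_SNR
            and m.refractory_violation_fraction < QC_MAX_REFRACTORY_VIOLATION
            and m.isolation_distance > QC_MIN_ISOLATION_DISTANCE
            and m.session_rate > QC_MIN_SESSION_RATE
        ):
            included.append(unit_id)
    return included


def classify_cell_type(metrics: UnitMetrics) -> str:
    """Waveform class: 'PE' (putative excitatory), 'FS' (fast spiking).

    Units with mean-waveform amplitude below 50 uV are 'unclassified';
    otherwise the trough-to-peak latency splits the population at
    400 us (> PE, < FS; exactly 400 us is left unclassified since the
    split defines only the two open branches).
    """
    if metrics.peak_amplitude < MIN_WAVEFORM_AMPLITUDE:
        return "unclassified"
    if metrics.trough_to_peak > TROUGH_TO_PEAK_SPLIT:
        return "PE"
    if metrics.trough_to_peak < TROUGH_TO_PEAK_SPLIT:
        return "FS"
    return "unclassified"


# ---------------------------------------------------------------------------
# behavioral epochs
# ---------------------------------------------------------------------------

# epoch -> (anchor event column, offset of t0 relative to the anchor)
_EPOCH_OFFSETS = {
    "object_approach": ("t_sample_start", -0.5),
    "discrimination": ("t_sample_start", 0.0),
    "reward_site_approach": ("t_reward_poke", -1.0),
    "outcome": ("t_reward_poke", 0.0),
    "baseline": ("t_reward_poke", 6.0),
}


def segment_epochs(
    trials: pd.DataFrame, session_end: float | None = None
) -> list[EpochWindow]:
    """Derive the five 500 ms epoch windows of every trial.

    Windows per trial, anchored to the sample-start (IR sensor at the
    sampling area) and reward-poke events:

    * object approach      [t_sample_start - 0.5, t_sample_start)
    * discrimination       [t_sample_start, t_sample_start + 0.5)
    * reward-site approach [t_reward_poke - 1.0, t_reward_poke - 0.5)
    * outcome              [t_reward_poke, t_reward_poke + 0.5)
    * baseline             [t_reward_poke + 6.0, t_reward_poke + 6.5)
      (the animal rests during the inter-trial interval)

    Trials where the animal withdrew its head from the sampling area
    in under 200 ms are excluded entirely.  Baseline windows running
    past ``session_end`` are dropped with a warning.
    """
    validate_trials(trials)
    windows: list[EpochWindow] = []
    for _, row in trials.iterrows():
        if row["withdrawal_latency"] < MIN_WITHDRAWAL_LATENCY:
            logger.info(
                "trial %d excluded: withdrawal latency %.3f s < 0.2 s",
                row["trial_id"],
                row["withdrawal_latency"],
            )
            continue
        for epoch, (anchor, offset) in _EPOCH_OFFSETS.items():
            t0 = float(row[anchor]) + offset
            t1 = t0 + EPOCH_LEN
            if session_end is not None and t1 > session_end:
                logger.warning(
                    "trial %d: %s window [%.2f, %.2f) exceeds session end %.2f; dropped",
                    row["trial_id"],
                    epoch,
                    t0,
                    t1,
                    session_end,
                )
                continue
            windows.append(EpochWindow(int(row["trial_id"]), epoch, t0, t1))
    return windows


def windows_for_epoch(
    windows: Iterable[EpochWindow], epoch: str
) -> list[EpochWindow]:
    return [w for w in windows if w.epoch == epoch]


def behavioral_performance(trials: pd.DataFrame) -> dict[str, float]:
    """Percent-correct per stimulus modality.

    Trials excluded by the withdrawal-latency rule are not counted.
    Modalities without any valid trial are absent from the output.
    """
    validate_trials(trials)
    kept = trials[trials["withdrawal_latency"] >= MIN_WITHDRAWAL_LATENCY]
    out: dict[str, float] = {}
    for modality, group in kept.groupby("modality"):
        if len(group):
            out[str(modality)] = 100.0 * float(group["correct"].mean())
    return out
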