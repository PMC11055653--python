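"""Theta phase and envelope extraction from LFP traces.

The chain is: decimate to 1 kHz (anti-aliased) -> 6-12 Hz 4th-order
Butterworth, applied forward-backward so the filter is zero-phase (spike
phase pairing cannot tolerate group delay) -> analytic signal via the
Hilbert transform -> instantaneous phase (angle) and envelope (modulus).

Phase convention: 0 rad at the oscillation peak of a cosine, +/-pi at
the trough; internal unit is radians, display unit degrees.

Spike phases are obtained by linearly interpolating the *complex*
analytic signal onto the spike times and then taking angle/modulus;
interpolating the wrapped angle directly would be discontinuous at
+/-pi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import LfpTrace, SpikeTrain

logger = logging.getLogger("thetalock")

THETA_BAND = (6.0, 12.0)
FILTER_ORDER = 4
TARGET_FS = 1000.0
#: leading/trailing margin contaminated by filter and Hilbert end effects
EDGE_MARGIN = 0.5  # s

__all__ = [
    "PhaseSeries",
    "SpikePhases",
    "decimate_lfp",
    "bandpass_theta",
    "analytic_phase_amp",
    "spike_phases",
]


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous theta phase and envelope on a uniform time grid."""

    t: np.ndarray  # s
    analytic: np.ndarray  # complex analytic signal (uV)
    source_channel: str
    fs: float
    valid: np.ndarray  # bool mask; False inside edge margins / degenerate samples
    tetrode_id: str | None = None

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.analytic)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.analytic)

    def restrict(self, t0: float, t1: float) -> np.ndarray:
        """Indices of valid samples with t in [t0, t1)."""
        idx = np.nonzero((self.t >= t0) & (self.t < t1) & self.valid)[0]
        return idx


def decimate_lfp(trace: LfpTrace, target_fs: float = TARGET_FS) -> LfpTrace:
    """Anti-alias filter and subsample an LFP trace to ``target_fs``.

    The polarity flag is applied here: traces marked ``inverted`` (e.g.
    electrodes below the hippocampal pyramidal-layer phase reversal)
    are negated so that downstream phase estimates share one convention.
    Decimation is cascaded so no single stage exceeds a factor of 10.
    """
    if target_fs > trace.fs:
        raise ValueError(f"target_fs {target_fs} exceeds trace fs {trace.fs}")
    q = trace.fs / target_fs
    q_int = int(round(q))
    if abs(q - q_int) > 1e-9:
        logger.warning(
            "fs %.1f not divisible by target %.1f; using factor %d",
            trace.fs,
            target_fs,
            q_int,
        )
    x = trace.samples.astype(float)
    if trace.inverted:
        x = -x
    remaining = q_int
    while remaining > 1:
        stage = remaining
        while stage > 10:
            # prefer balanced integer stages
            for cand in (10, 8, 5, 4, 2):
                if remaining % cand == 0:
                    stage = cand
                    break
            else:
                stage = 10
        x = signal.decimate(x, stage, ftype="fir", zero_phase=True)
        remaining //= stage
    return LfpTrace(
        samples=x,
        fs=trace.fs / q_int,
        area=trace.area,
        channel_id=trace.channel_id,
        tetrode_id=trace.tetrode_id,
        inverted=False,
    )


def bandpass_theta(
    trace: LfpTrace,
    band: tuple[float, float] = THETA_BAND,
    order: int = FILTER_ORDER,
) -> LfpTrace:
    """Zero-phase Butterworth bandpass (default 6-12 Hz, 4th order).

    Applied forward and backward (``sosfiltfilt``), so the effective
    magnitude response is the squared Butterworth response and the group
    delay is zero.
    """
    lo, hi = band
    nyq = trace.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=trace.fs, output="sos")
    y = signal.sosfiltfilt(sos, trace.samples - np.mean(trace.samples))
    return LfpTrace(
        samples=y,
        fs=trace.fs,
        area=trace.area,
        channel_id=trace.channel_id,
        tetrode_id=trace.tetrode_id,
        inverted=trace.inverted,
    )


def analytic_phase_amp(
    trace: LfpTrace, edge_margin: float = EDGE_MARGIN
) -> PhaseSeries:
    """Analytic signal of a (band-passed, zero-mean) trace.

    Phase is the angle of the Hilbert analytic signal (0 at a cosine
    peak); amplitude is its modulus.  The first/last ``edge_margin``
    seconds are flagged invalid (filter + Hilbert end effects), as are
    samples with (near-)zero amplitude, where phase is undefined.
    """
    x = trace.samples
    analytic = signal.hilbert(x)
    n = x.size
    t = np.arange(n) / trace.fs
    valid = np.ones(n, dtype=bool)
    margin = int(round(edge_margin * trace.fs))
    if margin > 0:
        valid[:margin] = False
        valid[n - margin :] = False
    amp = np.abs(analytic)
    scale = amp.max() if amp.size else 0.0
    if scale == 0.0:
        valid[:] = False
    else:
        valid &= amp > 1e-12 * scale
    return PhaseSeries(
        t=t,
        analytic=analytic,
        source_channel=trace.channel_id,
        fs=trace.fs,
        valid=valid,
        tetrode_id=trace.tetrode_id,
    )


@dataclass(frozen=True)
class SpikePhases:
    """Theta phase/envelope at spike times, with bookkeeping of drops."""

    times: np.ndarray  # s, spikes that were assigned a phase
    phase: np.ndarray  # rad
    amplitude: np.ndarray  # uV
    n_dropped: int  # spikes outside the series or on invalid samples


def spike_phases(series: PhaseSeries, spikes: SpikeTrain | np.ndarray) -> SpikePhases:
    """Interpolate the LFP phase/envelope onto spike times.

    The complex analytic signal is interpolated linearly between the two
    neighboring LFP samples and the angle/modulus of the interpolant is
    taken, avoiding the wrap-around artifact of interpolating the angle.
    Spikes outside the series' valid time range are dropped and counted.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    n_in = times.size
    t0, t1 = series.t[0], series.t[-1]
    keep = (times >= t0) & (times <= t1)
    times_kept = times[keep]
    # interpolate real and imaginary parts on the uniform grid
    pos = (times_kept - t0) * series.fs
    idx = np.clip(np.floor(pos).astype(int), 0, series.t.size - 2)
    frac = pos - idx
    z = series.analytic[idx] * (1.0 - frac) + series.analytic[idx + 1] * frac
    # a spike is valid only if both bracketing samples are valid
    ok = series.valid[idx] & series.valid[idx + 1]
    z = z[ok]
    times_kept = times_kept[ok]
    n_dropped = n_in - times_kept.size
    if n_dropped:
        logger.debug("spike_phases: dropped %d/%d spikes", n_dropped, n_in)
    return SpikePhases(
        times=times_kept,
        phase=np.angle(z),
        amplitude=np.abs(z),
        n_dropped=n_dropped,
    )
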