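"""Circular statistics for spike-triggered phase distributions.

Spike phases are angles in radians in (-pi, pi].  Two families of
statistics are provided:

* the Rayleigh test of circular uniformity, used to flag a cell as
  phase entrained;
* the pairwise phase consistency (PPC), the average cosine of all
  pairwise phase differences.  Unlike the squared resultant length
  (whose expectation under uniformity is 1/n), the PPC is an unbiased
  estimator of the squared population resultant, which makes it usable
  at the low spike counts of narrow analysis windows.

The between-trials PPC variant averages only over pairs of spikes from
different trials, removing the upward bias produced by within-trial
bursts (a burst contributes many nearly identical phases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseSample",
    "RayleighResult",
    "wrap_phase",
    "circular_mean",
    "resultant_length",
    "rayleigh_test",
    "ppc_pooled",
    "ppc_between_trials",
    "ppc_from_resultant",
    "vonmises_ppc",
]


def wrap_phase(phases: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    out = np.asarray(phases, dtype=float)
    out = -((-out + np.pi) % (2.0 * np.pi) - np.pi)
    return out


@dataclass(frozen=True)
class PhaseSample:
    """A set of phases (radians), optionally labelled by trial.

    ``trial_ids`` is parallel to ``phases``; it is required only by the
    between-trials PPC estimator.
    """

    phases: np.ndarray
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        phases = np.atleast_1d(np.asarray(self.phases, dtype=float))
        object.__setattr__(self, "phases", phases)
        if self.trial_ids is not None:
            ids = np.atleast_1d(np.asarray(self.trial_ids))
            if ids.shape != phases.shape:
                raise ValueError(
                    "trial_ids must be parallel to phases "
                    f"({ids.shape} vs {phases.shape})"
                )
            object.__setattr__(self, "trial_ids", ids)

    @property
    def n(self) -> int:
        return self.phases.size


@dataclass(frozen=True)
class RayleighResult:
    resultant: float  # mean resultant length R-bar
    z: float  # Rayleigh statistic Z = n * R-bar^2
    p: float
    mean_phase: float  # circular mean (radians)
    n: int


def circular_mean(phases: np.ndarray) -> float:
    """Circular mean direction of a set of angles (radians)."""
    z = np.exp(1j * np.asarray(phases, dtype=float))
    return float(np.angle(z.sum()))


def resultant_length(phases: np.ndarray) -> float:
    """Mean resultant length R-bar = |sum(e^{i theta})| / n."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("resultant_length undefined for empty sample")
    return float(np.abs(np.exp(1j * phases).sum()) / phases.size)


def rayleigh_test(sample: PhaseSample | np.ndarray) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    Returns the mean resultant length, the statistic Z = n * R-bar^2 and
    the standard small-sample series approximation of the p-value::

        p ~= exp(-Z) * [1 + (2Z - Z^2)/(4n)
                          - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    clipped to [0, 1].
    """
    if not isinstance(sample, PhaseSample):
        sample = PhaseSample(np.asarray(sample))
    n = sample.n
    if n == 0:
        raise ValueError("Rayleigh test undefined for an empty sample")
    z_sum = np.exp(1j * sample.phases).sum()
    rbar = float(np.abs(z_sum) / n)
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = float(np.clip(p, 0.0, 1.0))
    return RayleighResult(
        resultant=rbar, z=float(z), p=p, mean_phase=float(np.angle(z_sum)), n=n
    )


def ppc_from_resultant(abs_sum: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Pooled PPC from |sum(e^{i theta})| and the sample size n.

    Vector identity: sum_{j<k} cos(t_j - t_k) = (|S|^2 - n) / 2 with
    S = sum(e^{i theta}), so PPC = (|S|^2 - n) / (n (n - 1)).  Exposed
    separately because the permutation machinery computes many PPCs from
    precomputed complex sums.
    """
    abs_sum = np.asarray(abs_sum, dtype=float)
    n = np.asarray(n, dtype=float)
    return (abs_sum**2 - n) / (n * (n - 1.0))


def ppc_pooled(sample: PhaseSample | np.ndarray) -> float:
    """Pairwise phase consistency over all spike pairs.

    PPC = 2/(n(n-1)) * sum_{j<k} cos(theta_j - theta_k), in
    [-1/(n-1), 1].  Unbiased under uniformity (expectation 0).
    """
    if not isinstance(sample, PhaseSample):
        sample = PhaseSample(np.asarray(sample))
    n = sample.n
    if n < 2:
        raise ValueError("PPC requires at least 2 phases")
    s = np.abs(np.exp(1j * sample.phases).sum())
    return float(ppc_from_resultant(s, n))


def ppc_between_trials(sample: PhaseSample) -> float:
    """PPC averaged only over pairs of spikes from *different* trials.

    Bursty cells emit runs of spikes at nearly the same phase within a
    trial; pooling those pairs inflates the pooled PPC.  Restricting to
    across-trial pairs measures the phase consistency that survives from
    trial to trial.
    """
    if sample.trial_ids is None:
        raise ValueError("ppc_between_trials requires trial_ids")
    n = sample.n
    if n < 2:
        raise ValueError("PPC requires at least 2 phases")
    z = np.exp(1j * sample.phases)
    total_pairs_sum = (np.abs(z.sum()) ** 2 - n) / 2.0
    ids, inverse = np.unique(sample.trial_ids, return_inverse=True)
    if ids.size < 2:
        raise ValueError("ppc_between_trials requires >= 2 distinct trials")
    # complex sum and count per trial
    sums = np.zeros(ids.size, dtype=complex)
    np.add.at(sums, inverse, z)
    counts = np.bincount(inverse, minlength=ids.size).astype(float)
    within_sum = ((np.abs(sums) ** 2 - counts) / 2.0).sum()
    cross_pairs = (n * n - (counts**2).sum()) / 2.0
    if cross_pairs <= 0:
        raise ValueError("no across-trial spike pairs")
    return float((total_pairs_sum - within_sum) / cross_pairs)


def vonmises_ppc(kappa: float) -> float:
    """Population PPC of a von Mises distribution: (I1(k)/I0(k))^2."""
    from scipy.special import i0, i1

    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float((i1(kappa) / i0(kappa)) ** 2)
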