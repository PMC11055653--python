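"""Per-epoch entrainment flags, population fractions, deciles."""

import numpy as np
import pandas as pd
import pytest

import thetalock as tl
from conftest import CONST_AMP


@pytest.fixture(scope="module")
def epoch_session():
    """Session where one unit locks only during discrimination."""
    units = [
        tl.GroundTruth(
            "disc_only", "dHC", mu=0.5, base_rate=8.0,
            kappa={"discrimination": {"*": 2.0}},
        ),
        tl.GroundTruth("null", "dHC", mu=0.0, base_rate=8.0, kappa={}),
    ]
    cfg = tl.SessionGenConfig(
        n_trials_per_modality=12, seed=2, units=units, areas=("dHC",), iti=7.0
    )
    bundle = tl.gen_session(cfg)
    series = tl.analytic_phase_amp(tl.bandpass_theta(bundle.lfp["dHC"]))
    windows = tl.segment_epochs(bundle.trials, session_end=bundle.duration)
    return bundle, series, windows


class TestEntrainmentFlags:
    def test_discrimination_only_unit_recovered(self, epoch_session):
        bundle, series, windows = epoch_session
        f = tl.entrainment_flags(
            bundle.unit("disc_only"), {"same_area": series}, windows,
            trials=bundle.trials,
        )
        assert f.entrained("same_area", "discrimination")
        for epoch in ("baseline", "object_approach", "outcome"):
            assert not f.entrained("same_area", epoch)

    def test_null_unit_mostly_unflagged(self, epoch_session):
        bundle, series, windows = epoch_session
        f = tl.entrainment_flags(
            bundle.unit("null"), {"same_area": series}, windows, trials=bundle.trials
        )
        flagged = sum(f.entrained("same_area", e) for e in tl.EPOCHS)
        assert flagged <= 1  # chance-level flags only

    def test_same_tetrode_reference_rejected(self, epoch_session):
        bundle, series, windows = epoch_session
        unit = bundle.unit("null")
        bad = tl.SpikeTrain(unit.unit_id, unit.area, series.tetrode_id, unit.times)
        with pytest.raises(ValueError, match="tetrode"):
            tl.entrainment_flags(bad, {"same_area": series}, windows)

    def test_zero_spikes_epoch_recorded(self, epoch_session):
        bundle, series, windows = epoch_session
        silent = tl.SpikeTrain("silent", "dHC", "dHC_tt_unit", np.array([]))
        f = tl.entrainment_flags(silent, {"same_area": series}, windows)
        s = f.stats["same_area"]["discrimination"]
        assert s.n_spikes == 0 and not s.entrained


class TestReferenceChannelSelection:
    @staticmethod
    def _chan(theta_amp, noise_sd, seed, channel_id, tetrode_id):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 30, 1e-3)
        x = theta_amp * np.sin(2 * np.pi * 8 * t) + noise_sd * rng.standard_normal(
            t.size
        )
        return tl.LfpTrace(x, 1000.0, "dHC", channel_id, tetrode_id)

    def test_strongest_theta_channel_wins(self):
        weak = self._chan(5.0, 20.0, 0, "weak", "tt1")
        strong = self._chan(40.0, 20.0, 1, "strong", "tt2")
        chosen = tl.select_reference_channel([weak, strong])
        assert chosen.channel_id == "strong"

    def test_excluded_tetrode_skipped(self):
        weak = self._chan(5.0, 20.0, 0, "weak", "tt1")
        strong = self._chan(40.0, 20.0, 1, "strong", "tt2")
        chosen = tl.select_reference_channel([weak, strong], exclude_tetrode="tt2")
        assert chosen.channel_id == "weak"
        with pytest.raises(ValueError):
            tl.select_reference_channel([strong], exclude_tetrode="tt2")


class TestFractionCi:
    def test_all_entrained_degenerate_ci(self):
        out = tl.fraction_entrained_ci([True] * 20, rng=np.random.default_rng(0))
        assert out == {"fraction": 1.0, "ci_low": 1.0, "ci_high": 1.0, "n": 20}

    def test_coverage_at_study_scale(self):
        # true fraction 0.37 at n = 167 cells: the 95% CI should cover the
        # truth in about 95% of meta-runs
        rng = np.random.default_rng(1)
        covered = 0
        runs = 200
        for _ in range(runs):
            flags = rng.random(167) < 0.37
            out = tl.fraction_entrained_ci(flags, rng=rng)
            covered += out["ci_low"] <= 0.37 <= out["ci_high"]
        assert covered / runs >= 0.9

    def test_separated_populations_flagged_different(self):
        rng = np.random.default_rng(2)
        verdicts = 0
        runs = 50
        for _ in range(runs):
            a = tl.fraction_entrained_ci(rng.random(170) < 0.37, rng=rng)
            b = tl.fraction_entrained_ci(rng.random(370) < 0.06, rng=rng)
            verdicts += tl.compare_fractions(a, b)["different"]
        assert verdicts / runs > 0.95

    def test_ci_width_shrinks_with_population(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (50, 200, 800):
            flags = rng.random(n) < 0.4
            out = tl.fraction_entrained_ci(flags, rng=np.random.default_rng(0))
            widths.append(out["ci_high"] - out["ci_low"])
        assert widths[0] > widths[1] > widths[2]

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            tl.fraction_entrained_ci([])


def _flags(unit_id, same, dhc, ppc_same=0.2, ppc_dhc=0.1):
    stats = {}
    for ref, entrained, ppc in (
        ("same_area", same, ppc_same),
        ("dHC", dhc, ppc_dhc),
    ):
        stats[ref] = {
            e: tl.entrainment.EpochStats(100, 0.01 if entrained else 0.5, ppc, entrained)
            for e in tl.EPOCHS
        }
    return tl.EntrainmentFlags(unit_id, stats)


class TestReferencePreference:
    def test_categories(self):
        out = tl.reference_preference(
            [_flags("a", True, False), _flags("b", False, True), _flags("c", True, True)]
        )
        assert out["category"] == {"a": "same_only", "b": "dHC_only", "c": "both"}

    def test_shared_theta_gives_both(self, epoch_session):
        # perfect volume conduction: the same series as both references
        bundle, series, windows = epoch_session
        dup = tl.PhaseSeries(
            series.t, series.analytic, "other", series.fs, series.valid, "dHC_tt2"
        )
        f = tl.entrainment_flags(
            bundle.unit("disc_only"), {"same_area": series, "dHC": dup}, windows,
            trials=bundle.trials,
        )
        out = tl.reference_preference([f])
        assert out["counts"]["both"] == 1

    def test_independent_reference_gives_same_only(self, epoch_session):
        bundle, series, windows = epoch_session
        rng = np.random.default_rng(0)
        shuffled = tl.PhaseSeries(
            series.t,
            np.exp(1j * rng.uniform(-np.pi, np.pi, series.t.size)),
            "other",
            series.fs,
            series.valid,
            "dHC_tt2",
        )
        f = tl.entrainment_flags(
            bundle.unit("disc_only"), {"same_area": series, "dHC": shuffled}, windows,
            trials=bundle.trials,
        )
        out = tl.reference_preference([f])
        assert out["counts"]["same_only"] == 1


@pytest.fixture(scope="module")
def decile_setup():
    """Theta session with strongly epoch-modulated amplitude."""
    amp = dict(CONST_AMP, discrimination=90.0, baseline=10.0, object_approach=60.0)
    units = []  # spikes injected manually per test
    cfg = tl.SessionGenConfig(
        n_trials_per_modality=10, seed=4, units=units, areas=("dHC",), iti=7.0,
        lfp_params={"dHC": tl.LfpGenParams(amp_by_epoch=amp, pink_noise_sd=10.0)},
    )
    bundle = tl.gen_session(cfg)
    series = tl.analytic_phase_amp(tl.bandpass_theta(bundle.lfp["dHC"]))
    return bundle, series


def poisson_from_rate(rate_fn, series, rng):
    """Per-sample thinning of an inhomogeneous Poisson intensity."""
    lam = rate_fn(series)
    p = lam / series.fs
    hits = np.nonzero(rng.random(series.t.size) < p)[0]
    return tl.SpikeTrain("sim", "dHC", "dHC_tt_unit", series.t[hits])


class TestDeciles:
    def test_envelope_driven_unit_classified_increase(self, decile_setup):
        bundle, series = decile_setup
        rng = np.random.default_rng(0)
        env2 = np.abs(series.analytic) ** 2
        unit = poisson_from_rate(
            lambda s: 15.0 * env2 / env2.mean(), series, rng
        )
        out = tl.rate_by_power_deciles(unit, series, bundle.trials, rng=rng)
        assert out.cls == "increase"
        # normalized rate rises monotonically with power decile
        from scipy.stats import spearmanr

        rho = spearmanr(np.arange(10), out.normalized_rate).statistic
        assert rho > 0.9

    def test_independent_unit_classified_none(self, decile_setup):
        bundle, series = decile_setup
        rng = np.random.default_rng(1)
        classes = []
        for _ in range(20):
            unit = poisson_from_rate(lambda s: np.full(s.t.size, 8.0), series, rng)
            out = tl.rate_by_power_deciles(unit, series, bundle.trials, rng=rng)
            classes.append(out.cls)
        assert classes.count("none") >= 18

    def test_partition_counts(self, decile_setup):
        bundle, series = decile_setup
        rng = np.random.default_rng(2)
        unit = poisson_from_rate(lambda s: np.full(s.t.size, 5.0), series, rng)
        out = tl.rate_by_power_deciles(unit, series, bundle.trials, rng=rng)
        assert out.rate_per_decile.size == 10
        # deciles partition all segments with near-equal counts
        counts = [out.n_segments // 10, out.n_segments // 10 + 1]
        total = out.n_segments
        assert sum(counts) >= 2  # sanity on fixture size
        assert total >= 30

    def test_power_increases_across_deciles(self, decile_setup):
        bundle, series = decile_setup
        rng = np.random.default_rng(3)
        unit = poisson_from_rate(lambda s: np.full(s.t.size, 5.0), series, rng)
        out = tl.rate_by_power_deciles(unit, series, bundle.trials, rng=rng)
        assert np.all(np.diff(out.power_per_decile) >= 0)
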