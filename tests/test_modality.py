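"""Modality selectivity: classification, spike matching, amplitude controls."""

import numpy as np
import pandas as pd
import pytest

import thetalock as tl


class TestClassifyModality:
    @pytest.mark.parametrize(
        "sig, expected",
        [
            ({"T": True, "V": False, "M": False}, "T_only"),
            ({"T": False, "V": True, "M": False}, "V_only"),
            ({"T": True, "V": True, "M": True}, "T_and_V"),
            ({"T": True, "V": True, "M": False}, "T_and_V"),
            ({"T": False, "V": False, "M": True}, "M_only"),
            ({"T": True, "V": False, "M": True}, "T_only"),
            ({"T": False, "V": False, "M": False}, "none"),
        ],
    )
    def test_patterns(self, sig, expected):
        assert tl.classify_modality(sig) == expected

    def test_untestable_modality_gives_none(self):
        sig = {"T": True, "V": False, "M": False}
        testable = {"T": True, "V": True, "M": False}
        assert tl.classify_modality(sig, testable) == "none"


@pytest.fixture(scope="module")
def modality_session():
    """T-selective, V-selective and null units in one session."""
    units = [
        tl.GroundTruth("t_cell", "S1BF", 0.5, 8.0, {"discrimination": {"T": 2.0}}),
        tl.GroundTruth("v_cell", "S1BF", -1.0, 8.0, {"discrimination": {"V": 2.0}}),
        tl.GroundTruth("null_cell", "S1BF", 0.0, 8.0, {}),
    ]
    cfg = tl.SessionGenConfig(
        n_trials_per_modality=15, seed=5, units=units, areas=("S1BF",), iti=7.0
    )
    bundle = tl.gen_session(cfg)
    series = tl.analytic_phase_amp(tl.bandpass_theta(bundle.lfp["S1BF"]))
    windows = tl.segment_epochs(bundle.trials, session_end=bundle.duration)
    return bundle, series, windows


class TestModalitySignificance:
    def test_selective_units_recovered(self, modality_session):
        bundle, series, windows = modality_session
        rng = np.random.default_rng(0)
        res_t = tl.modality_significance(
            bundle.unit("t_cell"), series, windows, bundle.trials, rng=rng
        )
        assert res_t.per_modality["T"].significant
        assert not res_t.per_modality["V"].significant
        assert res_t.cls == "T_only"
        res_v = tl.modality_significance(
            bundle.unit("v_cell"), series, windows, bundle.trials, rng=rng
        )
        assert res_v.cls == "V_only"

    def test_identical_phases_extreme_p(self):
        # noiseless theta; spikes planted exactly on theta peaks (phase 0)
        # inside T windows only -> T PPC = 1 at the permutation floor
        cfg = tl.SessionGenConfig(
            n_trials_per_modality=10, seed=9, units=[], areas=("S1BF",), iti=7.0,
            lfp_params={"S1BF": tl.LfpGenParams(pink_noise_sd=0.0)},
        )
        bundle = tl.gen_session(cfg)
        series = tl.analytic_phase_amp(tl.bandpass_theta(bundle.lfp["S1BF"]))
        windows = tl.segment_epochs(bundle.trials, session_end=bundle.duration)
        modality = dict(zip(bundle.trials.trial_id, bundle.trials.modality))
        times = []
        for w in windows:
            if w.epoch == "discrimination" and modality[w.trial_id] == "T":
                k0 = int(np.ceil(w.t0 * 8))
                times += [k / 8 for k in range(k0, k0 + 3) if k / 8 < w.t1]
        unit = tl.SpikeTrain("planted", "S1BF", "S1BF_tt_unit", np.array(sorted(times)))
        res = tl.modality_significance(
            unit, series, windows, bundle.trials, rng=np.random.default_rng(1)
        )
        assert res.per_modality["T"].ppc == pytest.approx(1.0, abs=0.005)
        assert res.per_modality["T"].p == pytest.approx(1 / 500)

    def test_few_spikes_untestable(self, modality_session):
        bundle, series, windows = modality_session
        unit = tl.SpikeTrain(
            "sparse", "S1BF", "S1BF_tt_unit", np.array([10.0])
        )
        res = tl.modality_significance(
            unit, series, windows, bundle.trials, rng=np.random.default_rng(2)
        )
        assert not res.per_modality["T"].testable
        assert res.cls == "none"


class TestFractionPerClass:
    def test_single_class_population(self):
        out = tl.fraction_per_class_ci(
            ["T_only"] * 15, rng=np.random.default_rng(0)
        )
        row = out[out["class"] == "T_only"].iloc[0]
        assert row.fraction == 1.0 and row.significant

    def test_absent_class_not_significant(self):
        out = tl.fraction_per_class_ci(
            ["T_only"] * 10 + ["V_only"] * 5, rng=np.random.default_rng(1)
        )
        row = out[out["class"] == "M_only"].iloc[0]
        assert row.fraction == 0.0 and not row.significant

    def test_coverage_at_study_scale(self):
        # class probabilities at the sensory-cortex population scale (n=29)
        probs = {"T_only": 0.48, "V_only": 0.17, "T_and_V": 0.20, "M_only": 0.15}
        rng = np.random.default_rng(2)
        runs, covered = 150, 0
        labels = list(probs)
        p = np.array(list(probs.values()))
        covered = {c: 0 for c in labels}
        for _ in range(runs):
            classes = rng.choice(labels, size=29, p=p)
            out = tl.fraction_per_class_ci(list(classes), rng=rng)
            for c in labels:
                row = out[out["class"] == c].iloc[0]
                covered[c] += row.ci_low - 1e-12 <= probs[c] <= row.ci_high + 1e-12
        # each 99% interval covers its truth (bootstrap at n=29 slightly
        # undercovers, so allow a modest margin below nominal)
        for c in labels:
            assert covered[c] / runs >= 0.93

    def test_partition(self):
        rng = np.random.default_rng(3)
        classes = list(rng.choice(tl.modality.CLASSES, 40))
        out = tl.fraction_per_class_ci(classes, rng=rng)
        assert out["fraction"].sum() == pytest.approx(1.0)


class TestSpikeMatchedPpc:
    def test_rate_imbalance_removed(self):
        # same kappa, doubled spike count in T: matched PPCs statistically equal
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(50):
            t = rng.vonmises(0.0, 1.0, 400)
            v = rng.vonmises(0.0, 1.0, 200)
            out = tl.spike_matched_ppc({"T": t, "V": v}, rng=rng)
            diffs.append(out["T"] - out["V"])
        assert abs(np.mean(diffs)) < 0.01

    def test_true_difference_survives_matching(self):
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(50):
            t = rng.vonmises(0.0, 2.0, 400)  # stronger locking, more spikes
            v = rng.vonmises(0.0, 0.5, 200)
            out = tl.spike_matched_ppc({"T": t, "V": v}, rng=rng)
            wins += out["T"] > out["V"]
        assert wins >= 45

    def test_matched_count_is_minimum(self):
        rng = np.random.default_rng(2)
        out = tl.spike_matched_ppc(
            {"T": rng.vonmises(0, 1, 50), "V": rng.vonmises(0, 1, 9)}, rng=rng
        )
        assert np.isfinite(out["T"]) and np.isfinite(out["V"])


class TestModalityPpcCompare:
    def test_identical_data_not_significant(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 0.3, 20)
        df = pd.DataFrame({"T": base, "V": base, "M": base})
        out = tl.modality_ppc_compare(df)
        assert out["omnibus_p"] >= 0.01

    def test_separated_modality_detected(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "T": rng.uniform(0.3, 0.5, 25),
                "V": rng.uniform(0.0, 0.1, 25),
                "M": rng.uniform(0.0, 0.1, 25),
            }
        )
        out = tl.modality_ppc_compare(df)
        assert out["omnibus_p"] < 0.01
        assert out["posthoc"]["T_vs_V"]["significant"]
        assert out["posthoc"]["T_vs_V"]["greater"] == "T"


class TestAmplitudeControls:
    def test_equal_lfp_statistics_no_difference(self):
        # equal theta statistics AND equal locking across modalities: the
        # spike-triggered envelope must not differ between conditions
        # (phase-locked spikes sample the envelope non-uniformly, so the
        # locking strength must be matched for this negative control)
        units = [
            tl.GroundTruth("a", "S1BF", 0.5, 8.0, {"discrimination": {"*": 1.5}}),
            tl.GroundTruth("b", "S1BF", -1.0, 8.0, {"discrimination": {"*": 1.5}}),
            tl.GroundTruth("c", "S1BF", 0.0, 8.0, {}),
        ]
        cfg = tl.SessionGenConfig(
            n_trials_per_modality=15, seed=6, units=units, areas=("S1BF",), iti=7.0
        )
        bundle = tl.gen_session(cfg)
        series = tl.analytic_phase_amp(tl.bandpass_theta(bundle.lfp["S1BF"]))
        windows = tl.segment_epochs(bundle.trials, session_end=bundle.duration)
        rng = np.random.default_rng(0)
        results, amps = [], {}
        for uid in ("a", "b", "c"):
            res = tl.modality_significance(
                bundle.unit(uid), series, windows, bundle.trials, rng=rng
            )
            results.append(res)
            sp = tl.spike_phases(series, bundle.unit(uid))
            modality = dict(zip(bundle.trials.trial_id, bundle.trials.modality))
            by_mod = {m: [] for m in tl.MODALITIES}
            for w in windows:
                if w.epoch != "discrimination":
                    continue
                mask = (sp.times >= w.t0) & (sp.times < w.t1)
                by_mod[modality[w.trial_id]].append(sp.amplitude[mask])
            amps[uid] = {m: np.concatenate(v) for m, v in by_mod.items() if v}
        out = tl.amplitude_controls(results, amps)
        assert out["n_units_amplitude_differs"] == 0

    def test_boosted_amplitude_detected(self):
        rng = np.random.default_rng(1)
        amps = {
            "u": {
                "T": rng.normal(80, 5, 200),
                "V": rng.normal(40, 5, 200),
                "M": rng.normal(40, 5, 200),
            }
        }
        out = tl.amplitude_controls([], amps)
        assert out["n_units_amplitude_differs"] == 1

    def test_amplitude_ppc_correlation_recovered(self):
        # units whose locking strength scales with their theta amplitude
        rng = np.random.default_rng(2)
        results = []
        for i in range(30):
            amp = rng.uniform(20, 100)
            ppc = 0.004 * amp + rng.normal(0, 0.02)
            stats = {
                m: tl.modality.ModalityStats(100, ppc, 0.01, True, True, amp)
                for m in tl.MODALITIES
            }
            results.append(tl.ModalityResult(f"u{i}", stats, "T_and_V", {}))
        out = tl.amplitude_controls(results)
        assert out["amplitude_ppc_correlation"]["T"]["r"] > 0.5
        assert out["amplitude_ppc_correlation"]["T"]["p"] < 0.01
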