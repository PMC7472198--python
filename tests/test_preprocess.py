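import numpy as np
import pytest
from scipy.stats import kurtosis

from braingp import (
    PreprocessConfig,
    SimSpec,
    kurtosis_exclude,
    make_ground_truth,
    notch_filter,
    preprocess,
    resample_to,
    simulate_dataset,
    simulate_patient,
    zscore_sessions,
)

from conftest import make_recording


def rms(v):
    return float(np.sqrt(np.mean(np.square(v))))


def sine_recording(freq, fs=500.0, T=20_000, n_elec=2):
    t = np.arange(T) / fs
    v = np.sin(2 * np.pi * freq * t)[:, None] * np.ones((1, n_elec))
    locs = np.column_stack([np.arange(n_elec) * 5.0, np.zeros(n_elec), np.zeros(n_elec)])
    return make_recording(v, locs, samplerate=fs)


class TestNotch:
    def test_line_noise_attenuated(self):
        rec = sine_recording(60.0)
        out = notch_filter(rec)
        ratio = rms(out.sessions[0].voltages) / rms(rec.sessions[0].voltages)
        assert ratio < 0.10
        # steady-state attenuation (away from filter edge transients) >= 20 dB
        mid = slice(2000, -2000)
        mid_ratio = rms(out.sessions[0].voltages[mid]) / rms(rec.sessions[0].voltages[mid])
        assert 20 * np.log10(1.0 / mid_ratio) >= 20.0

    def test_passband_untouched(self):
        rec = sine_recording(10.0)
        out = notch_filter(rec)
        assert rms(out.sessions[0].voltages) == pytest.approx(
            rms(rec.sessions[0].voltages), rel=0.01)

    def test_zero_signal(self):
        rec = make_recording(np.zeros((1000, 2)), np.zeros((2, 3)), samplerate=500.0)
        out = notch_filter(rec)
        assert np.abs(out.sessions[0].voltages).max() < 1e-12

    def test_low_samplerate_errors(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((100, 1)),
                             np.zeros((1, 3)), samplerate=100.0)
        with pytest.raises(ValueError, match="too low"):
            notch_filter(rec)

    def test_input_unchanged(self):
        rec = sine_recording(60.0, T=4000)
        before = rec.sessions[0].voltages.copy()
        notch_filter(rec)
        np.testing.assert_array_equal(rec.sessions[0].voltages, before)


class TestResample:
    def test_length_arithmetic(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((1000, 2)),
                             np.zeros((2, 3)), samplerate=500.0)
        out = resample_to(rec, 250.0)
        assert out.sessions[0].n_timepoints == 500
        assert out.samplerate == 250.0

    def test_sine_preserved(self):
        fs, T = 500.0, 5000
        t = np.arange(T) / fs
        rec = make_recording(np.sin(2 * np.pi * 5 * t)[:, None], np.zeros((1, 3)),
                             samplerate=fs)
        out = resample_to(rec, 250.0)
        t2 = np.arange(out.sessions[0].n_timepoints) / 250.0
        analytic = np.sin(2 * np.pi * 5 * t2)
        r = np.corrcoef(out.sessions[0].voltages[:, 0], analytic)[0, 1]
        assert r > 0.99

    def test_identity_and_upsample_error(self):
        rec = make_recording(np.random.default_rng(1).standard_normal((100, 1)),
                             np.zeros((1, 3)), samplerate=250.0)
        out = resample_to(rec, 250.0)
        np.testing.assert_array_equal(out.sessions[0].voltages, rec.sessions[0].voltages)
        with pytest.raises(ValueError, match="upsampling"):
            resample_to(rec, 500.0)


class TestKurtosisExclusion:
    def test_gaussian_retained_spiky_excluded(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((5000, 3))
        # 1% of samples replaced by +/- 20 sigma spikes on channel 2
        idx = rng.choice(5000, 50, replace=False)
        v[idx, 2] = 20.0 * rng.choice([-1.0, 1.0], 50)
        # moment-formula excess kurtosis of the contaminated channel
        x = v[:, 2] - v[:, 2].mean()
        moment_k = np.mean(x**4) / np.mean(x**2) ** 2 - 3.0
        assert moment_k > 10.0
        assert kurtosis(v[:, 2], fisher=True, bias=True) == pytest.approx(moment_k)
        rec = make_recording(v, np.arange(9, dtype=float).reshape(3, 3))
        kept, report = kurtosis_exclude([rec])
        assert kept[0].n_electrodes == 2
        assert kept[0].electrode_ids == ["e0", "e1"]
        excluded = report[report.excluded]
        assert list(excluded.electrode_id) == ["e2"]
        assert excluded.max_kurtosis.iloc[0] == pytest.approx(moment_k)

    def test_patient_with_one_survivor_dropped(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((2000, 2))
        idx = rng.choice(2000, 40, replace=False)
        v[idx, 1] = 25.0 * rng.choice([-1.0, 1.0], 40)
        rec = make_recording(v, np.zeros((2, 3)) + np.arange(2)[:, None])
        kept, report = kurtosis_exclude([rec])
        assert kept == []
        assert (report.excluded).all()
        assert set(report.excluded_reason) == {"kurtosis", "patient_too_few_electrodes"}

    def test_max_over_sessions(self):
        rng = np.random.default_rng(4)
        clean = rng.standard_normal((2000, 2))
        dirty = rng.standard_normal((2000, 2))
        idx = rng.choice(2000, 40, replace=False)
        dirty[idx, 0] = 25.0 * rng.choice([-1.0, 1.0], 40)
        rec = make_recording([clean, dirty], np.zeros((2, 3)) + np.arange(2)[:, None])
        kept, _ = kurtosis_exclude([rec])
        assert kept == []  # e0 spiky in one session -> dropped -> 1 survivor

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        v = rng.standard_t(df=3, size=(3000, 6))  # heavy tails, varied kurtosis
        rec = make_recording(v, rng.uniform(-10, 10, (6, 3)))
        n_excluded = []
        for thr in (2.0, 5.0, 10.0, 50.0):
            _, report = kurtosis_exclude([rec], PreprocessConfig(kurtosis_threshold=thr))
            n_excluded.append(int(report.excluded.sum()))
        assert n_excluded == sorted(n_excluded, reverse=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_contaminant_free_simulation_keeps_all(self, seed):
        gt = make_ground_truth(seed=seed)
        recs, _ = simulate_dataset(gt, SimSpec(seed=seed))
        kept, report = kurtosis_exclude(recs)
        assert len(kept) == len(recs)
        assert int(report.excluded.sum()) == 0

    def test_contaminated_channels_excluded(self):
        gt = make_ground_truth(seed=10)
        rec, manifest = simulate_patient(
            gt, SimSpec(contaminant_fraction=0.25, seed=10), patient_seed=10)
        kept, report = kurtosis_exclude([rec])
        flagged = {rec.electrode_ids[i] for i in manifest["contaminated_channels"]}
        assert flagged
        assert set(report[report.excluded_reason == "kurtosis"].electrode_id) == flagged


class TestZScore:
    def test_ramp(self):
        v = np.linspace(0.0, 10.0, 100)[:, None]
        out = zscore_sessions(make_recording(v, np.zeros((1, 3))))
        z = out.sessions[0].voltages[:, 0]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        rec = make_recording(rng.standard_normal((500, 2)), np.zeros((2, 3)))
        once = zscore_sessions(rec)
        twice = zscore_sessions(once)
        np.testing.assert_allclose(twice.sessions[0].voltages,
                                   once.sessions[0].voltages, atol=1e-12)

    def test_sessions_scaled_independently(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((100, 1)) * 1000.0
        b = rng.standard_normal((80, 1)) * 0.001
        out = zscore_sessions(make_recording([a, b], np.zeros((1, 3))))
        for ses in out.sessions:
            assert ses.voltages.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_named(self):
        v = np.ones((50, 2))
        v[:, 0] = np.random.default_rng(8).standard_normal(50)
        rec = make_recording(v, np.zeros((2, 3)) + np.arange(2)[:, None])
        with pytest.raises(ValueError, match="e1"):
            zscore_sessions(rec)


def test_full_pipeline_order_and_purity():
    gt = make_ground_truth(seed=20)
    recs, _ = simulate_dataset(
        gt, SimSpec(n_patients=3, n_timepoints=3000, samplerate=500.0,
                    contaminant_fraction=0.2, line_noise_amplitude=1.0, seed=20))
    before = [r.sessions[0].voltages.copy() for r in recs]
    result = preprocess(recs)
    for rec, b in zip(recs, before):
        np.testing.assert_array_equal(rec.sessions[0].voltages, b)  # pure
    for rec in result.recordings:
        assert rec.samplerate == 250.0
        for ses in rec.sessions:
            np.testing.assert_allclose(ses.voltages.mean(axis=0), 0.0, atol=1e-10)
            np.testing.assert_allclose(ses.voltages.std(axis=0, ddof=1), 1.0, atol=1e-10)
    assert int(result.exclusions.excluded.sum()) > 0
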