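"""Spike detection, PSTH/efficiency, antidromic criteria, cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cordmetrics import (
    ParameterError,
    Recording,
    SynthRecordingParams,
    bandpass_filter,
    build_response_table,
    caudal_responsiveness,
    check_constant_latency,
    check_frequency_following,
    classify_antidromic,
    cohort_summary,
    collision_test,
    conduction_velocity,
    detect_spikes,
    efficiency,
    gen_recording,
    is_time_locked,
    psth,
    spontaneous_spikes,
)

RATE = 20000.0


def _responses(latencies, n_stim, stim_freq=5.0, amplitude=100.0,
               start=1.0):
    """Response table with given latencies on the first len(latencies)
    stimuli; remaining stimuli unanswered."""
    rows = []
    for i in range(n_stim):
        t = start + i / stim_freq
        if i < len(latencies):
            rows.append({"stim_time": t, "stim_freq": stim_freq,
                         "responded": True, "latency_ms": latencies[i],
                         "amplitude": amplitude})
        else:
            rows.append({"stim_time": t, "stim_freq": stim_freq,
                         "responded": False, "latency_ms": np.nan,
                         "amplitude": np.nan})
    return pd.DataFrame(rows)


class TestFilter:
    def test_low_frequency_hum_attenuated(self):
        t = np.arange(int(RATE)) / RATE
        rec = Recording(signal=np.sin(2 * np.pi * 50 * t), rate=RATE)
        out = bandpass_filter(rec)
        gain = np.abs(np.fft.rfft(out.signal))[50] / np.abs(np.fft.rfft(rec.signal))[50]
        assert 20 * np.log10(gain) < -40

    def test_passband_tone_preserved(self):
        t = np.arange(int(RATE)) / RATE
        rec = Recording(signal=np.sin(2 * np.pi * 1000 * t), rate=RATE)
        out = bandpass_filter(rec)
        gain = np.abs(np.fft.rfft(out.signal))[1000] / np.abs(np.fft.rfft(rec.signal))[1000]
        assert 20 * np.log10(gain) > -3

    def test_zero_signal_stays_zero(self):
        rec = Recording(signal=np.zeros(4000), rate=RATE)
        assert np.allclose(bandpass_filter(rec).signal, 0.0)

    def test_rate_too_low(self):
        with pytest.raises(ParameterError):
            bandpass_filter(Recording(signal=np.zeros(100), rate=8000.0))


class TestDetection:
    def test_planted_spikes_recovered_exactly(self):
        p = SynthRecordingParams(noise_sd=0, latency_jitter_sd=0,
                                 response_prob=1.0, stim_blocks=((5.0, 20),))
        rec, truth, _ = gen_recording(p)
        spikes = detect_spikes(rec, baseline_window=(0.0, 0.9))
        assert spikes.spike_times.size == 20
        expected = rec.stim_times + p.unit_latency * 1e-3
        assert np.all(np.abs(spikes.spike_times - expected) <= 1.0 / RATE)
        assert np.allclose(spikes.amplitudes, p.spike_amplitude)

    def test_flat_zero_signal_no_spikes(self):
        rec = Recording(signal=np.zeros(20000), rate=RATE)
        assert detect_spikes(rec, (0.0, 0.5)).spike_times.size == 0

    def test_noise_false_positive_rate_near_gaussian_tail(self, rng):
        # mean+3SD threshold on white noise: crossing probability per
        # sample is the one-sided 3-sigma tail; refractory grouping can
        # only reduce the count
        n = 200000
        rec = Recording(signal=rng.normal(0, 10, n), rate=RATE)
        spikes = detect_spikes(rec, (0.0, n / RATE / 2))
        p_tail = 1 - stats.norm.cdf(3)
        expected_crossings = n * p_tail
        assert 0.1 * expected_crossings < spikes.spike_times.size < expected_crossings

    def test_baseline_with_stimuli_rejected(self):
        rec = Recording(signal=np.zeros(20000), rate=RATE,
                        stim_times=np.array([0.25]))
        with pytest.raises(ParameterError):
            detect_spikes(rec, (0.0, 0.5))


class TestResponseTable:
    def test_all_spikes_at_fixed_latency(self):
        p = SynthRecordingParams(noise_sd=0, latency_jitter_sd=0,
                                 response_prob=1.0, stim_blocks=((5.0, 15),))
        rec, _, _ = gen_recording(p)
        spikes = detect_spikes(rec, (0.0, 0.9))
        table = build_response_table(spikes, rec.stim_times, (0.5, 10.0))
        assert table["responded"].all()
        assert np.allclose(table["latency_ms"], 3.0, atol=0.05)

    def test_no_spikes_no_responses(self):
        rec = Recording(signal=np.zeros(40000), rate=RATE,
                        stim_times=np.array([1.0, 1.2]))
        spikes = detect_spikes(rec, (0.0, 0.5))
        table = build_response_table(spikes, rec.stim_times)
        assert not table["responded"].any()

    def test_detected_fraction_matches_truth(self):
        p = SynthRecordingParams(noise_sd=0, response_prob=0.5,
                                 stim_blocks=((10.0, 200),), seed=3)
        rec, truth, _ = gen_recording(p)
        spikes = detect_spikes(rec, (0.0, 0.9))
        table = build_response_table(spikes, rec.stim_times)
        assert table["responded"].sum() == truth["responded"].sum()

    def test_window_start_beyond_isi_rejected(self):
        spikes = detect_spikes(Recording(signal=np.zeros(40000), rate=RATE),
                               (0.0, 0.5))
        with pytest.raises(ParameterError):
            build_response_table(spikes, np.array([1.0, 1.002]),
                                 response_window_ms=(5.0, 10.0))


class TestPSTH:
    def test_single_bin_hundred_percent(self):
        stim = 1.0 + np.arange(20) / 5.0
        spikes = stim + 3.2e-3
        h = psth(spikes, stim, bin_ms=1.0, window_ms=(0.0, 10.0))
        bin3 = np.flatnonzero(h.edges_ms[:-1] == 3.0)[0]
        assert h.normalized[bin3] == 100.0
        assert h.counts.sum() == 20

    def test_partial_bin_percentage(self):
        stim = 1.0 + np.arange(20) / 5.0
        spikes = stim[:11] + 4.5e-3  # 11 responses of 20 stimuli
        h = psth(spikes, stim, window_ms=(0.0, 10.0))
        assert h.normalized.max() == pytest.approx(55.0)

    def test_normalization_bounded(self, rng):
        stim = 1.0 + np.arange(50) / 5.0
        spikes = stim + rng.uniform(0.001, 0.009, 50)
        h = psth(spikes, stim, window_ms=(0.0, 10.0))
        assert h.normalized.sum() <= 100.0 + 1e-9

    def test_zero_stimuli_rejected(self):
        with pytest.raises(ParameterError):
            psth(np.array([1.0]), np.array([]))


class TestEfficiency:
    def test_limits(self):
        assert efficiency(_responses([3.0] * 50, 50)) == 100.0
        assert efficiency(_responses([], 30)) == 0.0

    def test_equals_truth_fraction(self):
        p = SynthRecordingParams(noise_sd=0, response_prob=0.47,
                                 stim_blocks=((10.0, 1000),), seed=8)
        rec, truth, _ = gen_recording(p)
        spikes = detect_spikes(rec, (0.0, 0.9))
        table = build_response_table(spikes, rec.stim_times)
        assert efficiency(table) == 100.0 * truth["responded"].sum() / 1000


class TestCriteria:
    def test_constant_latency_flags(self, rng):
        assert check_constant_latency(_responses([3.0] * 20, 20)) is True
        jittered = 3.0 + rng.normal(0, 1.5, 40)
        assert check_constant_latency(_responses(list(jittered), 40)) is False
        assert check_constant_latency(_responses([3.0] * 4, 4)) is None

    def test_frequency_following_flags(self):
        high = _responses([3.0] * 30, 30, stim_freq=200.0)
        assert check_frequency_following(high) is True
        sparse = _responses([3.0] * 12, 30, stim_freq=200.0)
        assert check_frequency_following(sparse) is False
        low_only = _responses([3.0] * 30, 30, stim_freq=5.0)
        assert check_frequency_following(low_only) is None

    def _collision_setup(self, blocking, spont, seed):
        p = SynthRecordingParams(seed=seed, stim_blocks=((5.0, 60),),
                                 noise_sd=0, latency_jitter_sd=0,
                                 response_prob=1.0, collision_blocking=blocking)
        rec0, _, _ = gen_recording(p)
        colliders = tuple((rec0.stim_times[::5] - 0.5e-3).tolist()) if spont else None
        p = SynthRecordingParams(**{**p.__dict__, "spont_times": colliders})
        rec, truth, _ = gen_recording(p)
        spikes = detect_spikes(rec, (0.0, 0.9))
        table = build_response_table(spikes, rec.stim_times)
        spont_det = spontaneous_spikes(spikes, rec.stim_times)
        return table, spont_det

    def test_collision_triad(self):
        table, spont = self._collision_setup(True, True, 0)
        assert collision_test(table, spont, 3.0) is True
        table, spont = self._collision_setup(False, True, 0)
        assert collision_test(table, spont, 3.0) is False
        table, spont = self._collision_setup(True, False, 0)
        assert collision_test(table, spont, 3.0) is None


class TestClassification:
    def test_two_of_three_with_indeterminate(self):
        resp = _responses([3.0] * 20, 20)
        v = classify_antidromic(True, True, None, resp)
        assert v.classification == "antidromic" and v.n_criteria_met == 2

    def test_responsive_failing_criteria_is_synaptic(self):
        resp = _responses([7.5] * 15, 30)
        v = classify_antidromic(False, False, False, resp)
        assert v.classification == "synaptic"

    def test_no_responses_is_unresponsive(self):
        v = classify_antidromic(None, None, None, _responses([], 20))
        assert v.classification == "unresponsive"

    def test_scattered_chance_responses_not_time_locked(self, rng):
        lat = list(rng.uniform(0.5, 10.0, 25))
        assert not is_time_locked(_responses(lat, 100))

    def test_concentrated_responses_time_locked(self):
        assert is_time_locked(_responses([6.9, 7.1, 7.0, 7.2, 6.8] * 4, 40))


class TestCaudalResponsiveness:
    def _hist(self, pre_counts, post_counts):
        pre = len(pre_counts)
        edges = np.arange(-pre, len(post_counts) + 1, dtype=float)
        counts = np.array(pre_counts + post_counts)
        n = 50
        from cordmetrics.ephys import PSTH
        return PSTH(edges_ms=edges, counts=counts,
                    normalized=counts / n * 100, n_stimuli=n, bin_ms=1.0,
                    window_ms=(-pre, len(post_counts)))

    def test_flat_pre_large_post(self):
        h = self._hist([2, 2, 2, 2, 2], [2, 30, 2])
        assert caudal_responsiveness(h) is True

    def test_empty_post_false(self):
        h = self._hist([2, 2, 2, 2], [0, 0, 0])
        assert caudal_responsiveness(h) is False

    def test_no_pre_bins_rejected(self):
        h = self._hist([], [1, 2])
        with pytest.raises(ParameterError):
            caudal_responsiveness(h)

    def test_null_false_positive_rate_measured(self, rng):
        # rate-matched Poisson pre/post: the any-bin mean+SD rule is a
        # weak criterion; measure its null rate and check the bound a
        # strong locked response always passes
        fp = 0
        trials = 200
        for _ in range(trials):
            pre = rng.poisson(3.0, 20)
            post = rng.poisson(3.0, 5)
            h = self._hist(list(pre), list(post))
            fp += caudal_responsiveness(h)
        assert fp / trials < 0.8
        strong = self._hist(list(rng.poisson(3.0, 20)), [45])
        assert caudal_responsiveness(strong) is True


class TestConduction:
    @pytest.mark.parametrize("d,lat,v", [(1.0, 1.0, 1.0),
                                         (57.3, 3.0, 19.1),
                                         (57.0, 2.0, 28.5)])
    def test_velocity_arithmetic(self, d, lat, v):
        assert conduction_velocity(d, lat) == pytest.approx(v)

    def test_latency_velocity_roundtrip(self):
        d, v = 57.3, 19.1
        lat = d / v
        assert conduction_velocity(d, lat) == pytest.approx(v, rel=1e-15)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            conduction_velocity(0.0, 1.0)
        with pytest.raises(ParameterError):
            conduction_velocity(1.0, -2.0)


class TestCohort:
    def _table(self):
        rows = []
        units = [5] + [4] * 10          # 45 units over 11 implanted animals
        for i, u in enumerate(units):
            rows.append({"animal": f"rgo{i}", "group": "SCI+rGO",
                         "n_insertions": 4, "n_antidromic_units": u,
                         "caudal_respondent": i < 3})
        for i in range(4):              # 20 units over 4 SCI animals
            rows.append({"animal": f"sci{i}", "group": "SCI",
                         "n_insertions": 4, "n_antidromic_units": 5,
                         "caudal_respondent": False})
        return pd.DataFrame(rows)

    def test_group_means_and_respondents(self):
        summary = cohort_summary(self._table()).set_index("group")
        assert summary.loc["SCI+rGO", "mean_units_per_animal"] == pytest.approx(45 / 11)
        assert round(summary.loc["SCI+rGO", "mean_units_per_animal"], 1) == 4.1
        assert summary.loc["SCI", "mean_units_per_animal"] == 5.0
        assert summary.loc["SCI+rGO", "pct_caudal_respondent"] == pytest.approx(300 / 11)
        assert summary["total_units"].sum() == 65

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            cohort_summary(pd.DataFrame(columns=["animal", "group",
                                                 "n_antidromic_units",
                                                 "caudal_respondent"]))

    def test_negative_counts_rejected(self):
        t = self._table()
        t.loc[0, "n_antidromic_units"] = -1
        with pytest.raises(ParameterError):
            cohort_summary(t)
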