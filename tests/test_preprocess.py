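"""Preprocessing chain: filtering, resampling, channel QC, common
average reference, epoching, artifact rejection and band power."""

import numpy as np
import pandas as pd
import pytest

import ecogface as ef
from ecogface import preprocess as pp
from ecogface.containers import ElectrodeLayout, Epochs, RawRecording, TaskDesign


def _layout(n):
    return ElectrodeLayout(
        table=pd.DataFrame(
            {
                "name": [f"e{i}" for i in range(n)],
                "x": 30.0,
                "y": np.linspace(-60, -30, n),
                "z": -15.0,
                "hemisphere": "r",
            }
        )
    )


def _raw(signal, fs=1000.0):
    return RawRecording(signal=np.asarray(signal, float), fs=fs, layout=_layout(len(signal)))


def _design(onsets, category="human_face"):
    return TaskDesign(
        events=pd.DataFrame(
            {"onset": onsets, "duration": 0.3, "trial_type": category}
        ),
        images_per_category=1,
        presentations_per_image=len(onsets),
    )


class TestNotch:
    def test_zero_signal_stays_zero(self):
        raw = _raw(np.zeros((2, 4000)))
        out = pp.notch_filter(raw)
        np.testing.assert_allclose(out.signal, 0.0)

    def test_60hz_attenuated_below_5_percent(self):
        t = np.arange(8000) / 1000.0
        raw = _raw([np.sin(2 * np.pi * 60 * t)])
        out = pp.notch_filter(raw)
        mid = slice(1000, 7000)  # avoid filter edges
        assert np.std(out.signal[0][mid]) < 0.05 * np.std(raw.signal[0][mid])

    def test_10hz_passband_preserved_within_1_percent(self):
        t = np.arange(8000) / 1000.0
        raw = _raw([np.sin(2 * np.pi * 10 * t)])
        out = pp.notch_filter(raw)
        mid = slice(1000, 7000)
        ratio = np.std(out.signal[0][mid]) / np.std(raw.signal[0][mid])
        assert abs(ratio - 1.0) < 0.01

    def test_stopband_above_nyquist_rejected(self):
        raw = _raw(np.zeros((1, 1000)), fs=300.0)
        with pytest.raises(ValueError):
            pp.notch_filter(raw)  # 177-183 Hz above 150 Hz Nyquist


class TestResample:
    def test_same_rate_is_identity(self):
        raw = _raw(np.random.default_rng(0).standard_normal((2, 1000)))
        out = pp.resample(raw, 1000.0)
        np.testing.assert_array_equal(out.signal, raw.signal)

    def test_clinical_rate_to_1khz_preserves_duration(self):
        fs0 = 1525.88
        n = int(round(10 * fs0))
        raw = _raw(np.random.default_rng(1).standard_normal((1, n)), fs=fs0)
        out = pp.resample(raw, 1000.0)
        assert abs(out.n_samples - 10_000) <= 1

    def test_sinusoid_matches_analytic_reference(self):
        fs0 = 2000.0
        t0 = np.arange(int(4 * fs0)) / fs0
        raw = _raw([np.sin(2 * np.pi * 5 * t0)], fs=fs0)
        out = pp.resample(raw, 1000.0)
        t1 = np.arange(out.n_samples) / 1000.0
        ref = np.sin(2 * np.pi * 5 * t1)
        mid = slice(200, -200)
        r = np.corrcoef(out.signal[0][mid], ref[mid])[0, 1]
        assert r > 0.999

    def test_upsampling_refused(self):
        raw = _raw(np.zeros((1, 100)), fs=500.0)
        with pytest.raises(ValueError):
            pp.resample(raw, 1000.0)


class TestChannelQC:
    def test_identical_channels_none_rejected(self):
        x = np.random.default_rng(0).standard_normal(5000)
        raw = _raw(np.tile(x, (4, 1)))
        qc = pp.detect_bad_channels(raw)
        assert not qc.table["rejected"].any()

    def test_high_variance_channel_rejected(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal((20, 5000))
        sig[2] *= 3.0  # variance x9; across-channel mean ~1.4, rule 5x
        qc = pp.detect_bad_channels(_raw(sig))
        row = qc.table.iloc[2]
        assert row["rejected"] and row["reason"] == "variance_high"
        assert not qc.table.drop(index=2)["rejected"].any()

    def test_spiky_channel_rejected_by_jump_rule(self):
        rng = np.random.default_rng(2)
        sig = 5.0 * rng.standard_normal((5, 5000))
        # steps >100 uV; a baseline jump count on every channel keeps the
        # spiky channel's variance near its peers
        for ch in range(5):
            sig[ch, 100:110] += 150.0
        for k in range(8):
            sig[0, 500 + 400 * k : 520 + 400 * k] += 150.0
        jumps = (np.abs(np.diff(sig, axis=1)) > 100).sum(axis=1)
        assert jumps[0] > 3 * jumps.mean()  # construction sanity
        qc = pp.detect_bad_channels(_raw(sig))
        assert qc.table.iloc[0]["rejected"]
        assert qc.table.iloc[0]["reason"] == "spiky"

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            pp.detect_bad_channels(_raw(np.zeros((1, 100))))


class TestCommonAverage:
    def test_two_channel_hand_arithmetic(self):
        raw = _raw([[1.0, 2.0], [3.0, 4.0]])
        out = pp.rereference_common_average(raw, raw.channel_names)
        np.testing.assert_allclose(out.signal, [[-1.0, -1.0], [1.0, 1.0]])

    def test_mean_over_good_channels_is_zero(self, rng):
        raw = _raw(rng.standard_normal((6, 2000)))
        out = pp.rereference_common_average(raw, raw.channel_names[:5])
        np.testing.assert_allclose(out.signal[:5].mean(axis=0), 0.0, atol=1e-12)

    def test_bad_channel_does_not_influence_good_outputs(self, rng):
        sig = rng.standard_normal((5, 1000))
        good = [f"e{i}" for i in range(4)]
        out1 = pp.rereference_common_average(_raw(sig), good)
        sig2 = sig.copy()
        sig2[4] += 500.0  # perturb the excluded channel
        out2 = pp.rereference_common_average(_raw(sig2), good)
        np.testing.assert_array_equal(out1.signal[:4], out2.signal[:4])

    def test_no_good_channels_rejected(self):
        with pytest.raises(ValueError):
            pp.rereference_common_average(_raw(np.zeros((2, 10))), [])


class TestEpoching:
    def test_constant_channel_zero_after_baseline_correction(self):
        raw = _raw(np.full((2, 5000), 7.0))
        ep = pp.epoch_and_baseline(raw, _design([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-12)

    def test_900ms_window_gives_900_samples_at_1khz(self):
        raw = _raw(np.zeros((1, 5000)))
        ep = pp.epoch_and_baseline(raw, _design([1.0, 2.0]))
        assert ep.data.shape[-1] == 900
        assert ep.times[0] == -200.0 and ep.times[-1] == 699.0

    def test_injected_pulse_lands_at_its_latency(self):
        sig = np.zeros((1, 5000))
        onset_s, latency_ms = 2.0, 100
        sig[0, int(onset_s * 1000) + latency_ms] = 50.0
        ep = pp.epoch_and_baseline(_raw(sig), _design([onset_s]))
        peak_time = ep.times[np.argmax(ep.data[0, 0])]
        assert peak_time == pytest.approx(latency_ms)

    def test_edge_events_dropped(self):
        raw = _raw(np.zeros((1, 1500)))
        ep = pp.epoch_and_baseline(raw, _design([0.1, 0.5]))  # first starts pre-recording
        assert ep.n_trials == 1


class TestArtifactRejection:
    def test_quiet_epochs_unflagged(self, rng):
        ep = Epochs(
            data=40.0 * rng.uniform(-1, 1, (8, 2, 100)),
            times=np.arange(100.0),
            categories=np.repeat("objects", 8),
            channel_names=["a", "b"],
            fs=1000.0,
        )
        out = pp.reject_artifact_epochs(ep)
        assert not out.artifact.any()

    def test_single_spiking_epoch_flagged(self, rng):
        data = 10.0 * rng.standard_normal((6, 2, 100))
        data[3, 1, 50] = 150.0
        ep = Epochs(
            data=data,
            times=np.arange(100.0),
            categories=np.repeat("objects", 6),
            channel_names=["a", "b"],
            fs=1000.0,
        )
        out = pp.reject_artifact_epochs(ep)
        assert list(np.flatnonzero(out.artifact)) == [3]

    def test_survivor_count_matches_brute_force(self, rng):
        data = 60.0 * rng.standard_normal((40, 3, 80))
        ep = Epochs(
            data=data,
            times=np.arange(80.0),
            categories=np.repeat("places", 40),
            channel_names=list("abc"),
            fs=1000.0,
        )
        out = pp.reject_artifact_epochs(ep, 100.0)
        brute = sum(1 for tr in data if not (np.abs(tr) > 100.0).any())
        assert int((~out.artifact).sum()) == brute

    def test_nonpositive_threshold_rejected(self, rng):
        ep = Epochs(
            data=rng.standard_normal((2, 1, 10)),
            times=np.arange(10.0),
            categories=np.repeat("places", 2),
            channel_names=["a"],
            fs=1000.0,
        )
        with pytest.raises(ValueError):
            pp.reject_artifact_epochs(ep, 0.0)


def _carrier_epochs(amp_post_over_pre=2.0, freq=100.0, n_trials=6):
    """Epochs holding a pure in-band carrier whose amplitude changes at
    +300 ms by a known factor (away from the baseline window, so the
    rescaling is uncontaminated by wavelet smearing)."""
    times = np.arange(-200.0, 700.0)
    t = times / 1000.0
    carrier = np.sin(2 * np.pi * freq * t)
    trial = np.where(times < 300.0, carrier, amp_post_over_pre * carrier)
    data = np.tile(trial, (n_trials, 1, 1))
    return Epochs(
        data=data,
        times=times,
        categories=np.repeat("objects", n_trials),
        channel_names=["a"],
        fs=1000.0,
    )


class TestBandPower:
    def test_baseline_window_mean_is_zero_db(self, rng):
        ep = Epochs(
            data=rng.standard_normal((5, 2, 900)),
            times=np.arange(-200.0, 700.0),
            categories=np.repeat("objects", 5),
            channel_names=["a", "b"],
            fs=1000.0,
        )
        bp = pp.band_power(ep, pp.STANDARD_BANDS["HFB"], smooth_ms=0.0)
        base = bp.data[:, :, bp.time_mask((-100.0, 0.0))].mean(axis=2)
        np.testing.assert_allclose(base, 0.0, atol=1e-9)

    def test_amplitude_doubling_gives_six_db_plateau(self):
        ep = _carrier_epochs(amp_post_over_pre=2.0)
        bp = pp.band_power(ep, pp.STANDARD_BANDS["HFB"])
        pre = bp.data[:, :, bp.time_mask((50.0, 250.0))].mean()
        post = bp.data[:, :, bp.time_mask((400.0, 600.0))].mean()
        assert post - pre == pytest.approx(10 * np.log10(4.0), abs=0.1)

    def test_hfb_frequency_list_avoids_notch_stopbands(self):
        freqs = pp.STANDARD_BANDS["HFB"].freqs
        # 177 itself sits in the third-harmonic stopband, so the last
        # analysable bin is 176 Hz
        assert freqs[0] == 70 and freqs[-1] == 176
        assert not np.any((freqs >= 117) & (freqs <= 123))
        assert not np.any(freqs >= 177)
        assert pp.STANDARD_BANDS["HFB"].n_cycles == 7
        assert pp.STANDARD_BANDS["gamma"].n_cycles == 5

    def test_band_inside_excluded_frequencies_rejected(self):
        dead = pp.BandSpec("dead", 118, 122)
        ep = _carrier_epochs()
        with pytest.raises(ValueError):
            pp.band_power(ep, dead)


class TestPipelineOrder:
    def test_full_chain_deterministic(self, raw_scenario):
        bp1 = raw_scenario["bp"]
        bp2, _, _ = ef.preprocess_raw(raw_scenario["raw"], raw_scenario["design"])
        np.testing.assert_array_equal(bp1.data, bp2.data)

    def test_swapping_qc_and_rereference_changes_outputs(self, rng):
        """Regression guard on stage order: re-referencing before QC
        alters the variance statistics and hence the signal."""
        sig = rng.standard_normal((12, 4000))
        sig[0] *= 4.0  # one bad channel
        raw = _raw(sig)
        qc = pp.detect_bad_channels(raw)
        assert qc.bad_channels  # construction sanity
        correct = pp.rereference_common_average(raw, qc.good_channels)
        swapped_input = pp.rereference_common_average(raw, raw.channel_names)
        assert not np.allclose(correct.signal, swapped_input.signal)
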