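"""Referencing, zero-phase filtering, and epileptiform-trial rejection."""

import numpy as np
import pytest
from scipy import signal as spsig

from corticalstate import (
    HIGH_BAND,
    LOW_BAND,
    bandpass,
    common_average_reference,
    design_filter,
    detect_spiking_trials,
    generate_session,
    inject_artifacts,
    remove_line_noise,
    zscore_channels,
)

FS = 1000.0


def rms(x):
    return float(np.sqrt(np.mean(np.asarray(x, float) ** 2)))


class TestCommonAverageReference:
    def test_identical_channels_cancel(self, make_session):
        trace = np.random.default_rng(0).standard_normal(1500)
        sess = make_session(np.tile(trace, (3, 4, 1)))
        out = common_average_reference(sess)
        assert np.allclose(out.voltages, 0.0, atol=1e-4)

    def test_symmetric_pair_unchanged(self, make_session):
        x = np.random.default_rng(1).standard_normal((2, 1, 1500))
        sess = make_session(np.concatenate([x, -x], axis=1))
        out = common_average_reference(sess)
        assert np.allclose(out.voltages, sess.voltages, atol=1e-4)

    def test_referenced_mean_is_zero(self, make_session):
        sess = make_session(np.random.default_rng(2).standard_normal((4, 5, 1500)))
        out = common_average_reference(sess)
        assert np.abs(out.voltages.mean(axis=1)).max() < 1e-4

    def test_requires_two_nonictal(self, make_session):
        sess = make_session(np.zeros((2, 3, 1500)))
        with pytest.raises(ValueError):
            common_average_reference(sess, nonictal_ids=[0])


class TestLineNoiseRemoval:
    # the notch rings for ~2 s (0.6 Hz-wide stopband), so steady-state
    # attenuation is measured well inside a longer record
    t = np.arange(8001) / FS  # ends on a 60 Hz zero crossing
    core = slice(3000, 5000)

    def test_60hz_attenuated_60db(self):
        x = np.sin(2 * np.pi * 60 * self.t)
        y = remove_line_noise(x[None, :], FS)[0]
        assert rms(y[self.core]) <= 1e-3 * rms(x)

    def test_10hz_passes(self):
        x = np.sin(2 * np.pi * 10 * self.t)
        y = remove_line_noise(x[None, :], FS)[0]
        assert rms(y[self.core]) == pytest.approx(rms(x[self.core]), rel=0.01)

    def test_mixture_decomposition(self):
        ten = np.sin(2 * np.pi * 10 * self.t)
        sixty = 0.7 * np.sin(2 * np.pi * 60 * self.t + 0.5)
        y = remove_line_noise((ten + sixty)[None, :], FS)[0]
        # output approximates the 10 Hz component alone
        resid = y[self.core] - ten[self.core]
        assert rms(resid) < 0.01 * rms(ten)

    @pytest.mark.parametrize("f", [50.0, 70.0])
    def test_neighbors_attenuated_below_3db(self, f):
        x = np.sin(2 * np.pi * f * self.t)
        y = remove_line_noise(x[None, :], FS)[0]
        assert rms(y[self.core]) > 10 ** (-3 / 20) * rms(x[self.core])


class TestBandpass:
    t = np.arange(3000) / FS

    def test_zero_phase_symmetric_pulse(self):
        n = 3001
        pulse = np.maximum(0, 1 - np.abs(np.arange(n) - n // 2) / 100.0)
        y = bandpass(pulse[None, :], FS, *LOW_BAND)[0]
        # symmetric input -> symmetric output about the same center
        assert np.allclose(y, y[::-1], atol=1e-6 * np.abs(y).max() + 1e-12)

    def test_8hz_in_low_band_passes_within_5pct(self):
        x = np.sin(2 * np.pi * 8 * self.t)
        y = bandpass(x[None, :], FS, *LOW_BAND)[0]
        assert rms(y[1000:2000]) == pytest.approx(rms(x[1000:2000]), rel=0.05)

    def test_8hz_in_high_band_stopped_60db(self):
        x = np.sin(2 * np.pi * 8 * self.t)
        y = bandpass(x[None, :], FS, *HIGH_BAND)[0]
        assert rms(y[1000:2000]) <= 1e-3 * rms(x)

    def test_white_noise_out_of_band_rejection(self):
        x = np.random.default_rng(3).standard_normal(60000)
        y = bandpass(x[None, :], FS, *LOW_BAND)[0]
        f, p = spsig.welch(y, FS, nperseg=4096)
        inband = p[(f > 4) & (f < 10)].mean()
        outband = p[(f > 20) & (f < 450)].mean()
        assert inband / outband >= 1e6  # >= 60 dB per pass, doubled zero-phase

    def test_zero_phase_cross_correlation_lag(self):
        x = np.random.default_rng(4).standard_normal(8000)
        xb = bandpass(x[None, :], FS, 4.0, 20.0)[0]
        y = bandpass(xb[None, :], FS, *LOW_BAND)[0]
        lags = spsig.correlation_lags(len(xb), len(y))
        xc = spsig.correlate(xb - xb.mean(), y - y.mean())
        assert lags[np.argmax(xc)] == 0

    def test_relaxed_design_is_reported(self):
        design_filter.cache_clear()
        with pytest.warns(RuntimeWarning, match="impractical"):
            spec = design_filter("bandpass", HIGH_BAND, FS)
        assert spec.relaxed
        assert spec.cutoffs == (HIGH_BAND[0] - 0.3, HIGH_BAND[1] + 0.3)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            design_filter("bandpass", (12.0, 2.5), FS)


class TestSpikingDetection:
    def test_all_zero_signal_rejects_nothing(self, make_session):
        sess = make_session(np.zeros((5, 2, 1500)))
        report = detect_spiking_trials(sess, "detection")
        assert report.rejected.sum() == 0
        assert np.all(report.threshold == 0)

    def test_single_burst_trial_detected_and_matches_brute_force(self, make_session):
        rng = np.random.default_rng(5)
        v = rng.standard_normal((100, 1, 1500))
        v[17, 0, 200:350] = 20.0 * np.sign(rng.standard_normal(150))  # 10% of samples
        sess = make_session(v)
        report = detect_spiking_trials(sess, "detection")
        # independent brute-force count
        absv = np.abs(v[:, 0, :])
        th = absv.mean() + 3 * absv.std()
        expected = {t for t in range(100) if (absv[t] > th).mean() >= 0.05}
        assert expected == {17}
        assert set(report.rejected_trials(0)) == expected

    def test_rejection_invariant_to_trial_order(self, make_session):
        rng = np.random.default_rng(6)
        v = rng.standard_normal((60, 2, 1500))
        v[5, :, :300] += 15.0
        perm = rng.permutation(60)
        r1 = detect_spiking_trials(make_session(v), "detection")
        r2 = detect_spiking_trials(make_session(v[perm]), "detection")
        assert np.array_equal(r1.rejected[perm], r2.rejected)

    def test_injected_artifacts_match_ground_truth(self, tame_config):
        sess = inject_artifacts(
            generate_session(tame_config),
            rate=0.3,
            amplitude_factor=6.0,
            duration_frac=0.2,
            seed=3,
        )
        report = detect_spiking_trials(sess, "detection")
        flagged = np.flatnonzero(sess.ground_truth["artifact"])
        for e in range(sess.n_electrodes):
            assert set(report.rejected_trials(e)) == set(flagged)

    def test_electrode_excluded_below_min_trials(self, make_session):
        # 35 of 80 trials carry constant-amplitude spikes on 10% of samples;
        # the contaminated threshold stays well below the spike level, so
        # exactly those trials reject and 45 < 50 survive
        rng = np.random.default_rng(40)
        v = rng.standard_normal((80, 2, 1500))
        v[:35, :, 150:300] = 50.0
        report = detect_spiking_trials(
            make_session(v), "detection", min_trials=50
        )
        assert np.all(report.n_surviving == 45)
        assert report.electrode_excluded.all()


class TestZScore:
    def test_normalizes_mean_and_sd(self, make_session):
        v = 2.0 * np.random.default_rng(7).standard_normal((6, 3, 1500)) + 5.0
        out = zscore_channels(make_session(v))
        assert np.abs(out.voltages.mean(axis=(0, 2))).max() < 1e-5
        assert np.abs(out.voltages.std(axis=(0, 2)) - 1).max() < 1e-5

    def test_idempotent(self, make_session):
        v = np.random.default_rng(8).standard_normal((4, 2, 1500))
        once = zscore_channels(make_session(v))
        twice = zscore_channels(once)
        assert np.allclose(once.voltages, twice.voltages, atol=1e-5)

    def test_zero_variance_channel_flagged(self, make_session):
        v = np.random.default_rng(9).standard_normal((4, 2, 1500))
        v[:, 1, :] = 3.0
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_channels(make_session(v))
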