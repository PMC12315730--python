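import numpy as np
import pytest
from scipy import signal

from smrloop import (EegGenConfig, LaplacianSpec, OnlineConfig, Recording,
                     TrialSchedule, apply_laplacian, band_power, calibrate,
                     causal_filter, erd_score, generate_eeg,
                     run_online_session, sham_replay, sliding_psd)
from smrloop.online import _design_sos

SR = 1000.0


def _rec(data, labels=None):
    data = np.atleast_2d(data)
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data, SR, labels)


LAP = LaplacianSpec("C3", ("a", "b", "c", "d", "e", "f"))


class TestLaplacian:
    def test_common_mode_cancellation(self):
        x = np.random.default_rng(0).normal(size=300)
        rec = _rec(np.tile(x, (7, 1)), ["C3", *LAP.neighbors])
        out = apply_laplacian(rec, LAP)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_identity_when_neighbors_silent(self):
        s = np.sin(np.arange(500) / 30.0)
        data = np.vstack([s, np.zeros((6, 500))])
        out = apply_laplacian(_rec(data, ["C3", *LAP.neighbors]), LAP)
        np.testing.assert_allclose(out.data[0], s)

    def test_shared_component_removed(self):
        rng = np.random.default_rng(1)
        s, c = rng.normal(size=400), rng.normal(size=400)
        data = np.vstack([s + c] + [c] * 6)
        out = apply_laplacian(_rec(data, ["C3", *LAP.neighbors]), LAP)
        np.testing.assert_allclose(out.data[0], s, atol=1e-12)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(7, 200))
        rec = _rec(data, ["C3", *LAP.neighbors])
        shifted = _rec(data + 17.3, ["C3", *LAP.neighbors])
        np.testing.assert_allclose(apply_laplacian(rec, LAP).data,
                                   apply_laplacian(shifted, LAP).data,
                                   atol=1e-10)

    def test_errors(self):
        rec = _rec(np.zeros((2, 10)), ["C3", "a"])
        with pytest.raises(KeyError):
            apply_laplacian(rec, LAP)
        with pytest.raises(ValueError, match="duplicate"):
            LaplacianSpec("C3", ("a", "a", "b", "c", "d", "e"))


class TestCausalFilter:
    def setup_method(self):
        self.cfg = OnlineConfig()
        self.t = np.arange(int(5 * SR)) / SR

    def _steady_gain(self, freq):
        x = np.sin(2 * np.pi * freq * self.t)
        out = causal_filter(_rec(x), self.cfg).data[0]
        tail = out[int(2 * SR):]        # past the transient
        return np.abs(signal.hilbert(tail))[200:-200].mean()

    def test_notch_attenuates_50hz(self):
        sos = _design_sos(self.cfg, SR)
        w, h = signal.sosfreqz(sos, worN=[50.0], fs=SR)
        assert 20 * np.log10(np.abs(h[0])) < -20
        assert self._steady_gain(50.0) < 0.1

    def test_passband_10hz_within_1db(self):
        sos = _design_sos(self.cfg, SR)
        w, h = signal.sosfreqz(sos, worN=[10.0], fs=SR)
        assert abs(20 * np.log10(np.abs(h[0]))) < 1.0
        assert abs(20 * np.log10(self._steady_gain(10.0))) < 1.0

    def test_zero_in_zero_out(self):
        out = causal_filter(_rec(np.zeros(1000)), self.cfg)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_causality(self):
        """Truncating the input does not change earlier outputs."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=3000)
        full = causal_filter(_rec(x), self.cfg).data[0]
        cut = causal_filter(_rec(x[:2000]), self.cfg).data[0]
        np.testing.assert_allclose(full[:2000], cut, atol=1e-10)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            causal_filter(_rec(np.zeros(1000)), OnlineConfig(bandpass=(1, 600)))


class TestSlidingPsd:
    def test_matches_direct_dft(self):
        """Each PSD column equals the DFT of the identically tapered window."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=3000)
        cfg = OnlineConfig()
        est = sliding_psd(_rec(x), cfg)
        taper = signal.windows.hann(1000, sym=False)
        scale = 2.0 / (SR * np.sum(taper ** 2))
        for k in [0, 7, est.values.shape[0] - 1]:
            seg = x[k * 100:k * 100 + 1000] * taper
            ref = np.abs(np.fft.rfft(seg)) ** 2 * scale
            ref[0] /= 2.0
            ref[-1] /= 2.0
            err = np.abs(est.values[k] - ref) / (ref.max())
            assert err.max() < 1e-10

    def test_sinusoid_peak_and_parseval(self):
        t = np.arange(2000) / SR
        x = np.sin(2 * np.pi * 10 * t)
        cfg = OnlineConfig()
        est = sliding_psd(_rec(x), cfg)
        assert est.freqs[np.argmax(est.values[5])] == 10.0
        # Parseval (window-compensated): PSD integrates to the signal power
        total = est.values[5].sum() * 1.0      # df = 1 Hz
        assert total == pytest.approx(0.5, rel=1e-6)
        # and each column matches scipy's Hann periodogram of that window
        f_sp, p_sp = signal.periodogram(x[500:1500], fs=SR, window="hann")
        np.testing.assert_allclose(est.values[5], p_sp, rtol=1e-9, atol=1e-12)

    def test_zero_signal(self):
        est = sliding_psd(_rec(np.zeros(1500)), OnlineConfig())
        np.testing.assert_array_equal(est.values, 0.0)

    def test_window_times_trailing(self):
        est = sliding_psd(_rec(np.zeros(1500)), OnlineConfig())
        assert est.times[0] == pytest.approx(0.999)
        assert np.allclose(np.diff(est.times), 0.1)

    def test_too_short(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_psd(_rec(np.zeros(500)), OnlineConfig())


class TestErdScore:
    def test_formula_identities(self):
        assert erd_score(10.0, 10.0)[1] == 0.0
        assert erd_score(0.0, 10.0)[1] == 100.0
        clipped, raw = erd_score(15.0, 10.0)
        assert raw == -50.0 and clipped == 0.0

    def test_clip_is_median(self, rng):
        A = rng.uniform(0, 30, size=200)
        clipped, raw = erd_score(A, 10.0)
        expected = np.median(np.vstack([np.zeros_like(raw), raw,
                                        np.full_like(raw, 100.0)]), axis=0)
        np.testing.assert_allclose(clipped, expected)

    def test_nonpositive_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            erd_score(1.0, 0.0)


class TestOnlineSession:
    def test_determinism(self, eeg_block, schedule10):
        calib = calibrate(eeg_block, schedule10)
        a = run_online_session(eeg_block, calib, schedule10)
        b = run_online_session(eeg_block, calib, schedule10)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.scores, sb.scores)

    def test_null_depth_scores_near_zero(self):
        sched = TrialSchedule.standard(10)
        raws = []
        for seed in range(5):
            rec = generate_eeg(EegGenConfig(erd_depth=0.0, seed=seed), sched)
            calib = calibrate(rec, sched)
            scores = run_online_session(rec, calib, sched)
            raws.append(np.mean([s.mean_raw_erd for s in scores]))
        assert abs(np.mean(raws)) < 2 * np.std(raws, ddof=1) + 2.0

    def test_depth_recovered_in_scores(self):
        sched = TrialSchedule.standard(10)
        means = []
        for seed in range(4):
            rec = generate_eeg(EegGenConfig(erd_depth=0.4, seed=seed), sched)
            calib = calibrate(rec, sched)
            scores = run_online_session(rec, calib, sched)
            means.append(np.mean([s.mean_raw_erd for s in scores]))
        assert abs(np.mean(means) - 40.0) < 5.0

    def test_agreement_with_offline_ersp(self, eeg_block, schedule10):
        """Online mean raw ERD and offline band ERSP agree in magnitude."""
        from smrloop import (block_summary, common_average_reference,
                             compute_ersp, preprocess_offline,
                             reject_bad_trials, segment_epochs)
        calib = calibrate(eeg_block, schedule10)
        online = run_online_session(eeg_block, calib, schedule10)
        online_mean = np.mean([s.mean_raw_erd for s in online])
        filt = preprocess_offline(eeg_block)
        epochs, _ = reject_bad_trials(segment_epochs(filt, schedule10))
        epochs = common_average_reference(epochs)
        maps = compute_ersp(epochs, "C3")
        ersp = float(block_summary(maps, calib.iaf_band)["ersp_iaf"].iloc[0])
        assert abs(-online_mean - ersp) < 5.0


class TestShamReplay:
    def test_pass_through(self, eeg_block, schedule10):
        calib = calibrate(eeg_block, schedule10)
        donor = run_online_session(eeg_block, calib, schedule10)
        replay = sham_replay(donor, schedule10)
        for d, r in zip(donor, replay):
            np.testing.assert_array_equal(d.scores, r.scores)

    def test_donor_too_short(self, eeg_block, schedule10):
        calib = calibrate(eeg_block, schedule10)
        donor = run_online_session(eeg_block, calib, schedule10)
        with pytest.raises(ValueError, match="empty"):
            sham_replay([], schedule10)
        with pytest.raises(ValueError, match="donor"):
            sham_replay(donor[:3], schedule10)

    def test_feedback_decoupled_from_recipient(self):
        """Sham feedback ignores the recipient's EEG entirely, so it cannot
        track the recipient's own trial-to-trial ERD."""
        sched = TrialSchedule.standard(20)
        donor_rec = generate_eeg(EegGenConfig(erd_depth=0.3, erd_depth_sd=0.15,
                                              seed=999), sched)
        calib = calibrate(donor_rec, sched)
        donor = run_online_session(donor_rec, calib, sched)
        replay = sham_replay(donor, sched)
        feedback = [s.mean_score for s in replay]
        # structural decoupling: any recipient gets the same feedback
        replay2 = sham_replay(donor, sched)
        np.testing.assert_array_equal(feedback,
                                      [s.mean_score for s in replay2])
        # statistical decoupling: correlation with independent recipients'
        # true per-trial ERD behaves like a null distribution
        rs = []
        for seed in range(20):
            recip = generate_eeg(EegGenConfig(erd_depth=0.9, erd_depth_sd=0.1,
                                              seed=seed), sched)
            rs.append(np.corrcoef(feedback, recip.meta["trial_depths"])[0, 1])
        assert abs(np.mean(rs)) < 0.2
        assert np.median(np.abs(rs)) < 0.3
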