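"""Pupil preprocessing chain: artifacts, interpolation, filtering, epochs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from pupilgain import preprocess as P


def make_rec(y, fs=500.0, valid=None):
    y = np.asarray(y, dtype=float)
    return P.PupilRecording(t=np.arange(y.size) / fs, y=y, fs=fs, valid=valid)


class TestDerivativeArtifacts:
    def test_constant_trace_clean(self):
        assert len(P.detect_derivative_artifacts(make_rec(np.full(1000, 5.0)))) == 0

    def test_single_step_flagged_once(self):
        fs = 100.0
        y = np.zeros(1001)
        y[int(5 * fs):] = 50.0
        ann = P.detect_derivative_artifacts(make_rec(y, fs), threshold=10.0)
        assert len(ann) == 1
        kind, a, b = ann.intervals[0]
        assert kind == "derivative_spike"
        assert a <= 5.0 <= b

    def test_smooth_sinusoid_not_flagged(self):
        fs = 500.0
        t = np.arange(0, 10, 1 / fs)
        y = np.sin(2 * np.pi * 0.5 * t)  # max step ~ pi/500 << 10
        assert len(P.detect_derivative_artifacts(make_rec(y, fs), 10.0)) == 0

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(P.InvalidRecordingError):
            P.PupilRecording(t=np.array([0.0, 0.1, 0.3]), y=np.zeros(3), fs=10.0)


class TestInterpolation:
    def test_flat_trace_unchanged(self):
        rec = make_rec(np.full(2000, 3.0))
        ann = P.ArtifactAnnotations([("blink", 1.0, 1.5)])
        out = P.interpolate_intervals(rec, ann)
        assert np.allclose(out.y, 3.0)

    def test_linear_ramp_recovered_exactly(self):
        fs = 500.0
        t = np.arange(0, 4, 1 / fs)
        rec = P.PupilRecording(t=t, y=2.0 * t + 1.0, fs=fs)
        corrupted = rec.y.copy()
        gap = (t >= 1.8) & (t < 2.0)
        corrupted[gap] = 99.0
        rec2 = P.PupilRecording(t=t, y=corrupted, fs=fs)
        out = P.interpolate_intervals(
            rec2, P.ArtifactAnnotations([("missing", 1.8, 2.0)])
        )
        assert np.allclose(out.y, 2.0 * t + 1.0, atol=1e-9)

    def test_samples_outside_padded_spans_untouched(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=4000)
        rec = make_rec(y)
        ann = P.ArtifactAnnotations([("blink", 2.0, 2.2)])
        out = P.interpolate_intervals(rec, ann, pad_s=0.15)
        outside = (rec.t < 2.0 - 0.15 - 1e-9) | (rec.t > 2.2 + 0.15 + 1e-9)
        assert np.array_equal(out.y[outside], y[outside])

    def test_nearby_gaps_merge_into_one_span(self):
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        y = np.sin(t)
        rec = P.PupilRecording(t=t, y=y, fs=fs)
        # gaps 0.1 s apart with 0.15 s pads overlap -> one merged span
        ann = P.ArtifactAnnotations([("blink", 3.0, 3.2), ("blink", 3.3, 3.5)])
        out = P.interpolate_intervals(rec, ann, pad_s=0.15)
        span = (t >= 2.85) & (t <= 3.65)
        inner = span & (t > 2.86) & (t < 3.64)
        seg = out.y[inner]
        assert np.allclose(np.diff(seg, 2), 0.0, atol=1e-9)  # single line

    def test_fully_invalid_recording_rejected(self):
        rec = make_rec(np.zeros(100), fs=100.0)
        with pytest.raises(P.InvalidRecordingError):
            P.interpolate_intervals(rec, P.ArtifactAnnotations([("missing", 0.0, 2.0)]))


class TestBandpass:
    def test_dc_rejected(self):
        rec = make_rec(np.full(30000, 100.0))
        out = P.bandpass_filter(rec)
        assert np.max(np.abs(out.y)) < 1e-4

    def test_passband_gain_near_unity(self):
        fs = 500.0
        t = np.arange(0, 60, 1 / fs)
        rec = P.PupilRecording(t=t, y=np.sin(2 * np.pi * 1.0 * t), fs=fs)
        out = P.bandpass_filter(rec)
        mid = (t > 10) & (t < 50)
        gain = out.y[mid].std() / rec.y[mid].std()
        assert 0.9 < gain < 1.1

    def test_stopband_attenuated(self):
        # long signal: the 0.01 Hz high-pass has a ~100 s impulse response,
        # so edge transients must decay before measuring attenuation
        fs = 500.0
        t = np.arange(0, 100, 1 / fs)
        rec = P.PupilRecording(t=t, y=np.sin(2 * np.pi * 20.0 * t), fs=fs)
        out = P.bandpass_filter(rec)
        mid = (t > 40) & (t < 60)
        assert out.y[mid].std() < 0.1 * rec.y[mid].std()

    def test_cutoff_beyond_nyquist_rejected(self):
        rec = make_rec(np.zeros(1000), fs=10.0)
        with pytest.raises(ValueError):
            P.bandpass_filter(rec, high=6.0)


def blink_kernel(t, tau=1.2):
    k = (t / tau) ** 2 * np.exp(-t / tau)
    return k / k.max()


class TestNuisanceRegression:
    def test_no_events_identity(self):
        rec = make_rec(np.sin(np.arange(1000) / 50.0), fs=100.0)
        out, fit = P.remove_nuisance_responses(rec, P.ArtifactAnnotations([]))
        assert np.array_equal(out.y, rec.y)
        assert fit.kernels == {}

    def test_planted_kernel_recovered_noiselessly(self):
        fs = 100.0
        rng = np.random.default_rng(0)
        dur = 150.0
        n = int(dur * fs) + 1
        t = np.arange(n) / fs
        kt = np.arange(0, 6.0, 1 / fs)
        truth = blink_kernel(kt)
        onsets = np.sort(rng.uniform(5, dur - 10, 20))
        y = np.zeros(n)
        for o in onsets:
            i0 = int(round(o * fs))
            y[i0 : i0 + kt.size] += truth[: n - i0][: kt.size]
        rec = P.PupilRecording(t=t, y=y, fs=fs)
        ann = P.ArtifactAnnotations([("blink", o - 0.1, o) for o in onsets])
        res, fit = P.remove_nuisance_responses(rec, ann)
        est = fit.kernel_at("blink", fs)
        m = min(est.size, truth.size)
        assert np.corrcoef(est[:m], truth[:m])[0, 1] > 0.99
        assert res.y.std() < 0.01 * y.std()

    def test_two_kernels_separated_under_noise(self):
        fs = 100.0
        rng = np.random.default_rng(1)
        dur = 200.0
        n = int(dur * fs) + 1
        t = np.arange(n) / fs
        kt = np.arange(0, 6.0, 1 / fs)
        k_blink = blink_kernel(kt)
        k_sacc = (kt / 0.3) ** 1.5 * np.exp(-kt / 0.3)
        k_sacc /= k_sacc.max()
        on_b = np.sort(rng.uniform(5, dur - 10, 25))
        on_s = np.sort(rng.uniform(5, dur - 10, 30))
        y = np.zeros(n)
        for o in on_b:
            i0 = int(round(o * fs))
            y[i0 : i0 + kt.size] += k_blink[: n - i0][: kt.size]
        for o in on_s:
            i0 = int(round(o * fs))
            y[i0 : i0 + kt.size] += 0.8 * k_sacc[: n - i0][: kt.size]
        y += rng.normal(0, y.std() / 5, n)  # SNR 5
        rec = P.PupilRecording(t=t, y=y, fs=fs)
        ann = P.ArtifactAnnotations(
            [("blink", o - 0.1, o) for o in on_b]
            + [("saccade", o - 0.05, o) for o in on_s]
        )
        _, fit = P.remove_nuisance_responses(rec, ann)
        eb = fit.kernel_at("blink", fs)[: kt.size]
        es = fit.kernel_at("saccade", fs)[: kt.size]
        assert np.corrcoef(eb, k_blink)[0, 1] > 0.95
        assert np.corrcoef(es, k_sacc)[0, 1] > 0.95

    def test_underdetermined_design_rejected(self):
        rec = make_rec(np.zeros(50), fs=100.0)
        ann = P.ArtifactAnnotations([("blink", 0.1, 0.2)])
        with pytest.raises(ValueError):
            P.remove_nuisance_responses(rec, ann)


class TestPercentSignalChange:
    def test_zero_residual_stays_zero(self):
        out = P.percent_signal_change(make_rec(np.zeros(100)), 10.0)
        assert np.all(out.y == 0)

    def test_proportionality_and_linearity(self):
        rec = make_rec(np.full(100, 1.0))
        assert np.allclose(P.percent_signal_change(rec, 10.0).y, 10.0)
        scaled = make_rec(np.full(100, 3.0))
        assert np.allclose(
            P.percent_signal_change(scaled, 10.0).y,
            3 * P.percent_signal_change(rec, 10.0).y,
        )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            P.percent_signal_change(make_rec(np.zeros(10)), 0.0)


class TestEpochs:
    def test_epoch_count_matches_onsets(self):
        rec = make_rec(np.zeros(500 * 60))
        onsets = np.linspace(5, 50, 10)
        ep = P.extract_epochs(rec, onsets)
        assert ep.n_trials == 10

    def test_impulse_alignment_at_zero_lag(self):
        fs = 500.0
        y = np.zeros(int(60 * fs))
        t0 = 20.0
        y[int(t0 * fs)] = 1.0
        ep = P.extract_epochs(make_rec(y, fs), np.array([t0]))
        peak_rel = ep.time[np.argmax(ep.data[0])]
        assert abs(peak_rel) < 1e-9

    def test_out_of_bounds_onset_dropped(self):
        rec = make_rec(np.zeros(500 * 30))
        onsets = np.concatenate([[-0.2], np.linspace(5, 25, 9)])
        labels = pd.DataFrame({"trial": np.arange(1, 11)})
        ep = P.extract_epochs(rec, onsets, labels=labels)
        assert ep.n_trials == 9
        assert 1 not in set(ep.labels["trial"])


class TestBaselineAndWindows:
    def test_constant_epoch_zeroed(self):
        fs = 500.0
        time = np.arange(-0.5 * fs, 3.0 * fs + 1) / fs
        ep = P.EpochSet(
            data=np.full((3, time.size), 7.0),
            time=time,
            labels=pd.DataFrame({"trial": [1, 2, 3]}),
        )
        corrected, table = P.baseline_and_window(ep)
        assert np.allclose(corrected.data, 0.0)
        assert np.allclose(table["early"], 0.0)
        assert np.allclose(table["late"], 0.0)

    def test_linear_epoch_window_arithmetic(self):
        fs = 500.0
        time = np.arange(-0.5 * fs, 3.0 * fs + 1) / fs
        ep = P.EpochSet(
            data=time[None, :].copy(),
            time=time,
            labels=pd.DataFrame({"trial": [1]}),
        )
        _, table = P.baseline_and_window(ep)
        # baseline mean ~ -0.251, early raw mean ~ 0.999 -> corrected 1.25
        assert table["early"].iloc[0] == pytest.approx(1.25, abs=1e-3)

    def test_early_window_sample_count_at_500hz(self):
        fs = 500.0
        time = np.arange(-0.5 * fs, 3.0 * fs + 1) / fs
        mask = (time >= 0.75) & (time < 1.25)
        assert mask.sum() == 250

    def test_window_outside_epoch_rejected(self):
        time = np.arange(-0.5, 1.0, 0.01)
        ep = P.EpochSet(
            data=np.zeros((1, time.size)),
            time=time,
            labels=pd.DataFrame({"trial": [1]}),
        )
        with pytest.raises(ValueError):
            P.baseline_and_window(ep)


class TestRTExclusion:
    def test_constant_rts_keep_everything(self):
        with pytest.warns(UserWarning):
            mask = P.exclude_rt_outliers(np.full(10, 0.5))
        assert mask.all()

    def test_single_extreme_rt_excluded(self):
        rng = np.random.default_rng(0)
        rts = np.concatenate([rng.normal(0.5, 0.01, 99), [5.0]])
        mask = P.exclude_rt_outliers(rts)
        assert not mask[-1]
        assert mask[:-1].all()

    def test_gaussian_exclusion_fraction(self):
        rng = np.random.default_rng(1)
        rts = rng.standard_normal(10_000)
        mask = P.exclude_rt_outliers(rts)
        frac = 1 - mask.mean()
        assert frac == pytest.approx(2 * norm.cdf(-3), abs=0.0015)


class TestChainInvariants:
    def test_chain_reduces_to_bandpass_and_psc_without_artifacts(self):
        fs = 500.0
        t = np.arange(0, 120, 1 / fs)
        y = 100.0 + np.sin(2 * np.pi * 0.5 * t)
        rec = P.PupilRecording(t=t, y=y, fs=fs)
        ann = P.ArtifactAnnotations([])
        rec_i = P.interpolate_intervals(rec, P.missing_intervals(rec) + ann)
        assert np.array_equal(rec_i.y, y)
        spikes = P.detect_derivative_artifacts(rec_i)
        assert len(spikes) == 0
        rec_f = P.bandpass_filter(rec_i)
        rec_r, _ = P.remove_nuisance_responses(rec_f, ann)
        assert np.array_equal(rec_r.y, rec_f.y)

    def test_planted_amplitudes_recovered_through_full_chain(self):
        """Per-trial white amplitudes survive the chain with unit relative gain.

        The deterministic window gain of the processed unit response is
        calibrated from a noise-free replicate; the noisy run's regression
        slope on the planted amplitudes must match it within 10% at SNR 2.
        """
        from pupilgain import synthetic as G
        from conftest import preprocess_chain

        fs = 500.0
        n_tr = 80
        rng = np.random.default_rng(4)
        onsets = G.schedule_onsets(n_tr, rng)
        amps = 100.0 + rng.normal(0, 30.0, n_tr)  # planted white amplitudes

        def build(amp, noise_sd, rng2):
            dur = onsets[-1] + 6.0
            n = int(dur * fs) + 1
            t = np.arange(n) / fs
            y = np.full(n, 5000.0)
            kt = np.arange(0, 4, 1 / fs)
            k = G.pupil_irf(kt)
            for o, a in zip(onsets, amp):
                i0 = int(round(o * fs))
                i1 = min(i0 + k.size, n)
                y[i0:i1] += a * k[: i1 - i0]
            if noise_sd:
                from scipy import signal as sg

                sos = sg.butter(2, 4.0, btype="lowpass", fs=fs, output="sos")
                w = sg.sosfiltfilt(sos, rng2.standard_normal(n))
                y += noise_sd * w / w.std()
            return P.PupilRecording(t=t, y=y, fs=fs)

        labels = pd.DataFrame({"trial": np.arange(1, n_tr + 1)})
        # SNR 2 at the trial-amplitude level: amplitude sd 30 -> noise 15
        noisy, _ = preprocess_chain(build(amps, 15.0, rng), P.ArtifactAnnotations([]))
        clean, _ = preprocess_chain(build(amps, 0.0, rng), P.ArtifactAnnotations([]))
        _, wt_noisy = P.baseline_and_window(
            P.extract_epochs(noisy, onsets, labels=labels)
        )
        _, wt_clean = P.baseline_and_window(
            P.extract_epochs(clean, onsets, labels=labels)
        )
        A = np.vstack([amps, np.ones_like(amps)]).T
        slope_noisy = np.linalg.lstsq(A, wt_noisy["early"], rcond=None)[0][0]
        slope_clean = np.linalg.lstsq(A, wt_clean["early"], rcond=None)[0][0]
        assert slope_noisy / slope_clean == pytest.approx(1.0, abs=0.1)
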