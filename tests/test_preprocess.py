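import numpy as np
import pytest

from topoerp import preprocess as pp
from topoerp import synth
from topoerp.containers import EpochedRecording, GroundTruth, Segment


SRATE = 1024.0


def _sine(freq, srate=SRATE, dur=4.0):
    t = np.arange(0.0, dur, 1.0 / srate)
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_sine_untouched(self):
        x = _sine(10.0)
        y = pp.bandpass_filter(x, SRATE)
        core = slice(1024, -1024)  # away from edges
        atten = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert atten > 0.99
        # zero phase: cross-correlation peaks at lag 0
        xc, yc = x[core], y[core]
        lags = range(-5, 6)
        cc = [np.dot(yc, np.roll(xc, l)) for l in lags]
        assert list(lags)[int(np.argmax(cc))] == 0

    def test_stopband_attenuation(self):
        # lock-in amplitude of the 120 Hz component (edge transients of the
        # 0.1 Hz high-pass would otherwise dominate a naive peak measure)
        x = _sine(120.0)
        y = pp.bandpass_filter(x, SRATE)
        core = slice(1024, -1024)
        t = np.arange(len(x))[core] / SRATE
        s, c = np.sin(2 * np.pi * 120 * t), np.cos(2 * np.pi * 120 * t)
        amp = np.hypot(2 * np.mean(y[core] * s), 2 * np.mean(y[core] * c))
        atten_db = 20 * np.log10(amp / 1.0)
        assert atten_db <= -24.0

    def test_symmetric_impulse_gives_symmetric_output(self):
        # zero-phase property; tolerance is set by the numerics of the
        # 0.1 Hz section, whose pole sits within 6e-4 of the unit circle
        x = np.zeros(2049)
        x[1024] = 1.0
        y = pp.bandpass_filter(x, SRATE)
        assert np.abs(y - y[::-1]).max() < 1e-3 * np.abs(y).max()

    def test_invalid_cutoffs(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass_filter(_sine(10.0), SRATE, low_hz=0.1, high_hz=600.0)


class TestSplineInterpolation:
    def test_exact_on_low_degree_harmonic_field(self):
        """A spherical-harmonic field of degree <= 10 is reconstructed
        exactly at a left-out sensor: with 127 good channels of a
        128-channel cap the spline kernels span the whole degree-<=10
        space."""
        from topoerp.montage import make_montage

        montage = make_montage(128, 0)
        rng = np.random.default_rng(0)
        pos = montage.positions
        sources = rng.standard_normal((20, 3))
        sources /= np.linalg.norm(sources, axis=1, keepdims=True)
        field = sum(w * pp._spline_g(pos @ s, 4, 10)
                    for w, s in zip(rng.standard_normal(20), sources))
        data = np.tile(field[:, None], (1, 4))
        bad = [montage.labels[10]]
        out = pp.interpolate_bad_channels(data, montage, bad)
        rel = np.abs(out[10] - data[10]).max() / np.abs(data[10]).max()
        assert rel < 1e-6

    def test_no_bads_is_identity(self, montage64):
        data = np.random.default_rng(1).standard_normal((64, 7))
        assert np.array_equal(pp.interpolate_bad_channels(data, montage64, []), data)

    def test_good_channels_untouched(self, montage64):
        data = np.random.default_rng(2).standard_normal((64, 7))
        out = pp.interpolate_bad_channels(data, montage64, [montage64.labels[3]],
                                          max_fraction=0.05)
        mask = np.ones(64, bool)
        mask[3] = False
        assert np.array_equal(out[mask], data[mask])

    def test_too_many_bads_refused(self, montage64):
        data = np.zeros((64, 3))
        bads = list(montage64.labels[:4])  # 6.25% > 4% ceiling
        with pytest.raises(ValueError, match="ceiling"):
            pp.interpolate_bad_channels(data, montage64, bads)


class TestResample:
    def test_sine_preserved(self):
        x = _sine(10.0)
        y, hz = pp.resample(x, SRATE, 256.0)
        t = np.arange(len(y)) / 256.0
        ref = np.sin(2 * np.pi * 10.0 * t)
        core = slice(256, -256)
        assert np.abs(y[core] - ref[core]).max() < 0.01

    def test_constant_preserved(self):
        y, _ = pp.resample(np.full(4096, 5.0), SRATE, 256.0)
        assert np.allclose(y, 5.0, atol=1e-9)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="below"):
            pp.resample(np.zeros(100), 256.0, 512.0)


def test_average_reference_zero_mean_and_idempotent():
    data = np.random.default_rng(0).standard_normal((3, 16, 20)) + 2.0
    out = pp.average_reference(data)
    assert np.abs(out.mean(axis=-2)).max() < 1e-10
    assert np.allclose(pp.average_reference(out), out, atol=1e-12)
    with pytest.raises(ValueError, match="2 channels"):
        pp.average_reference(np.ones((1, 5)))


def test_baseline_correct():
    times = np.arange(-200.0, 350.0, 1000.0 / 256.0)
    data = np.full((2, 4, len(times)), 5.0)
    out = pp.baseline_correct(data, times)
    assert np.abs(out).max() < 1e-10
    m = (times >= -200) & (times <= 0)
    assert np.abs(out[..., m].mean(axis=-1)).max() < 1e-10
    with pytest.raises(ValueError, match="outside"):
        pp.baseline_correct(data, times, (-500.0, -400.0))


class TestRejection:
    def test_boundary_semantics(self):
        epochs = np.zeros((3, 2, 10))
        epochs[0, 0, 5] = 85.0   # above threshold -> rejected
        epochs[1, 1, 2] = 80.0   # exactly at threshold -> retained
        kept, kept_idx, rej_idx = pp.reject_artifacts(epochs, 80.0)
        assert list(rej_idx) == [0]
        assert list(kept_idx) == [1, 2]

    def test_exactly_injected_epochs_rejected(self, montage32, null_truth):
        recs = synth.simulate_null_dataset(montage32, 1, 10, null_truth, seed=3,
                                           srate=256.0, epoch_ms=(0.0, 180.0))
        out = synth.inject_artifacts(recs[0], montage32, spike_rate=0.25,
                                     outlier_amplitude=100.0, seed=7)
        _, _, rej = pp.reject_artifacts(out.data, 80.0)
        assert sorted(rej.tolist()) == sorted(out.info["spike_epochs"])

    def test_all_rejected_is_error(self):
        with pytest.raises(ValueError, match="nothing retained"):
            pp.reject_artifacts(np.full((2, 2, 5), 200.0), 80.0)


def test_delay_correction_inverse_and_arithmetic():
    times = np.arange(0.0, 200.0, 2.0)
    assert np.array_equal(pp.correct_stimulus_delay(times, 0.0), times)
    shifted = pp.correct_stimulus_delay(times, 32.0)
    assert np.allclose(pp.correct_stimulus_delay(shifted, -32.0), times)
    assert shifted[times == 102.0][0] == 70.0


class TestAverageEpochs:
    def _rec(self, data, conds, srate=256.0):
        times = np.arange(0.0, data.shape[-1]) * 1000.0 / srate
        return EpochedRecording("S01", data, srate, times, conds)

    def test_identical_epochs(self):
        data = np.tile(np.random.default_rng(0).standard_normal((1, 4, 50)), (3, 1, 1))
        evs = self._rec(data, ["a"] * 3)
        out = pp.average_epochs(evs, crop_ms=(0.0, 200.0))
        assert np.allclose(out["a"].data, data[0], atol=1e-12)
        assert out["a"].nave == 3

    def test_antisymmetric_pair_cancels(self):
        v = np.random.default_rng(1).standard_normal((4, 50))
        evs = self._rec(np.stack([v, -v]), ["a", "a"])
        assert np.abs(pp.average_epochs(evs, crop_ms=(0.0, 190.0))["a"].data).max() < 1e-12

    def test_missing_condition_error(self):
        evs = self._rec(np.zeros((2, 4, 50)), ["a", "a"])
        with pytest.raises(ValueError, match="'b'"):
            pp.average_epochs(evs, conditions=["b"])


def test_chain_recovers_truth_and_large_n_convergence(montage32):
    """Noise-free full chain reproduces the planted ERP; with noise the
    average converges to it at the statistical rate."""
    t = synth.random_templates(montage32, 1, seed=2)[0]
    segs = [Segment(35.0, 190.0, 0, 2.0), Segment(190.0, 345.0, 1, 2.0)]
    truth = GroundTruth(templates=[t, -t],
                        segments={"direct/BB": segs, "averted/BB": segs},
                        noise_sd=0.0, seed=0)
    recs, _ = synth.simulate_dataset(montage32, design=("direct/BB", "averted/BB"),
                                     n_subjects=1, n_epochs_per_cond=2,
                                     truth=truth, seed=0, srate=1024.0,
                                     rotation_deg=0.0, gain_sigma=0.0)
    evs, report = pp.preprocess_recording(recs[0], montage32)
    ev = evs["direct/BB"]
    gt = truth.condition_signal("direct/BB", ev.times)
    gt -= gt.mean(axis=0)
    interior = (ev.times >= -80) & (ev.times <= 330)
    assert np.abs(ev.data - gt)[:, interior].max() < 0.05
    assert report.rejection_rate == 0.0

    # noisy: mean over n epochs approaches truth within 3 SEM of the noise
    noisy = GroundTruth(templates=[t, -t], segments=truth.segments,
                        noise_sd=5.0, seed=0)
    n_ep = 200
    recs2, _ = synth.simulate_dataset(montage32, design=("direct/BB",),
                                      n_subjects=1, n_epochs_per_cond=n_ep,
                                      truth=noisy, seed=1, srate=512.0,
                                      rotation_deg=0.0, gain_sigma=0.0)
    evs2, _ = pp.preprocess_recording(recs2[0], montage32, threshold_uv=1e6)
    ev2 = evs2["direct/BB"]
    gt2 = noisy.condition_signal("direct/BB", ev2.times)
    gt2 -= gt2.mean(axis=0)
    sem = 5.0 / np.sqrt(n_ep)
    resid = np.abs(ev2.data - gt2)[:, (ev2.times >= -80) & (ev2.times <= 330)]
    # filtering whitens/shrinks noise, so 3 SEM (+ chain bias) is a safe cap
    assert resid.max() < 3 * sem + 0.05


def test_blink_attenuation_reduces_frontal_artifact(montage32, null_truth):
    recs = synth.simulate_null_dataset(montage32, 1, 20, null_truth, seed=5,
                                       srate=256.0, epoch_ms=(-200.0, 350.0))
    dirty = synth.inject_artifacts(recs[0], montage32, blink_rate=0.5, seed=6)
    tpl = synth.blink_topography(montage32)
    cleaned = pp.attenuate_blinks(dirty.data, tpl, 256.0)
    blinked = dirty.info["blink_epochs"]
    before = np.abs(dirty.data[blinked] - recs[0].data[blinked]).max()
    after = np.abs(cleaned[blinked] - recs[0].data[blinked]).max()
    assert after < 0.25 * before
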