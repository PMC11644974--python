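import dataclasses
import warnings

import numpy as np
import pytest

from imuposture.io import SensorRecording
from imuposture.preprocess import (
    GRAVITY,
    PreprocessConfig,
    SyncWarning,
    decompose_acc,
    estimate_sync_delay,
    fill_gaps,
    mask_artifacts,
    preprocess_recording,
    resample_to_target,
    roll_pitch,
)
from imuposture.simulate import SimulationConfig, simulate_clap_track


def _recording(t, acc=None, rate=60, **kw):
    n = len(t)
    acc = np.tile([[0.0], [0.0], [GRAVITY]], (1, n)) if acc is None else acc
    return SensorRecording(
        location="trunk_a",
        timestamps=np.asarray(t, dtype=float),
        acc=np.asarray(acc, dtype=float),
        gyro=np.zeros((3, n)),
        mag=np.ones((3, n)),
        nominal_rate=rate,
        **kw,
    )


class TestFillGaps:
    def test_no_missing_samples_is_identity(self):
        t = np.arange(120) / 60.0
        rec = _recording(t)
        out = fill_gaps(rec)
        assert np.array_equal(out.timestamps, t)
        assert np.array_equal(out.acc, rec.acc)

    def test_spline_reproduces_cubic_polynomial(self):
        # cubic splines are exact on polynomials of degree <= 3
        t_full = np.arange(120) / 60.0
        missing = [40, 41, 77]
        keep = np.setdiff1d(np.arange(120), missing)
        acc = np.vstack([t_full ** 2, 2 * t_full ** 2 + 1, t_full ** 3])
        rec = _recording(t_full[keep], acc[:, keep])
        out = fill_gaps(rec)
        assert out.n_samples == 120
        assert np.allclose(out.acc, acc, rtol=1e-9, atol=1e-12)
        assert not out.artifact_mask.any()

    def test_long_gap_masked_not_trusted(self):
        t_full = np.arange(300) / 60.0
        missing = np.arange(100, 180)  # 1.33 s gap
        keep = np.setdiff1d(np.arange(300), missing)
        rec = _recording(t_full[keep])
        out = fill_gaps(rec, max_gap_s=1.0)
        assert out.artifact_mask[missing].all()
        assert not out.artifact_mask[keep].any()


class TestResample:
    def test_60hz_input_is_identity(self):
        rec = _recording(np.arange(120) / 60.0)
        assert resample_to_target(rec) is rec

    def test_40hz_sinusoid_amplitude_preserved(self):
        t = np.arange(400) / 40.0
        x = np.sin(2 * np.pi * 2.0 * t)
        rec = _recording(t, np.vstack([x, x, x]), rate=40)
        out = resample_to_target(rec)
        assert out.nominal_rate == 60
        expected = np.sin(2 * np.pi * 2.0 * out.timestamps)
        core = slice(60, -60)  # away from edges
        err = np.abs(out.acc[0, core] - expected[core])
        assert err.max() < 0.01

    def test_40hz_constant_preserved(self):
        t = np.arange(200) / 40.0
        rec = _recording(t, np.full((3, 200), 3.7), rate=40)
        out = resample_to_target(rec)
        assert np.allclose(out.acc, 3.7, atol=1e-6)


class TestMaskArtifacts:
    def test_constant_span_fully_masked(self):
        rec = _recording(np.arange(600) / 60.0)  # constant gravity
        out = mask_artifacts(rec)
        assert out.artifact_mask.all()

    def test_noise_spans_retained(self, rng):
        n = 600
        acc = np.tile([[0.0], [0.0], [GRAVITY]], (1, n))
        acc += rng.normal(scale=0.1, size=(3, n))
        out = mask_artifacts(_recording(np.arange(n) / 60.0, acc))
        assert not out.artifact_mask.any()

    def test_threshold_extremes_and_monotonicity(self, rng):
        n = 600
        acc = np.tile([[0.0], [0.0], [GRAVITY]], (1, n))
        acc[:, :300] += rng.normal(scale=0.05, size=(3, 300))
        rec = _recording(np.arange(n) / 60.0, acc)
        lo = mask_artifacts(rec, dataclasses.replace(PreprocessConfig(),
                                                     artifact_var_threshold=0.0))
        hi = mask_artifacts(rec, dataclasses.replace(PreprocessConfig(),
                                                     artifact_var_threshold=np.inf))
        mid = mask_artifacts(rec)
        assert not lo.artifact_mask.any()
        assert hi.artifact_mask.all()
        # monotone: every sample masked at the default stays masked at +inf
        assert (hi.artifact_mask | ~mid.artifact_mask).all()

    def test_mask_invariant_to_constant_acc_offset(self, rng):
        n = 600
        acc = rng.normal(scale=0.2, size=(3, n))
        acc[2, 200:400] = 5.0  # flat z-span -> but x,y still vary
        acc[0, 200:400] = 0.1
        acc[1, 200:400] = 0.2
        rec1 = _recording(np.arange(n) / 60.0, acc)
        rec2 = _recording(np.arange(n) / 60.0, acc + 3.3)
        m1 = mask_artifacts(rec1).artifact_mask
        m2 = mask_artifacts(rec2).artifact_mask
        # variance of the magnitude is not offset-invariant in general, but
        # flat spans stay flat: the masked (zero-variance) spans must agree
        assert np.array_equal(m1[200:395], m2[200:395])


class TestDecompose:
    def test_constant_gravity_splits_to_lp(self):
        rec = _recording(np.arange(600) / 60.0)
        d = decompose_acc(rec)
        assert np.allclose(d["acc_lp_z"], GRAVITY, atol=1e-6)
        assert np.abs(d["acc_hp_z"]).max() < 1e-6
        assert np.allclose(d["norm"], GRAVITY)

    def test_fast_oscillation_blocked_by_lp(self):
        t = np.arange(1200) / 60.0
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = _recording(t, np.vstack([x, 0 * t, 0 * t + GRAVITY]))
        d = decompose_acc(rec)  # lp cutoff 1 Hz, 10x below the tone
        assert np.abs(d["acc_lp_x"][120:-120]).max() < 0.05
        assert np.abs(d["acc_hp_x"][120:-120] - x[120:-120]).max() < 0.05

    def test_norm_of_3_4_0_is_5(self):
        n = 12
        acc = np.tile([[3.0], [4.0], [0.0]], (1, n))
        d = decompose_acc(_recording(np.arange(n) / 60.0, acc))
        assert np.allclose(d["norm"], 5.0)

    def test_complementarity_when_cutoffs_equal(self, rng):
        acc = rng.normal(size=(3, 600))
        rec = _recording(np.arange(600) / 60.0, acc)
        d = decompose_acc(rec)
        lp = np.vstack([d["acc_lp_x"], d["acc_lp_y"], d["acc_lp_z"]])
        hp = np.vstack([d["acc_hp_x"], d["acc_hp_y"], d["acc_hp_z"]])
        assert np.allclose(lp + hp, acc, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(Exception):
            PreprocessConfig(lp_cutoff_hz=31.0)


class TestRollPitch:
    @pytest.mark.parametrize(
        "vec,expected_roll,expected_pitch",
        [
            ((0, 0, GRAVITY), 0.0, 0.0),
            ((-GRAVITY, 0, 0), 0.0, np.pi / 2),
            ((0, GRAVITY, 0), np.pi / 2, 0.0),
        ],
    )
    def test_reference_orientations(self, vec, expected_roll, expected_pitch):
        acc = np.tile(np.asarray(vec, dtype=float)[:, None], (1, 4))
        roll, pitch = roll_pitch(acc)
        assert np.allclose(roll, expected_roll, atol=1e-12)
        assert np.allclose(pitch, expected_pitch, atol=1e-12)

    def test_invariant_to_positive_scaling(self, rng):
        acc = rng.normal(size=(3, 50))
        r1, p1 = roll_pitch(acc)
        r2, p2 = roll_pitch(3.14 * acc)
        assert np.allclose(r1, r2) and np.allclose(p1, p2)

    def test_zero_norm_propagates_nan(self):
        acc = np.zeros((3, 3))
        roll, pitch = roll_pitch(acc)
        assert np.isnan(roll).all() and np.isnan(pitch).all()


class TestSyncDelay:
    def _track(self, spike_times, n=3600, rate=60):
        t = np.arange(n) / rate
        norms = np.full((2, n), GRAVITY)
        for st in spike_times:
            i = int(round(st * rate))
            norms[:, i] += 25.0
        return t, norms

    def test_constant_offset_recovered(self):
        audio = [10.0, 11.0, 12.0, 13.0, 14.0]
        t, norms = self._track([a + 0.5 for a in audio])
        assert estimate_sync_delay(norms, t, audio) == pytest.approx(0.5, abs=1e-9)

    def test_zero_delay(self):
        audio = [10.0, 11.0, 12.0, 13.0, 14.0]
        t, norms = self._track(audio)
        assert estimate_sync_delay(norms, t, audio) == pytest.approx(0.0, abs=1e-9)

    def test_spurious_peak_discarded_by_ordered_matching(self):
        audio = [10.0, 11.0, 12.0, 13.0, 14.0]
        t, norms = self._track([a + 0.4 for a in audio] + [25.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SyncWarning)
            delay = estimate_sync_delay(norms, t, audio)
        assert delay == pytest.approx(0.4, abs=1 / 60)

    def test_recovery_on_simulated_clap_tracks(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(7)
        delay_true = -1.234
        t, norms = simulate_clap_track(cfg, rng, delay_true, duration=30.0)
        est = estimate_sync_delay(norms, t, cfg.clap_times_audio)
        assert abs(est - delay_true) <= 1 / 60


def test_preprocess_idempotent_on_clean_input(rng):
    n = 1200
    acc = np.tile([[0.0], [0.0], [GRAVITY]], (1, n)) + rng.normal(0, 0.2, (3, n))
    rec = _recording(np.arange(n) / 60.0, acc)
    d1 = preprocess_recording(rec)
    # feed the derived raw channels back through as a recording
    rec2 = _recording(
        d1.timestamps,
        np.vstack([d1["acc_x"], d1["acc_y"], d1["acc_z"]]),
    )
    d2 = preprocess_recording(rec2)
    for ch in ("acc_x", "acc_lp_z", "norm", "roll", "pitch"):
        assert np.allclose(d1[ch], d2[ch], atol=1e-9)
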