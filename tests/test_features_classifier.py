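"""Band-pass, epoching, log-variance features, and the linear classifier."""

import numpy as np
import pytest

from beamadapt.features_classifier import (
    ALPHA,
    THETA,
    BandSpec,
    ClassifierModel,
    FeatureMatrix,
    bandpass,
    epoch,
    logvar_features,
    logvar_from_covariances,
    predict,
    train_lda,
)
from beamadapt.model_core import Block, EEGRecording, EpochSet
from beamadapt.synthetic_data import make_schedule

from conftest import make_epochs, random_spd


def _sine_recording(freq, fs=200.0, dur=30.0):
    t = np.arange(int(dur * fs)) / fs
    data = np.sin(2 * np.pi * freq * t)[None, :]
    return EEGRecording(data, fs, ["Cz"], annotations=[Block(0, dur, "low", "nback")])


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = bandpass(_sine_recording(10.0), ALPHA)
        steady = rec.data[0, 2000:]  # skip the causal transient
        amp = (steady.max() - steady.min()) / 2
        assert abs(amp - 1.0) < 0.05

    def test_stopband_tone_suppressed(self):
        rec = bandpass(_sine_recording(20.0), ALPHA)
        steady = rec.data[0, 2000:]
        amp = (steady.max() - steady.min()) / 2
        assert amp < 0.15

    def test_zero_in_zero_out(self):
        rec = EEGRecording(np.zeros((2, 1000)), 100.0, ["Cz", "Pz"])
        out = bandpass(rec, THETA)
        np.testing.assert_array_equal(out.data, 0)

    def test_band_above_nyquist_errors(self):
        rec = _sine_recording(5.0, fs=20.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, BandSpec("alpha", 8.0, 13.0))

    def test_annotations_untouched(self):
        rec = _sine_recording(10.0)
        out = bandpass(rec, ALPHA)
        assert out.annotations == rec.annotations


class TestEpoch:
    def _recording_from_schedule(self, schedule, fs=50.0):
        n = int(schedule.duration_s * fs)
        return EEGRecording(
            np.zeros((2, n)) + np.arange(n), fs, ["Cz", "Pz"], annotations=schedule.blocks
        )

    def test_default_maneuver_schedule_yields_30_epochs(self):
        rec = self._recording_from_schedule(make_schedule("maneuver"))
        eps = epoch(rec, 60.0)
        assert eps.n_epochs == 30

    def test_floor_rule_single_epoch(self):
        rec = EEGRecording(
            np.zeros((1, 4500)), 50.0, ["Cz"], annotations=[Block(0, 90, "low", "nback")]
        )
        assert epoch(rec, 60.0).n_epochs == 1

    def test_exact_block_split_is_disjoint_and_covering(self):
        fs = 50.0
        n = int(120 * fs)
        rec = EEGRecording(
            np.arange(n, dtype=float)[None], fs, ["Cz"], annotations=[Block(0, 120, "low", "nback")]
        )
        eps = epoch(rec, 60.0)
        assert eps.n_epochs == 2
        flat = np.concatenate([eps.epochs[0, 0], eps.epochs[1, 0]])
        np.testing.assert_array_equal(flat, np.arange(n))

    def test_epochs_never_straddle_blocks(self):
        fs = 50.0
        blocks = [Block(0, 90, "low", "nback"), Block(90, 180, "high", "nback")]
        n = int(180 * fs)
        rec = EEGRecording(np.zeros((1, n)), fs, ["Cz"], annotations=blocks)
        eps = epoch(rec, 60.0)
        # 1 epoch per block (30 s discarded in each), labels follow blocks
        assert eps.n_epochs == 2
        assert list(eps.labels) == ["low", "high"]

    def test_no_annotations_errors(self):
        rec = EEGRecording(np.zeros((1, 100)), 50.0, ["Cz"])
        with pytest.raises(ValueError, match="no usable epochs"):
            epoch(rec, 60.0)

    def test_all_blocks_too_short_errors(self):
        rec = EEGRecording(
            np.zeros((1, 100)), 50.0, ["Cz"], annotations=[Block(0, 1, "low", "nback")]
        )
        with pytest.raises(ValueError, match="no usable epochs"):
            epoch(rec, 60.0)


class TestLogvarFeatures:
    def test_unit_variance_gives_zero_and_scaling_adds_two(self):
        rng = np.random.default_rng(0)
        eps = make_epochs(rng, 4, 2, 5000)
        f = logvar_features({"alpha": eps})
        np.testing.assert_allclose(f.values, 0.0, atol=0.1)
        scaled = EpochSet(
            np.e * eps.epochs, eps.labels, eps.block_ids, eps.band, eps.fs, eps.epoch_length_s
        )
        f2 = logvar_features({"alpha": scaled})
        np.testing.assert_allclose(f2.values - f.values, 2.0, atol=1e-12)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(1)
        eps = make_epochs(rng, 3, 2, 40)
        f = logvar_features({"theta": eps})
        for e in range(3):
            for c in range(2):
                xs = eps.epochs[e, c]
                m = sum(xs) / len(xs)
                var = sum((v - m) ** 2 for v in xs) / (len(xs) - 1)
                assert abs(f.values[e, c] - np.log(var)) < 1e-12

    def test_bands_concatenate(self):
        rng = np.random.default_rng(2)
        eps_t = make_epochs(rng, 2, 3, 50)
        eps_a = make_epochs(rng, 2, 3, 50)
        eps_a = EpochSet(
            eps_a.epochs, eps_t.labels, eps_t.block_ids, "alpha", eps_t.fs, eps_t.epoch_length_s
        )
        f = logvar_features({"theta": eps_t, "alpha": eps_a})
        assert f.n_features == 6
        assert f.feature_names[0] == ("theta", 0) and f.feature_names[3] == ("alpha", 0)

    def test_zero_variance_errors(self):
        eps = EpochSet(
            np.ones((1, 2, 50)), np.array(["low"]), np.array([0]), "alpha", 1.0, 50.0
        )
        with pytest.raises(ValueError, match="degenerate component"):
            logvar_features({"alpha": eps})

    def test_covariance_route_equals_time_series_route(self):
        rng = np.random.default_rng(3)
        eps = make_epochs(rng, 4, 5, 100)
        W = rng.standard_normal((5, 3))
        from beamadapt.model_core import FilterBank, apply_filters, _epoch_covariances

        bank = FilterBank(W, W.copy(), "none", "alpha")
        direct = logvar_features({"alpha": apply_filters(bank, eps)})
        via_cov = logvar_from_covariances(
            {"alpha": _epoch_covariances(eps.epochs)}, {"alpha": W}, eps.labels, eps.block_ids
        )
        np.testing.assert_allclose(direct.values, via_cov.values, atol=1e-10)


def _feature_matrix(x, labels):
    names = [("alpha", k) for k in range(x.shape[1])]
    return FeatureMatrix(np.asarray(x, float), names, np.asarray(labels), np.arange(len(labels)))


class TestLda:
    def test_separable_one_dimensional(self):
        x = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        f = _feature_matrix(x, ["low", "low", "high", "high"])
        model = train_lda(f, shrinkage=0.0)
        assert model.weights[0] > 0
        pred, _ = predict(model, f)
        assert list(pred) == ["low", "low", "high", "high"]

    def test_isotropic_covariance_weight_parallel_to_mean_difference(self):
        rng = np.random.default_rng(4)
        mu = np.array([1.0, -0.5, 2.0])
        lo = rng.standard_normal((400, 3))
        hi = rng.standard_normal((400, 3)) + mu
        f = _feature_matrix(np.vstack([lo, hi]), ["low"] * 400 + ["high"] * 400)
        model = train_lda(f, shrinkage=1.0)  # force the isotropic target
        w = model.weights / np.linalg.norm(model.weights)
        d = (hi.mean(0) - lo.mean(0)) / np.linalg.norm(hi.mean(0) - lo.mean(0))
        assert abs(w @ d) > 1 - 1e-8

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((200, 2)) @ np.array([[1.0, 0.4], [0.0, 0.8]])
        labels = np.array(["low"] * 100 + ["high"] * 100)
        x[100:] += [1.0, 2.0]
        f = _feature_matrix(x, labels)
        model = train_lda(f, shrinkage=0.0)
        mu_l, mu_h = x[:100].mean(0), x[100:].mean(0)
        resid = np.vstack([x[:100] - mu_l, x[100:] - mu_h])
        sigma = resid.T @ resid / (200 - 2)
        w_oracle = np.linalg.solve(sigma, mu_h - mu_l)
        np.testing.assert_allclose(model.weights, w_oracle, atol=1e-8)

    def test_single_class_errors(self):
        f = _feature_matrix(np.zeros((3, 1)), ["low", "low", "low"])
        with pytest.raises(ValueError, match="both classes"):
            train_lda(f)


class TestPredict:
    def test_midpoint_decision_zero_is_low(self):
        model = ClassifierModel(np.array([2.0]), -2.0)  # boundary at f = 1
        f = _feature_matrix(np.array([[1.0]]), ["high"])
        pred, dv = predict(model, f)
        assert dv[0] == 0.0 and pred[0] == "low"

    def test_decision_values_affine(self):
        rng = np.random.default_rng(6)
        model = ClassifierModel(rng.standard_normal(3), 0.7)
        f1, f2 = rng.standard_normal(3), rng.standard_normal(3)
        dv = lambda v: predict(model, _feature_matrix(v[None], ["low"]))[1][0]
        assert abs(dv(f1 + f2) - (dv(f1) + dv(f2) - model.bias)) < 1e-12

    def test_dimension_mismatch(self):
        model = ClassifierModel(np.zeros(2), 0.0)
        with pytest.raises(ValueError, match="mismatch"):
            predict(model, _feature_matrix(np.zeros((1, 3)), ["low"]))


class TestScalingInvariance:
    def test_global_scaling_shifts_features_and_preserves_decisions(self):
        rng = np.random.default_rng(7)
        lo = make_epochs(rng, 6, 3, 100, sigma=np.diag([1.0, 1, 1]), label="low")
        hi = make_epochs(rng, 6, 3, 100, sigma=np.diag([4.0, 1, 1]), label="high")
        eps = EpochSet(
            np.concatenate([lo.epochs, hi.epochs]),
            np.r_[lo.labels, hi.labels],
            np.arange(12),
            "alpha",
            200.0,
            0.5,
        )
        f1 = logvar_features({"alpha": eps})
        scaled = EpochSet(3.0 * eps.epochs, eps.labels, eps.block_ids, "alpha", 200.0, 0.5)
        f2 = logvar_features({"alpha": scaled})
        np.testing.assert_allclose(f2.values - f1.values, 2 * np.log(3.0), atol=1e-12)
        p1 = predict(train_lda(f1, 0.1), f1)[0]
        p2 = predict(train_lda(f2, 0.1), f2)[0]
        np.testing.assert_array_equal(p1, p2)
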