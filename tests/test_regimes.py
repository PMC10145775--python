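"""Regime slicing, the per-regime feature vector and the cascade classifier."""

import numpy as np
import pytest

from gaitring import regimes, synthetic
from gaitring.preprocess import CHANNELS, ImuRecording
from gaitring.regimes import (
    FEATURE_NAMES,
    extract_features,
    fit_classifiers,
    n_components_99,
    predict_labels,
    slice_regimes,
)


def make_recording(channels: dict, fs=100.0):
    n = len(next(iter(channels.values())))
    kw = {c: np.asarray(channels.get(c, np.zeros(n)), dtype=float) for c in CHANNELS}
    return ImuRecording(fs, **kw)


@pytest.fixture(scope="module")
def class_prototypes():
    """Noiseless prototype regimes, several per class, from the generator."""
    feats, labs = [], []
    for seed in range(6):
        rng = np.random.default_rng(seed)
        k = synthetic.GaitKnobs(noise_sd=0.01)
        walk = synthetic.generate_walking_segment(k, 12, 100, rng)
        sed = synthetic.generate_activity_segment("sedentary", 12, 100, rng)
        non = synthetic.generate_activity_segment("non_sedentary", 12, 100, rng)
        for block, lab in ((walk, "walking"), (sed, "sedentary"), (non, "non_sedentary")):
            feats.append(extract_features(make_recording(block)))
            labs.append(lab)
    return feats, labs


class TestSliceRegimes:
    def test_no_breakpoints_single_regime(self, short_annotated):
        rec = short_annotated.recording
        out = slice_regimes(rec, [])
        assert len(out) == 1
        assert out[0].span == (0.0, rec.duration_s)

    def test_half_open_partition(self, short_annotated):
        rec = short_annotated.recording
        out = slice_regimes(rec, [10.0, 20.0])
        assert [r.span for r in out] == [(0.0, 10.0), (10.0, 20.0), (20.0, rec.duration_s)]
        assert sum(r.samples.n_samples for r in out) == rec.n_samples

    def test_exterior_breakpoint_rejected(self, short_annotated):
        with pytest.raises(ValueError):
            slice_regimes(short_annotated.recording, [500.0])


class TestExtractFeatures:
    def test_constant_channel_statistics(self):
        rec = make_recording({"acc_ml": np.full(300, 2.5)})
        f = extract_features(rec).as_dict()
        assert f["mean_acc_ml"] == 2.5
        assert f["std_acc_ml"] == 0.0
        assert f["var_acc_ml"] == 0.0
        assert f["min_acc_ml"] == f["max_acc_ml"] == 2.5
        assert f["RMS_acc_ml"] == 2.5
        assert f["CV_acc_ml"] == 0.0  # imputed on zero variance
        assert f["F0_acc_ml"] == 0.0

    def test_sinusoid_dominant_frequency(self):
        t = np.arange(1000) / 100.0
        rec = make_recording({"gyr_ap": np.sin(2 * np.pi * 2.0 * t)})
        f = extract_features(rec).as_dict()
        assert f["F0_gyr_ap"] == pytest.approx(2.0, abs=0.1)

    def test_nearest_rank_percentile(self):
        # toy series [1,2,3,4]: 75th percentile rank R = 3 -> third value
        x = np.tile([1.0, 2.0, 3.0, 4.0], 50)  # length 200, same sorted ranks
        rec = make_recording({"acc_cc": x})
        f = extract_features(rec).as_dict()
        assert f["p75_acc_cc"] == 3.0
        assert f["p25_acc_cc"] == 1.0
        assert f["p95_acc_cc"] == 4.0

    def test_vector_shape_and_order_stable(self, short_annotated):
        rec = short_annotated.recording.slice_seconds(0, 10)
        a = extract_features(rec)
        b = extract_features(rec)
        assert a.names == FEATURE_NAMES
        assert len(a.values) == 6 * 21 + 3
        np.testing.assert_array_equal(a.values, b.values)

    def test_too_short_regime_rejected(self):
        with pytest.raises(ValueError, match="1 s"):
            extract_features(make_recording({"acc_cc": np.zeros(50)}))

    def test_stationary_regime_crop_invariance(self):
        """Features of a stationary periodic regime barely move when 5% is
        cropped off either end (regime-level stationarity rationale).
        Periodogram peak *powers* scale with segment length by construction
        and are excluded; all other features must be stable."""
        k = synthetic.GaitKnobs(step_freq_hz=2.0, timing_jitter_sd=0.0, noise_sd=0.0)
        block = synthetic.generate_walking_segment(k, 20, 100, np.random.default_rng(0))
        rec = make_recording(block)
        full = extract_features(rec)
        crop = extract_features(rec.slice_seconds(1.0, 19.0))
        for name, v0, v1 in zip(FEATURE_NAMES, full.values, crop.values):
            # periodogram peak power scales with segment length; the
            # middle-two-thirds percentiles move with their window
            if name.startswith(("PD0", "PD2", "p75m", "p25m", "p85m", "p15m")):
                continue
            # ddof-1 moments carry a sqrt(n/(n-1)) finite-size factor, so
            # agreement is to ~3e-5 relative at these lengths, not exact
            assert v1 == pytest.approx(v0, rel=1e-4, abs=1e-6), name


class TestProjection:
    def test_component_count_matches_eigen_spectrum(self, rng):
        latent = rng.normal(size=(200, 4)) * np.array([10.0, 5.0, 1.0, 0.1])
        mixing = rng.normal(size=(4, 30))
        X = latent @ mixing
        m = n_components_99(X)
        # oracle: eigenvalues of the covariance, cumulated
        ev = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        cum = np.cumsum(ev) / ev.sum()
        assert m == int(np.argmax(cum >= 0.99 - 1e-12)) + 1


class TestCascade:
    def test_separable_clouds_fit_perfectly(self, rng):
        X = np.vstack([
            rng.normal(0, 0.1, (20, 5)) + [5, 0, 0, 0, 0],
            rng.normal(0, 0.1, (20, 5)) + [-5, 5, 0, 0, 0],
            rng.normal(0, 0.1, (20, 5)) + [-5, -5, 0, 0, 0],
        ])
        y = ["walking"] * 20 + ["non_sedentary"] * 20 + ["sedentary"] * 20
        model = fit_classifiers(list(X), y)
        assert predict_labels(model, list(X)) == y

    def test_prototype_regimes_recovered(self, class_prototypes):
        feats, labs = class_prototypes
        model = fit_classifiers(feats, labs)
        assert predict_labels(model, feats) == labs

    def test_walking_never_reaches_stage_two(self, class_prototypes):
        """Cascade contract: stage-1 walking wins outright; relabeling the
        stage-2 data cannot change any walking prediction."""
        feats, labs = class_prototypes
        model = fit_classifiers(feats, labs)
        flipped = regimes.RegimeClassifier(
            feat_mean=model.feat_mean, feat_sd=model.feat_sd,
            components=model.components, w1=model.w1, b1=model.b1,
            w2=-model.w2, b2=-model.b2,
        )
        walk_idx = [i for i, lab in enumerate(labs) if lab == "walking"]
        preds = predict_labels(flipped, feats)
        assert all(preds[i] == "walking" for i in walk_idx)

    def test_label_conservation(self, class_prototypes):
        feats, labs = class_prototypes
        model = fit_classifiers(feats, labs)
        preds = predict_labels(model, feats)
        assert len(preds) == len(feats)
        assert set(preds) <= set(regimes.LABELS)

    def test_single_class_stage_rejected(self, class_prototypes):
        feats, labs = class_prototypes
        only_walk = ["walking"] * len(labs)
        with pytest.raises(ValueError, match="stage 1"):
            fit_classifiers(feats, only_walk)
        no_sed = ["walking" if lab == "sedentary" else lab for lab in labs]
        with pytest.raises(ValueError, match="stage 2"):
            fit_classifiers(feats, no_sed)

    def test_feature_length_mismatch_rejected(self, class_prototypes):
        feats, labs = class_prototypes
        model = fit_classifiers(feats, labs)
        with pytest.raises(ValueError, match="mismatch"):
            predict_labels(model, [np.zeros(5)])

    def test_json_round_trip(self, class_prototypes, tmp_path):
        feats, labs = class_prototypes
        model = fit_classifiers(feats, labs)
        p = tmp_path / "clf.json"
        model.to_json(p)
        back = regimes.RegimeClassifier.from_json(p)
        assert predict_labels(back, feats) == predict_labels(model, feats)
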