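"""Spot detection and Fisher-linear-discriminant classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from focimetry.foci import (
    DegenerateTrainingError,
    FldModel,
    SingularScatterError,
    SpotCandidate,
    SpotDetectionParams,
    detect_candidates,
    fld_classify,
    fld_finetune,
    fld_train,
)


def _field_with_foci(centers, amplitude=300.0, sigma=1.62, shape=(96, 96), background=10.0):
    img = np.full(shape, background)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for r0, c0 in centers:
        img += amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    labels = np.zeros(shape, dtype=np.int32)
    labels[8:-8, 8:-8] = 1  # one big nucleus covering the interior
    return img, labels


class TestDetectCandidates:
    def test_uniform_image_has_no_candidates(self):
        img, labels = _field_with_foci([])
        assert detect_candidates(img, labels) == []

    def test_single_focus_location_and_integral(self):
        sigma = 1.62
        amp = 300.0
        img, labels = _field_with_foci([(48, 48)], amplitude=amp, sigma=sigma)
        (cand,) = detect_candidates(img, labels)
        assert np.hypot(cand.centroid_px[0] - 48, cand.centroid_px[1] - 48) <= 1.0
        assert cand.integrated_intensity == pytest.approx(amp * 2 * np.pi * sigma**2, rel=0.10)
        assert cand.nucleus_label == 1
        assert 0 <= cand.roundness <= 1

    def test_two_separated_foci_stay_separate(self):
        img, labels = _field_with_foci([(48, 43), (48, 53)])  # 10 px apart
        cands = detect_candidates(img, labels)
        assert len(cands) == 2

    def test_candidates_outside_nuclei_discarded(self):
        img, _ = _field_with_foci([(48, 48)])
        labels = np.zeros_like(img, dtype=np.int32)  # no nuclei at all
        assert detect_candidates(img, labels) == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            detect_candidates(np.zeros((8, 8)), np.zeros((9, 9), dtype=np.int32))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SpotDetectionParams(min_sigma_px=3.0, max_sigma_px=1.0)


WORKED_FOCUS = np.array([[2.0, 0.0], [3.0, 1.0]])
WORKED_BACKGROUND = np.array([[0.0, 0.0], [1.0, -1.0]])


class TestFldTrain:
    def test_worked_example_closed_form(self):
        # S_W = I, w = mu1 - mu0 = (2, 1), t = midpoint of projections = 3.0
        model = fld_train(WORKED_FOCUS, WORKED_BACKGROUND, ridge=0.0)
        assert np.allclose(model.scatter_within, np.eye(2))
        assert np.allclose(model.w, [2.0, 1.0])
        assert model.threshold == pytest.approx(3.0)

    def test_isotropic_scatter_aligns_w_with_mean_difference(self):
        # exactly isotropic classes (S_W proportional to I): w parallel to mu1 - mu0
        delta = np.array([3.0, -2.0])
        base = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]])
        model = fld_train(base + delta, base, ridge=0.0)
        cos = model.w @ delta / (np.linalg.norm(model.w) * np.linalg.norm(delta))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_identical_means_degenerate(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(DegenerateTrainingError):
            fld_train(X, X)

    def test_singular_scatter_requires_ridge(self):
        # both classes constant along axis 1 -> rank-deficient scatter
        focus = np.array([[1.0, 5.0], [2.0, 5.0]])
        background = np.array([[0.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SingularScatterError, match="ridge"):
            fld_train(focus, background, ridge=0.0)
        model = fld_train(focus, background, ridge=1e-6)
        assert np.linalg.norm(model.w) > 0

    def test_matches_fisher_criterion_grid_search(self, rng):
        # oracle: maximize J(w) over a fine grid of 2D directions
        angles = np.deg2rad(np.arange(0, 180, 0.1))
        directions = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        for _ in range(20):
            f = rng.normal(size=(12, 2)) @ rng.normal(size=(2, 2)) + rng.normal(size=2) * 3
            b = rng.normal(size=(12, 2)) @ rng.normal(size=(2, 2))
            model = fld_train(f, b, ridge=0.0)
            sw = model.scatter_within
            delta = model.mu_focus - model.mu_background
            J = (directions @ delta) ** 2 / np.einsum("ij,jk,ik->i", directions, sw, directions)
            best = directions[np.argmax(J)]
            cos = abs(best @ model.w) / (np.linalg.norm(best) * np.linalg.norm(model.w))
            assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_serialization_roundtrip(self, tmp_path):
        model = fld_train(WORKED_FOCUS, WORKED_BACKGROUND, ridge=0.0)
        back = FldModel.load(model.save(tmp_path / "model.json"))
        assert np.allclose(back.w, model.w)
        assert back.threshold == model.threshold
        assert back.feature_names == model.feature_names
        assert np.allclose(back.scatter_focus, model.scatter_focus)


def _candidate(**feats) -> SpotCandidate:
    base = dict(
        nucleus_label=1, centroid_px=(0.0, 0.0), scale_px=1.5, response=10.0,
        peak_intensity=100.0, integrated_intensity=500.0, area_px=5,
        contrast=3.0, roundness=0.9,
    )
    base.update(feats)
    return SpotCandidate(**base)


class TestFldClassify:
    @pytest.fixture()
    def worked_model(self):
        model = fld_train(WORKED_FOCUS, WORKED_BACKGROUND, ridge=0.0)
        # re-key to two real candidate features so classify can read them
        model.feature_names = ("peak_intensity", "contrast")
        return model

    def test_scores_at_class_means(self, worked_model):
        at_mu1 = _candidate(peak_intensity=2.5, contrast=0.5)
        at_mu0 = _candidate(peak_intensity=0.5, contrast=-0.5)
        out = fld_classify(worked_model, [at_mu1, at_mu0])
        assert out[0].score == pytest.approx(2.5)
        assert out[0].accepted
        assert out[1].score == pytest.approx(-2.5)
        assert not out[1].accepted

    def test_empty_candidate_list(self, worked_model):
        assert fld_classify(worked_model, []) == []

    def test_missing_feature_named(self, worked_model):
        worked_model.feature_names = ("peak_intensity", "no_such_feature")
        with pytest.raises(KeyError, match="no_such_feature"):
            fld_classify(worked_model, [_candidate()])

    def test_order_preserved(self, worked_model):
        cands = [_candidate(peak_intensity=float(v)) for v in (5, 1, 3)]
        out = fld_classify(worked_model, cands)
        assert [c.peak_intensity for c in out] == [5.0, 1.0, 3.0]


class TestFldFinetune:
    def test_no_new_examples_is_identity(self):
        model = fld_train(WORKED_FOCUS, WORKED_BACKGROUND, ridge=0.0)
        same = fld_finetune(model)
        assert np.allclose(same.w, model.w)
        assert same.threshold == model.threshold
        assert same.n_focus == model.n_focus

    def test_equals_training_on_pooled_data(self, rng):
        for _ in range(10):
            fa, fb = rng.normal(size=(8, 3)) + 2, rng.normal(size=(5, 3)) + 2
            ba, bb = rng.normal(size=(7, 3)), rng.normal(size=(6, 3))
            pooled = fld_train(np.vstack([fa, fb]), np.vstack([ba, bb]), ridge=1e-3)
            tuned = fld_finetune(fld_train(fa, ba, ridge=1e-3), fb, bb)
            assert np.allclose(tuned.w, pooled.w)
            assert tuned.threshold == pytest.approx(pooled.threshold)
            assert np.allclose(tuned.scatter_within, pooled.scatter_within)

    def test_one_class_update_keeps_other(self, rng):
        model = fld_train(rng.normal(size=(6, 2)) + 3, rng.normal(size=(6, 2)), ridge=1e-3)
        tuned = fld_finetune(model, new_focus=rng.normal(size=(4, 2)) + 3)
        assert tuned.n_focus == 10
        assert tuned.n_background == model.n_background
        assert np.allclose(tuned.mu_background, model.mu_background)


class TestScaleEquivariance:
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(0, 100),
    )
    def test_feature_scaling_preserves_decisions(self, scale, seed):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=(10, 3)) + [2, 0, 1]
        b = rng.normal(size=(10, 3))
        X = rng.normal(size=(25, 3)) + [1, 0, 0.5]
        model = fld_train(f, b, ridge=0.0)
        scaled = fld_train(f * scale, b * scale, ridge=0.0)
        assert np.array_equal(
            model.decision_scores(X) > 0, scaled.decision_scores(X * scale) > 0
        )
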