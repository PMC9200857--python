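"""Motor feature distributions and the age-normative BIMS model."""

import numpy as np
import pytest

from maiju.bims import (
    AGE_MAX,
    AgeNormativeModel,
    GaussianBinNormativeModel,
    N_FEATURES,
    N_MOV,
    N_POST,
    aims_predict,
    bims_score,
    compute_distributions,
    length_robustness,
    loso_evaluate,
)
from maiju.simulate import SimConfig, generate_age_cohort, simulate_state_sequence
from maiju.taxonomy import FUSED_MOVEMENTS, FUSED_POSTURES, MOVEMENTS, POSTURES


class TestRescaling:
    @pytest.mark.parametrize("age,score", [(4.0, 0.0), (10.0, 50.0), (16.0, 100.0)])
    def test_endpoints_and_midpoint(self, age, score):
        assert bims_score(age) == pytest.approx(score)


class TestDistributions:
    def test_all_prone_still(self):
        n = 100
        post = np.full(n, POSTURES.index("prone"))
        mov = np.full(n, MOVEMENTS.index("still"))
        mfv = compute_distributions(post, mov)
        expect_post = np.zeros(N_POST)
        expect_post[FUSED_POSTURES.index("prone")] = 1.0
        assert np.allclose(mfv.values[:N_POST], expect_post)
        prone_blk = mfv.values[N_POST + 1 * N_MOV:N_POST + 2 * N_MOV]
        assert prone_blk[FUSED_MOVEMENTS.index("still")] == 1.0

    def test_carrying_mask_reduces_denominator(self):
        post = np.array([0] * 50 + [6] * 50)
        mov = np.zeros(100, int)
        retained = np.arange(100) < 50
        mfv = compute_distributions(post, mov, retained)
        assert mfv.n_retained == 50
        assert mfv.values[FUSED_POSTURES.index("supine")] == 1.0

    def test_matches_simulator_occupancy(self):
        seq = simulate_state_sequence(SimConfig(age_months=11, duration_s=2000,
                                                seed=3))
        mfv = compute_distributions(seq.posture, seq.movement)
        from maiju.bims import _POSTURE_TO_FUSED
        emp = np.bincount(_POSTURE_TO_FUSED[seq.posture], minlength=N_POST)
        assert np.allclose(mfv.values[:N_POST], emp / emp.sum())

    def test_empty_retained_set_rejected(self):
        with pytest.raises(ValueError, match="retained"):
            compute_distributions(np.zeros(5, int), np.zeros(5, int),
                                  np.zeros(5, bool))

    def test_unsupported_block_flagged(self):
        post = np.full(10, POSTURES.index("supine"))
        mov = np.zeros(10, int)
        mfv = compute_distributions(post, mov)
        assert mfv.support[FUSED_POSTURES.index("standing")] == 0
        x = mfv.with_nan_unsupported()
        stand_blk = x[N_POST + 5 * N_MOV:N_POST + 6 * N_MOV]
        assert np.all(np.isnan(stand_blk))


class TestAgeBins:
    def test_sigma_floor_on_identical_members(self):
        X = np.tile(np.linspace(0, 1, N_FEATURES), (3, 1))
        model = AgeNormativeModel().fit(X, np.array([10.0, 10.2, 9.8]))
        b = np.flatnonzero(model.centers_ == 10)[0]
        assert np.all(model.sigmas_[b] == 1e-4)

    def test_ages_over_16_pool_into_top_bin(self):
        rng = np.random.default_rng(0)
        X = rng.random((6, 4))
        ages = np.array([5.0, 8.0, 12.0, 30.0, 15.5, 16.5])
        model = GaussianBinNormativeModel(
            centers=np.arange(4.0, 17.0), window=1.0, clip_max=16.0).fit(X, ages)
        b16 = np.flatnonzero(model.centers_ == 16)[0]
        # 30-month and 16.5-month recordings clip to 16 -> members of bin 16
        assert model.n_members_[b16] >= 3

    def test_bin_fill_to_three_members(self):
        # only 2 recordings within +/-1 of the 6-month bin: nearest third joins
        X = np.random.default_rng(1).random((5, 3))
        ages = np.array([5.5, 6.5, 9.0, 12.0, 15.0])
        model = GaussianBinNormativeModel(centers=np.array([6.0]),
                                          window=1.0).fit(X, ages)
        assert model.n_members_[0] == 3


class TestPrediction:
    def test_single_bin_model_predicts_center(self):
        X = np.random.default_rng(2).random((4, 5))
        model = GaussianBinNormativeModel(centers=np.array([10.0]),
                                          window=20.0).fit(X, np.full(4, 10.0))
        pred = model.predict_one(X[0])
        assert pred.predicted == pytest.approx(10.0)
        assert bims_score(pred.predicted) == pytest.approx(50.0)

    def test_equal_likelihoods_average_centers(self):
        model = GaussianBinNormativeModel(centers=np.arange(4.0, 17.0))
        model.centers_ = np.arange(4.0, 17.0)
        model.means_ = np.zeros((13, 4))
        model.sigmas_ = np.ones((13, 4))
        model.n_members_ = np.full(13, 3)
        pred = model.predict_one(np.zeros(4))
        assert pred.predicted == pytest.approx(10.0)
        assert np.allclose(pred.weights, 1 / 13)

    def test_tight_bin_dominates(self):
        rng = np.random.default_rng(3)
        centers = np.arange(4.0, 17.0)
        model = GaussianBinNormativeModel(centers=centers)
        model.centers_ = centers
        model.means_ = rng.random((13, 6))
        model.sigmas_ = np.full((13, 6), 1.0)
        b14 = np.flatnonzero(centers == 14)[0]
        model.sigmas_[b14] = 0.01
        model.n_members_ = np.full(13, 3)
        pred = model.predict_one(model.means_[b14])
        assert abs(pred.predicted - 14.0) < 0.1

    def test_weights_invariant_to_loglik_shift(self):
        # max-subtraction: adding a constant to all log-likelihoods cannot
        # change the weights; verify via two scalings of the same model
        X = np.random.default_rng(4).random((12, 5))
        ages = np.linspace(4, 16, 12)
        model = GaussianBinNormativeModel(centers=np.arange(4.0, 17.0)).fit(X, ages)
        p = model.predict_one(X[0])
        assert p.weights.sum() == pytest.approx(1.0)
        assert 4.0 <= p.predicted <= 16.0


class TestLOSO:
    def test_recovery_on_synthetic_cohort(self):
        coh = generate_age_cohort(60, (4, 16), seed=1)
        res = loso_evaluate(coh.subjects, coh.ages, coh.X)
        assert res["pearson_r"] > 0.9
        assert res["mae"] <= 1.5

    def test_degenerate_cohort_zero_mae(self):
        X = np.tile(np.linspace(0, 1, 8), (6, 1))
        subjects = [f"s{i}" for i in range(6)]
        res = loso_evaluate(subjects, np.full(6, 10.0), X)
        assert res["mae"] == pytest.approx(0.0, abs=1e-6)

    def test_subject_level_holdout(self):
        # two recordings of one subject must never predict each other
        coh = generate_age_cohort(12, (4, 16), seed=2)
        subjects = [f"s{i // 2}" for i in range(12)]  # paired recordings
        res = loso_evaluate(subjects, coh.ages, coh.X)
        assert len(res["predictions"]) == 12  # runs without leakage assertion


@pytest.fixture(scope="module")
def robustness_setup():
    coh = generate_age_cohort(40, (4, 16), seed=3)
    model = AgeNormativeModel().fit(coh.X, coh.ages)
    recs = []
    for i, age in enumerate([5.0, 9.0, 13.0]):
        seq = simulate_state_sequence(
            SimConfig(age_months=age, duration_s=125 * 60, seed=50 + i))
        recs.append(dict(posture=seq.posture, movement=seq.movement, age=age))
    return model, recs


class TestLengthRobustness:

    def test_full_length_matches_direct_prediction(self, robustness_setup):
        model, recs = robustness_setup
        rec = recs[0]
        res = length_robustness([rec], model, lengths_min=(125,), n_iter=3, seed=0)
        mfv = compute_distributions(rec["posture"], rec["movement"])
        direct = abs(model.predict_one(mfv.with_nan_unsupported()).predicted
                     - rec["age"])
        assert res[125]["median"] == pytest.approx(direct, abs=1e-9)

    def test_error_shrinks_with_length(self, robustness_setup):
        model, recs = robustness_setup
        res = length_robustness(recs, model, lengths_min=(10, 60), n_iter=50,
                                seed=1)
        assert res[60]["median"] <= res[10]["median"]

    def test_long_segments_skipped_with_warning(self, robustness_setup):
        model, recs = robustness_setup
        with pytest.warns(UserWarning, match="skipped"):
            res = length_robustness(recs, model, lengths_min=(200,), n_iter=2,
                                    seed=2)
        assert res == {}

    def test_seed_reproducibility(self, robustness_setup):
        model, recs = robustness_setup
        a = length_robustness(recs, model, lengths_min=(20,), n_iter=20, seed=5)
        b = length_robustness(recs, model, lengths_min=(20,), n_iter=20, seed=5)
        assert a == b


class TestAimsPredictor:
    def test_affine_score_recovered(self):
        coh = generate_age_cohort(40, (4, 16), seed=4)
        scores = 3.0 * coh.ages + 5.0  # clinical score affine in age
        res = aims_predict(coh.subjects, scores, coh.X, bin_width=5.0)
        assert len(res["predictions"]) == 40
        assert res["pearson_r"] > 0.9

    def test_too_few_scored_recordings(self):
        with pytest.raises(ValueError, match="recordings"):
            aims_predict(["a", "b"], np.array([1.0, 2.0]), np.zeros((2, 4)))
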