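"""Synthetic-data generator: occupancy recovery, physical consistency,
rater-noise behavior, cohort structure, determinism."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from maiju.annotations import fleiss_kappa
from maiju.simulate import (
    Cohort,
    DEFAULT_CARRYING_PRIOR,
    NoiseParams,
    SimConfig,
    default_confusions,
    generate_age_cohort,
    mean_feature_vector,
    posture_prior,
    simulate_raters,
    simulate_state_sequence,
    synthesize_imu,
)
from maiju.taxonomy import MOVEMENTS, POSTURES, SAMPLE_RATE, SENSORS

from conftest import make_recording


class TestStateSequence:
    def test_degenerate_prior_gives_all_prone(self):
        cfg = SimConfig(duration_s=100, posture_prior_override={"prone": 1.0})
        seq = simulate_state_sequence(cfg)
        assert np.all(seq.posture == POSTURES.index("prone"))

    def test_empirical_standing_fraction_tracks_prior(self):
        cfg = SimConfig(age_months=14.0, duration_s=3600, seed=1)
        seq = simulate_state_sequence(cfg)
        prior = posture_prior(cfg)
        frac = np.mean(seq.posture == POSTURES.index("standing"))
        assert abs(frac - prior[POSTURES.index("standing")]) < 0.05

    def test_occupancy_l1_convergence(self):
        cfg = SimConfig(age_months=9.0, duration_s=10_000, seed=3)
        seq = simulate_state_sequence(cfg)
        prior = posture_prior(cfg)
        emp = np.bincount(seq.posture, minlength=len(POSTURES)) / seq.n_seconds
        assert np.abs(emp - prior).sum() < 0.03

    def test_movement_respects_posture_compatibility(self):
        cfg = SimConfig(age_months=13.0, duration_s=2000, seed=5)
        seq = simulate_state_sequence(cfg)
        supine = seq.posture == POSTURES.index("supine")
        assert not np.any(seq.movement[supine] == MOVEMENTS.index("fluent"))

    def test_determinism(self):
        cfg = SimConfig(age_months=8.0, duration_s=300, seed=7)
        a = simulate_state_sequence(cfg)
        b = simulate_state_sequence(cfg)
        assert np.array_equal(a.posture, b.posture)
        assert np.array_equal(a.movement, b.movement)
        assert np.array_equal(a.carrying, b.carrying)

    def test_invalid_age_rejected(self):
        with pytest.raises(ValueError, match="age"):
            simulate_state_sequence(SimConfig(age_months=-1.0))

    def test_dwell_times_near_configured_mean(self):
        cfg = SimConfig(age_months=10.0, duration_s=20_000, seed=11)
        seq = simulate_state_sequence(cfg)
        bounds = np.flatnonzero(np.diff(seq.posture)) + 1
        dwells = np.diff(np.concatenate(([0], bounds, [seq.n_seconds])))
        # scheduler may draw the same state twice (merged runs), so the mean
        # run length is at least the configured dwell
        assert cfg.dwell.posture_s * 0.8 < dwells.mean() < cfg.dwell.posture_s * 2.5


class TestImuSynthesis:
    @staticmethod
    def _static_cfg(**kw):
        noise = NoiseParams(accel_noise_sd=0.0, gyro_noise_sd=0.0,
                            gyro_bias_range=0.0, packet_jitter_sd=0.0,
                            packet_drop_p=0.0)
        return SimConfig(duration_s=30, noise=noise, dynamics_scale=0.0, **kw)

    def test_static_accel_reads_gravity_exactly(self):
        cfg = self._static_cfg(posture_prior_override={"supine": 1.0},
                               movement_prior_override={"still": 1.0},
                               carrying_prior_override={"independent": 1.0})
        seq = simulate_state_sequence(cfg)
        rec = synthesize_imu(seq, cfg)
        for s in SENSORS:
            acc = rec.streams[s][:, 1:4]
            assert np.allclose(np.linalg.norm(acc, axis=1), 9.81)

    def test_static_gyro_reads_exact_bias(self):
        noise = NoiseParams(accel_noise_sd=0.0, gyro_noise_sd=0.0,
                            gyro_bias_range=2.0, packet_jitter_sd=0.0,
                            packet_drop_p=0.0)
        cfg = SimConfig(duration_s=30, noise=noise, dynamics_scale=0.0,
                        posture_prior_override={"prone": 1.0},
                        movement_prior_override={"still": 1.0},
                        carrying_prior_override={"independent": 1.0})
        seq = simulate_state_sequence(cfg)
        rec = synthesize_imu(seq, cfg)
        for s in SENSORS:
            gyr = rec.streams[s][:, 4:7]
            assert np.allclose(gyr, rec.gyro_bias_true[s][None, :])

    def test_fluent_band_power_exceeds_still(self):
        cfg = SimConfig(duration_s=120, seed=2,
                        posture_prior_override={"standing": 1.0},
                        carrying_prior_override={"independent": 1.0})
        seq = simulate_state_sequence(cfg)
        rec = synthesize_imu(seq, cfg)
        x = rec.streams["left_arm"]
        sec = np.minimum(np.arange(len(x)) // 52, seq.n_seconds - 1)

        def band_power(mask):
            seg = x[mask, 1]
            f, p = sps.welch(seg - seg.mean(), fs=SAMPLE_RATE, nperseg=128)
            return p[(f >= 0.5) & (f <= 10)].sum()

        still = seq.movement[sec] == MOVEMENTS.index("still")
        fluent = seq.movement[sec] == MOVEMENTS.index("fluent")
        if still.sum() < 200 or fluent.sum() < 200:
            pytest.skip("draw lacks both movement classes")
        assert band_power(fluent) > band_power(still)

    def test_sample_count_without_drops(self):
        noise = NoiseParams(packet_drop_p=0.0)
        cfg = SimConfig(duration_s=60, seed=3, noise=noise)
        seq = simulate_state_sequence(cfg)
        rec = synthesize_imu(seq, cfg)
        for s in SENSORS:
            assert abs(rec.streams[s].shape[0] - 60 * 52) <= 1

    def test_timestamps_strictly_increasing(self):
        cfg = SimConfig(duration_s=60, seed=4)
        seq = simulate_state_sequence(cfg)
        rec = synthesize_imu(seq, cfg)
        for s in SENSORS:
            assert np.all(np.diff(rec.streams[s][:, 0]) > 0)

    def test_determinism(self):
        _, _, a = make_recording(seed=9)
        _, _, b = make_recording(seed=9)
        for s in SENSORS:
            assert np.array_equal(a.streams[s], b.streams[s])


class TestRaterSimulation:
    def test_identity_confusion_reproduces_truth(self):
        cfg = SimConfig(age_months=9, duration_s=500, seed=1)
        seq = simulate_state_sequence(cfg)
        ident = {t: np.eye(k) for t, k in
                 (("posture", 7), ("movement", 9), ("carrying", 5))}
        ann = simulate_raters(seq, confusion=ident, boundary_jitter_s=0.0,
                              n_raters=3, seed=0)
        for r in range(3):
            assert np.array_equal(ann.data["posture"][r], seq.posture)
        assert fleiss_kappa(ann, track="posture") == pytest.approx(1.0)

    def test_uniform_confusion_gives_chance_kappa(self):
        cfg = SimConfig(age_months=9, duration_s=10_000, seed=2)
        seq = simulate_state_sequence(cfg)
        uni = {t: np.full((k, k), 1.0 / k) for t, k in
               (("posture", 7), ("movement", 9), ("carrying", 5))}
        ann = simulate_raters(seq, confusion=uni, boundary_jitter_s=0.0,
                              n_raters=3, seed=3)
        assert abs(fleiss_kappa(ann, track="posture")) < 0.05

    def test_single_rater_rejected(self):
        cfg = SimConfig(duration_s=10)
        seq = simulate_state_sequence(cfg)
        with pytest.raises(ValueError, match="raters"):
            simulate_raters(seq, n_raters=1)

    def test_unnormalized_confusion_rejected(self):
        cfg = SimConfig(duration_s=10)
        seq = simulate_state_sequence(cfg)
        bad = default_confusions()
        bad["posture"] = bad["posture"] * 2
        with pytest.raises(ValueError, match="normalize"):
            simulate_raters(seq, confusion=bad)

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(duration_s=200, seed=5)
        seq = simulate_state_sequence(cfg)
        a = simulate_raters(seq, n_raters=3, seed=11)
        b = simulate_raters(seq, n_raters=3, seed=11)
        for t in a.data:
            assert np.array_equal(a.data[t], b.data[t])


class TestAgeCohort:
    def test_infinite_concentration_returns_means(self):
        coh = generate_age_cohort(5, seed=1, concentration=np.inf)
        for age, x in zip(coh.ages, coh.X):
            assert np.allclose(x, mean_feature_vector(SimConfig(age_months=age)))

    def test_blocks_are_simplices(self):
        coh = generate_age_cohort(20, seed=2)
        assert np.allclose(coh.X[:, :6].sum(axis=1), 1.0)
        for p in range(6):
            blk = coh.X[:, 6 + 7 * p:6 + 7 * (p + 1)]
            assert np.allclose(blk.sum(axis=1), 1.0)

    def test_standing_fraction_increases_with_age(self):
        coh = generate_age_cohort(60, (4, 16), seed=3)
        standing = coh.X[:, 5]  # fused posture block, standing column
        rho = stats.spearmanr(coh.ages, standing).statistic
        assert rho > 0.8

    def test_bad_args_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            generate_age_cohort(10, concentration=0.0)
        with pytest.raises(ValueError, match="n_recordings"):
            generate_age_cohort(1)

    def test_seed_reproducibility(self):
        a = generate_age_cohort(10, seed=4)
        b = generate_age_cohort(10, seed=4)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.ages, b.ages)
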