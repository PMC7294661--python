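"""Calibration (Hosmer-Lemeshow) and added-value statistics (NRI, IDI)."""

import numpy as np
import pytest

from cipdus import (
    canonical_weights,
    compare_models,
    generate_cohort,
    hosmer_lemeshow,
    published_cohort_config,
    reclassification,
)


def printed_count_vectors():
    """Probability pairs realizing the published reclassification counts:
    14 events up / 4 down (of 22), 18 non-events down / 9 up (of 54)."""
    y = np.array([1] * 22 + [0] * 54)
    old = np.full(76, 0.5)
    new = old.copy()
    new[:14] += 0.1          # 14 events up
    new[14:18] -= 0.1        # 4 events down
    new[22:40] -= 0.1        # 18 non-events down
    new[40:49] += 0.1        # 9 non-events up
    return old, new, y


def brute_force_nri(p_old, p_new, y):
    up_e = down_e = up_n = down_n = 0
    for o, n, yy in zip(p_old, p_new, y):
        if yy == 1:
            up_e += n > o
            down_e += n < o
        else:
            up_n += n > o
            down_n += n < o
    ne, nn = int((y == 1).sum()), int((y == 0).sum())
    return 100 * ((up_e - down_e) / ne + (down_n - up_n) / nn)


def two_pass_idi(p_old, p_new, y):
    """Independent discrimination-slope implementation."""
    def slope(p):
        return np.mean(p[y == 1]) - np.mean(p[y == 0])
    return 100 * (slope(np.asarray(p_new)) - slope(np.asarray(p_old)))


class TestReclassification:
    def test_published_counts_give_nri_62_1(self):
        old, new, y = printed_count_vectors()
        res = reclassification(old, new, y)
        assert (res.events_up, res.events_down) == (14, 4)
        assert (res.nonevents_down, res.nonevents_up) == (18, 9)
        assert round(res.nri, 1) == 62.1
        assert res.nri_p < 0.01

    def test_identical_probabilities_give_zero_with_p_one(self, rng):
        p = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        y[:2] = [0, 1]
        res = reclassification(p, p, y)
        assert res.nri == 0.0 and res.nri_p == 1.0
        assert res.idi == 0.0 and res.idi_p == 1.0

    def test_raising_every_event_gives_nri_100(self):
        y = np.array([1] * 10 + [0] * 20)
        old = np.full(30, 0.3)
        new = old + np.where(y == 1, 0.05, 0.0)
        assert reclassification(old, new, y).nri == pytest.approx(100.0)

    def test_uniform_event_shift_gives_idi_ten(self, rng):
        y = np.array([1] * 500 + [0] * 500)
        old = rng.uniform(0.2, 0.6, 1000)
        new = old + np.where(y == 1, 0.1, 0.0)
        res = reclassification(old, new, y)
        assert res.idi == pytest.approx(10.0, abs=1e-9)
        assert res.idi_p < 1e-6

    def test_matches_brute_force_tally(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = np.array([1] * max(2, n // 4) + [0] * n)
            old = rng.random(len(y))
            new = rng.random(len(y))
            res = reclassification(old, new, y)
            assert res.nri == pytest.approx(brute_force_nri(old, new, y),
                                            abs=1e-12)
            assert res.idi == pytest.approx(two_pass_idi(old, new, y),
                                            abs=1e-12)

    def test_antisymmetry_under_model_swap(self, rng):
        y = np.array([1] * 30 + [0] * 70)
        old, new = rng.random(100), rng.random(100)
        ab = reclassification(old, new, y)
        ba = reclassification(new, old, y)
        assert ab.nri == pytest.approx(-ba.nri, abs=1e-12)
        assert ab.idi == pytest.approx(-ba.idi, abs=1e-12)
        assert ab.nri_p == pytest.approx(ba.nri_p, abs=1e-12)


class TestHosmerLemeshow:
    def test_expected_events_sum_to_probability_total(self, rng):
        p = rng.uniform(0.05, 0.95, 300)
        y = (rng.random(300) < p).astype(int)
        res = hosmer_lemeshow(p, y)
        assert res.group_table["expected"].sum() == pytest.approx(p.sum())
        assert res.group_table["n"].sum() == 300

    def test_well_calibrated_probabilities_pass(self, rng):
        p = rng.uniform(0.1, 0.9, 2000)
        y = (rng.random(2000) < p).astype(int)
        res = hosmer_lemeshow(p, y)
        assert res.degrees_freedom == 8
        assert res.p_value > 0.001   # gross miscalibration would be ~0

    def test_all_equal_probabilities_do_not_crash(self):
        """Degenerate single-value grouping falls back to positional groups."""
        y = np.array([1] * 6 + [0] * 14)
        p = np.full(20, 0.3)
        res = hosmer_lemeshow(p, y, n_groups=5)
        assert res.chi_square >= 0
        assert len(res.group_table) == 5

    def test_detects_systematic_miscalibration(self):
        """True rate = prob^2: rejected at the 5% level in >80% of seeds."""
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.1, 0.9, 2000)
            y = (rng.random(2000) < p ** 2).astype(int)
            rejections += hosmer_lemeshow(p, y).p_value < 0.05
        assert rejections / n_seeds > 0.8

    def test_configurable_degrees_of_freedom(self, rng):
        p = rng.uniform(0.1, 0.9, 200)
        y = (rng.random(200) < p).astype(int)
        res = hosmer_lemeshow(p, y, degrees_freedom=10)
        assert res.degrees_freedom == 10


class TestCompareModels:
    def test_identical_schemes_show_no_improvement(self, small_cohort):
        scheme = canonical_weights(True)
        cmp = compare_models(small_cohort, scheme, scheme)
        assert cmp.reclassification.nri == 0.0
        assert cmp.reclassification.idi == 0.0
        assert cmp.delong.p_value == 1.0

    def test_full_score_usually_beats_reduced_on_published_structure(self):
        """Imaging features carry real signal, so the full score's AUC should
        be at least the reduced score's in most seeds, and IDI mostly > 0."""
        import dataclasses

        wins = idi_pos = 0
        n_seeds = 15
        cfg = published_cohort_config()
        for seed in range(n_seeds):
            cohort = generate_cohort(dataclasses.replace(cfg, seed=seed))
            cmp = compare_models(cohort, canonical_weights(True),
                                 canonical_weights(False))
            wins += cmp.auc_full >= cmp.auc_reduced
            idi_pos += cmp.reclassification.idi > 0
        assert wins / n_seeds > 0.5
        assert idi_pos / n_seeds > 0.5

    def test_noise_imaging_features_give_centered_nri(self):
        """When FOI and Doppler are pure noise, adding them should not
        systematically improve reclassification."""
        import dataclasses

        from cipdus.cohort import FeatureSpec

        cfg = published_cohort_config()
        features = dict(cfg.features)
        for name in ("foi_missing_enhancement", "cdus_pathologic_gt35"):
            features[name] = FeatureSpec(name=name, p_given_event=0.4,
                                         p_given_nonevent=0.4)
        cfg = dataclasses.replace(cfg, features=features)
        nris = []
        for seed in range(15):
            cohort = generate_cohort(dataclasses.replace(cfg, seed=seed))
            cmp = compare_models(cohort, canonical_weights(True),
                                 canonical_weights(False))
            nris.append(cmp.reclassification.nri)
        assert abs(np.mean(nris)) < 40   # centered, vs ~100 for real signal

    def test_empirical_probability_mapping_flag(self, small_cohort):
        cmp = compare_models(small_cohort, canonical_weights(True),
                             canonical_weights(False), prob_mapping="empirical")
        assert 0.5 < cmp.auc_full <= 1.0
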