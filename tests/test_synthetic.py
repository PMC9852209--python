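"""Unit tests for the synthetic cohort and phantom generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from petsurv.synthetic import (
    CLASS_SUPPORTS,
    KINGS_COUNTS,
    Lesion,
    PhantomConfig,
    default_phantom_config,
    generate_clinical_covariates,
    generate_cohort,
    generate_phantom_volumes,
    generate_survival_times,
    get_preset,
)


class TestSurvivalTimes:
    def test_single_draw_is_one_positive_pair(self):
        times, classes = generate_survival_times("marginal", 1, seed=7)
        assert times.shape == (1,) and classes.shape == (1,)
        assert times[0] > 0

    @pytest.mark.parametrize("preset", ["marginal", "clustered"])
    def test_draws_respect_class_supports(self, preset):
        times, classes = generate_survival_times(preset, 5000, seed=3)
        for c in (1, 2, 3):
            lo, hi = CLASS_SUPPORTS[c]
            sel = classes == c
            assert np.all(times[sel] > lo) and np.all(times[sel] <= hi)

    def test_marginal_quantiles_converge_to_printed_cohort_values(self):
        times, _ = generate_survival_times("marginal", 100_000, seed=11)
        q1, med, q3 = np.percentile(times, [25, 50, 75])
        assert med == pytest.approx(1.45, abs=0.1)
        assert q1 == pytest.approx(0.61, abs=0.1)
        assert q3 == pytest.approx(3.27, abs=0.1)

    def test_clustered_class_means_match_numeric_integration(self):
        """Sample means per class agree with quadrature over each truncated density."""
        times, classes = generate_survival_times("clustered", 10_000, seed=5)

        def truncnorm_mean(mu, sd, lo, hi):
            a, b = (lo - mu) / sd, (hi - mu) / sd
            f = lambda x: x * stats.truncnorm.pdf(x, a, b, loc=mu, scale=sd)
            return integrate.quad(f, lo, hi)[0]

        def truncexp_mean(scale, shift, cap):
            z = 1.0 - np.exp(-(cap - shift) / scale)
            f = lambda x: x * np.exp(-(x - shift) / scale) / (scale * z)
            return integrate.quad(f, shift, cap)[0]

        expected = {
            1: truncnorm_mean(1.0, 0.35, 0.0, 2.0),
            2: truncnorm_mean(3.4, 0.5, 2.0, 5.0),
            3: truncexp_mean(0.8, 5.0, 8.0),
        }
        for c in (1, 2, 3):
            sample = times[classes == c]
            assert sample.mean() == pytest.approx(expected[c], abs=0.05)

    def test_same_seed_bit_identical_different_seed_differs(self):
        a = generate_survival_times("marginal", 400, seed=2)
        b = generate_survival_times("marginal", 400, seed=2)
        c = generate_survival_times("marginal", 400, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not np.array_equal(a[0], c[0])

    def test_unknown_preset_and_bad_n(self):
        with pytest.raises(ValueError, match="unknown"):
            get_preset("weird")
        with pytest.raises(ValueError):
            generate_survival_times("marginal", 0)


class TestClinicalCovariates:
    def test_class2_expected_kings_counts(self):
        """The class-2 King's multinomial expectation reproduces the printed row."""
        probs = np.asarray(KINGS_COUNTS[2], dtype=float)
        expected = probs / probs.sum() * 124
        assert np.allclose(expected, [62, 37, 21, 4])
        # and a large draw concentrates near it
        cov = generate_clinical_covariates(np.full(124 * 50, 2), seed=1)
        observed = cov["kings_stage"].value_counts().reindex([1, 2, 3, 4]).fillna(0) / 50
        assert np.allclose(observed, [62, 37, 21, 4], atol=6)

    def test_long_survivors_never_reach_kings_stage_four(self):
        cov = generate_clinical_covariates(np.full(2000, 3), seed=4)
        assert (cov["kings_stage"] != 4).all()

    def test_fixed_seed_reproducible(self):
        classes = np.repeat([1, 2, 3], 50)
        a = generate_clinical_covariates(classes, seed=9)
        b = generate_clinical_covariates(classes, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_female_fraction_rises_and_age_falls_with_class(self):
        cohort = generate_cohort("marginal", n=20_000, seed=6)
        female = cohort.groupby("true_class")["sex"].apply(lambda s: (s == "F").mean())
        age = cohort.groupby("true_class")["age_years"].mean()
        assert female[1] < female[2] < female[3]
        assert age[1] > age[2] > age[3]


class TestPhantom:
    def test_noiseless_lesion_voxels_are_exact(self):
        cfg = default_phantom_config(n_subjects=1, noise_sd=0.0, amplitude_sd=0.0)
        cohort = pd.DataFrame({"subject_id": ["s0"], "true_class": [1]})
        res = generate_phantom_volumes(cfg, cohort)
        hypo = next(
            lm for lm, les in zip(res.lesion_masks, cfg.lesions)
            if les.class_id == 1 and les.effect < 0
        )
        assert np.allclose(res.volumes[0].data[hypo], 0.9 * cfg.background_mean)

    def test_null_effect_gives_identical_class_means_up_to_noise(self):
        cfg = default_phantom_config(n_subjects=40, noise_sd=0.02)
        cfg.lesions = [Lesion(l.class_id, l.center, l.radius, 0.0) for l in cfg.lesions]
        cohort = generate_cohort("clustered", n=40, seed=0)
        res = generate_phantom_volumes(cfg, cohort)
        labels = cohort["true_class"].to_numpy()
        means = [
            np.mean([v.data[res.mask.data] for v, keep in zip(res.volumes, labels == c) if keep])
            for c in (1, 2) if (labels == c).sum() > 3
        ]
        assert np.ptp(means) < 0.01

    def test_sphere_voxel_count_matches_exhaustive_scan(self):
        cfg = default_phantom_config()
        cfg.lesions = [Lesion(1, (16, 19, 16), 4.0, -0.1)]
        cohort = pd.DataFrame({"subject_id": ["s0"], "true_class": [1]})
        res = generate_phantom_volumes(cfg, cohort)
        count = 0
        for i in range(32):
            for j in range(38):
                for k in range(32):
                    if (i - 16) ** 2 + (j - 19) ** 2 + (k - 16) ** 2 <= 16:
                        count += 1
        assert res.lesion_masks[0].sum() == count

    def test_default_lesions_disjoint_and_inside_mask(self):
        cfg = default_phantom_config(n_subjects=2)
        cohort = pd.DataFrame({"subject_id": ["a", "b"], "true_class": [1, 2]})
        res = generate_phantom_volumes(cfg, cohort)
        assert not res.lesions_overlap
        total = sum(lm.sum() for lm in res.lesion_masks)
        union = np.any(res.lesion_masks, axis=0).sum()
        assert total == union  # pairwise disjoint

    def test_lesion_outside_mask_rejected(self):
        cfg = default_phantom_config(n_subjects=1)
        cfg.lesions = [Lesion(1, (1, 1, 1), 3.5, -0.1)]
        cohort = pd.DataFrame({"subject_id": ["s0"], "true_class": [1]})
        with pytest.raises(ValueError, match="outside"):
            generate_phantom_volumes(cfg, cohort)

    def test_phantom_reproducible_under_seed(self):
        cfg = default_phantom_config(n_subjects=3, seed=42)
        cohort = generate_cohort("clustered", n=3, seed=1)
        a = generate_phantom_volumes(cfg, cohort)
        b = generate_phantom_volumes(cfg, cohort)
        for va, vb in zip(a.volumes, b.volumes):
            assert np.array_equal(va.data, vb.data)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = default_phantom_config(n_subjects=7, seed=3)
        cfg.to_yaml(tmp_path / "phantom.yaml")
        back = PhantomConfig.from_yaml(tmp_path / "phantom.yaml")
        assert back == cfg
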