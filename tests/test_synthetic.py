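"""Synthetic-cohort generator: dimensions, determinism, planted structure,
and the survival generator's calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipistage import (
    SyntheticConfig,
    generate_cohort,
    km_estimate,
    multiomics_config,
    stage_config,
    three_class_config,
)
from lipistage.errors import ConfigurationError


class TestDimensionsAndDeterminism:
    def test_three_class_cohort_shape(self):
        cohort = generate_cohort(three_class_config(seed=0))
        reps = cohort.config.replicate_count
        assert cohort.features.intensities.shape == (66 * reps, 333)
        assert len(cohort.clinical.sample_ids) == 66
        assert cohort.clinical.data["group"].value_counts().to_dict() == {
            "CRC": 32, "CLM": 18, "CFI": 16}

    def test_stage_cohort_shape(self):
        cohort = generate_cohort(stage_config(seed=0))
        assert len(cohort.clinical.sample_ids) == 59
        assert cohort.features.n_features == 289
        stages = cohort.clinical.data.loc[
            cohort.clinical.data["group"] == "CRC", "stage"]
        assert stages.value_counts().to_dict() == {1: 13, 2: 11, 3: 12, 4: 10}

    def test_multiomics_cohort_shape(self):
        cohort = generate_cohort(multiomics_config(seed=0))
        assert len(cohort.clinical.sample_ids) == 48
        assert cohort.features.n_features == 344

    def test_same_seed_bit_identical(self):
        a = generate_cohort(three_class_config(seed=7))
        b = generate_cohort(three_class_config(seed=7))
        pd.testing.assert_frame_equal(a.features.intensities, b.features.intensities)
        pd.testing.assert_frame_equal(a.clinical.data, b.clinical.data)
        assert a.planted_features == b.planted_features

    def test_different_seed_differs(self):
        a = generate_cohort(three_class_config(seed=1))
        b = generate_cohort(three_class_config(seed=2))
        assert not a.features.intensities.equals(b.features.intensities)

    def test_planted_features_subset_of_features(self):
        cohort = generate_cohort(three_class_config(seed=3))
        ids = set(cohort.features.feature_ids)
        assert all(f in ids for f, _ in cohort.planted_features)
        assert all(d in (-1, 1) for _, d in cohort.planted_features)

    def test_sample_alignment_after_collapse(self):
        cohort = generate_cohort(three_class_config(seed=3))
        bio = list(dict.fromkeys(cohort.replicate_map[s]
                                 for s in cohort.features.sample_ids))
        assert bio == cohort.clinical.sample_ids


class TestPlantedEffects:
    def test_null_cohort_t_test_rejection_rate(self):
        """With effect_size 0 every feature is null; the two-sample t-test on
        log intensities should reject at ≈ the nominal 5% level."""
        cfg = SyntheticConfig(
            n_per_class={"CFI": 30, "CRC": 30}, n_features=1000,
            n_informative=0, effect_size=0.0, missing_rate=0.0,
            outlier_rate=0.0,
            survival_median_months={"CFI": 100.0, "CRC": 100.0}, seed=42)
        cohort = generate_cohort(cfg)
        X = np.log(cohort.features.intensities.to_numpy())
        groups = cohort.clinical.data["group"].to_numpy()
        a, b = X[groups == "CFI"], X[groups == "CRC"]
        _, p = stats.ttest_ind(a, b, axis=0)
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.07

    def test_planted_class_means_monotone(self):
        """Planted features shift monotonically with disease severity: the
        empirical class-mean ordering follows the planted direction in ≥95%
        of feature × seed draws."""
        ok = total = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                n_per_class={"CFI": 16, "CRC": 32, "CLM": 18},
                n_features=40, n_informative=9, effect_size=1.0,
                missing_rate=0.0, outlier_rate=0.0, seed=seed)
            cohort = generate_cohort(cfg)
            X = cohort.features.intensities
            codes = cohort.clinical.data["group"].map(
                {"CFI": 0, "CRC": 1, "CLM": 2})
            for feat, direction in cohort.planted_features:
                means = [X.loc[codes.index[codes == c], feat].mean()
                         for c in (0, 1, 2)]
                diffs = np.diff(means) * direction
                total += 1
                ok += bool(np.all(diffs > 0))
        assert ok / total >= 0.95

    def test_no_negative_intensities(self):
        cfg = three_class_config(seed=5, missing_rate=0.0)
        cohort = generate_cohort(cfg)
        assert (cohort.features.intensities.to_numpy() >= 0).all()

    def test_missing_rate_realized(self):
        cohort = generate_cohort(three_class_config(seed=5, missing_rate=0.1))
        frac = cohort.features.intensities.isna().to_numpy().mean()
        assert 0.08 < frac < 0.12


class TestSurvivalGenerator:
    def test_km_median_matches_configured_median(self):
        """With no censoring, the KM median of generated event times
        converges to the configured per-class median (within 15% at n=500)."""
        cfg = SyntheticConfig(
            n_per_class={"CFI": 500, "CLM": 500}, n_features=5,
            n_informative=0, censor_rate=0.0, missing_rate=0.0,
            survival_median_months={"CFI": 100.0, "CLM": 24.0}, seed=9)
        cohort = generate_cohort(cfg)
        for group, median in (("CFI", 100.0), ("CLM", 24.0)):
            sub = cohort.clinical.data[cohort.clinical.data["group"] == group]
            curve = km_estimate(sub["dfs_months"], sub["dfs_event"])
            assert abs(curve.median() - median) / median < 0.15

    def test_censor_rate_realized(self):
        cohort = generate_cohort(three_class_config(seed=2, censor_rate=0.3))
        frac = 1.0 - cohort.clinical.data["dfs_event"].mean()
        assert 0.2 < frac < 0.4


class TestConfigValidation:
    @pytest.mark.parametrize("overrides, field_hint", [
        ({"missing_rate": 1.2}, "missing_rate"),
        ({"outlier_magnitude": 0.5}, "outlier_magnitude"),
        ({"n_informative": 400}, "n_informative"),
        ({"n_per_class": {"CFI": -3}}, "n_per_class"),
        ({"n_per_class": {"WHO": 5}}, "n_per_class"),
        ({"gene_prevalence": {"kras": (0.8, 0.5)}}, "gene_prevalence"),
        ({"chemokine_effects": {"tnf": 1.0}}, "chemokine_effects"),
        ({"survival_median_months": {"CFI": 100.0}}, "survival_median_months"),
    ])
    def test_invalid_config_names_offending_field(self, overrides, field_hint):
        with pytest.raises(ConfigurationError, match=field_hint):
            three_class_config(seed=0, **overrides)

    def test_roundtrip_through_yaml(self, tmp_path):
        cfg = three_class_config(seed=4)
        import yaml
        path = tmp_path / "cohort.yaml"
        d = {
            "n_per_class": dict(cfg.n_per_class),
            "n_features": cfg.n_features,
            "n_informative": cfg.n_informative,
            "survival_median_months": dict(cfg.survival_median_months),
            "seed": cfg.seed,
        }
        path.write_text(yaml.safe_dump(d))
        loaded = SyntheticConfig.from_file(path)
        assert loaded.n_per_class == cfg.n_per_class
        assert loaded.seed == cfg.seed
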