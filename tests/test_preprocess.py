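"""Scaling, replicate-outlier masking, imputation and design coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipistage import (
    ClinicalTable,
    FeatureTable,
    align,
    assemble_design,
    code_gene_status,
    collapse_replicates,
    impute_missing,
    mask_replicate_outliers,
    scale_intensities,
)
from lipistage.errors import (
    AssemblyError,
    CodingError,
    MappingError,
    ParameterError,
)


def _table(values, samples=None, features=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i}" for i in range(values.shape[0])]
    features = features or [f"F{j}" for j in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=samples, columns=features))


class TestScaleIntensities:
    def test_division_by_default_factor(self):
        scaled = scale_intensities(_table([[250000.0, 0.0]]))
        assert scaled.intensities.iloc[0, 0] == 2.5
        assert scaled.intensities.iloc[0, 1] == 0.0

    def test_missing_preserved(self):
        scaled = scale_intensities(_table([[np.nan, 1.0]]))
        assert np.isnan(scaled.intensities.iloc[0, 0])

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ParameterError):
            scale_intensities(_table([[1.0]]), factor=0)

    @given(a=st.floats(0.5, 100), b=st.floats(0.5, 100))
    @settings(max_examples=25, deadline=None)
    def test_scaling_is_multiplicative(self, a, b):
        t = _table([[3.0, 7.0], [11.0, 13.0]])
        once = scale_intensities(scale_intensities(t, a), b)
        combined = scale_intensities(t, a * b)
        assert np.allclose(once.intensities, combined.intensities)


class TestReplicateOutliers:
    def test_gross_outlier_masked(self):
        t = _table([[10.0], [10.2], [9.8], [50.0]],
                   samples=["r1", "r2", "r3", "r4"])
        rep = {s: "A" for s in t.sample_ids}
        masked, mask = mask_replicate_outliers(t, rep, k_sd=3)
        assert bool(mask.loc["r4", "F0"])
        assert mask.to_numpy().sum() == 1
        assert np.isnan(masked.intensities.loc["r4", "F0"])

    def test_tight_triplet_untouched(self):
        t = _table([[10.0], [10.2], [9.8]], samples=["r1", "r2", "r3"])
        _, mask = mask_replicate_outliers(t, {s: "A" for s in t.sample_ids})
        assert not mask.to_numpy().any()

    def test_pairs_never_masked(self):
        t = _table([[1.0], [1000.0]], samples=["r1", "r2"])
        _, mask = mask_replicate_outliers(t, {"r1": "A", "r2": "A"})
        assert not mask.to_numpy().any()

    def test_unknown_sample_rejected(self):
        t = _table([[1.0]], samples=["r1"])
        with pytest.raises(MappingError, match="r1"):
            mask_replicate_outliers(t, {"other": "A"})

    def test_masking_invariant_to_replicate_order(self):
        values = [[10.0], [10.2], [9.8], [50.0]]
        t = _table(values, samples=["r1", "r2", "r3", "r4"])
        rep = {s: "A" for s in t.sample_ids}
        _, mask = mask_replicate_outliers(t, rep)
        perm = ["r4", "r2", "r1", "r3"]
        t2 = FeatureTable(t.intensities.loc[perm])
        _, mask2 = mask_replicate_outliers(t2, rep)
        pd.testing.assert_frame_equal(mask.loc[perm], mask2)

    def test_masking_never_adds_values(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(2, 1, (12, 5))
        t = _table(values)
        rep = {s: f"G{i // 3}" for i, s in enumerate(t.sample_ids)}
        masked, _ = mask_replicate_outliers(t, rep)
        assert masked.intensities.notna().sum().sum() <= t.intensities.notna().sum().sum()


class TestCollapseAndImpute:
    def test_mean_of_unmasked_replicates(self):
        t = _table([[10.0], [10.2], [9.8], [np.nan]],
                   samples=["r1", "r2", "r3", "r4"])
        rep = {s: "A" for s in t.sample_ids}
        out = collapse_replicates(t, rep)
        assert out.intensities.loc["A", "F0"] == pytest.approx(10.0)

    def test_single_replicate_is_identity(self):
        t = _table([[1.0, 2.0]], samples=["S1"])
        out = collapse_replicates(t, {"S1": "S1"})
        assert out.intensities.loc["S1"].tolist() == [1.0, 2.0]

    def test_all_masked_cell_stays_missing(self):
        t = _table([[np.nan], [np.nan]], samples=["r1", "r2"])
        out = collapse_replicates(t, {"r1": "A", "r2": "A"})
        assert np.isnan(out.intensities.loc["A", "F0"])

    def test_feature_mean_imputation(self):
        t = _table([[1.0], [np.nan], [3.0]])
        out = impute_missing(t)
        assert out.intensities.iloc[:, 0].tolist() == [1.0, 2.0, 3.0]

    def test_fully_present_unchanged(self):
        t = _table([[1.0], [2.0]])
        out = impute_missing(t)
        assert out.intensities.iloc[:, 0].tolist() == [1.0, 2.0]

    def test_fully_missing_feature_dropped(self, caplog):
        t = _table([[np.nan, 1.0], [np.nan, 2.0]])
        with caplog.at_level("WARNING", logger="lipistage.preprocess"):
            out = impute_missing(t)
        assert out.feature_ids == ["F1"]
        assert "1 fully-missing" in caplog.text


class TestCoding:
    @pytest.mark.parametrize("status, code", [
        ("positive", 1), ("negative", -1), ("unknown", 0)])
    def test_gene_status_codes(self, status, code):
        assert code_gene_status(status) == code

    def test_unrecognized_status_rejected(self):
        with pytest.raises(CodingError, match="wildtype"):
            code_gene_status("wildtype")


def _study(groups, stages=None, n_features=3):
    n = len(groups)
    rng = np.random.default_rng(1)
    features = FeatureTable(pd.DataFrame(
        rng.lognormal(1, 0.3, (n, n_features)),
        index=[f"S{i}" for i in range(n)],
        columns=[f"F{j}" for j in range(n_features)]))
    df = pd.DataFrame({
        "group": groups,
        "stage": stages if stages is not None else [np.nan] * n,
        "age": 60.0, "gender": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
        "waist_cm": 100.0, "il8": 10.0, "pf4": 2000.0, "midkine": 400.0,
        "kras": "positive", "braf": "negative", "mlh1": "unknown",
        "dfs_months": 10.0, "dfs_event": 1, "os_months": 20.0, "os_event": 0,
    }, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))
    return align(features, ClinicalTable(df))


class TestAssembleDesign:
    def test_three_class_codes(self):
        study = _study(["CFI", "CRC", "CLM", "CFI", "CRC", "CLM"],
                       [np.nan, 2, np.nan, np.nan, 3, np.nan])
        ds = assemble_design(study, "CFI-CRC-CLM")
        assert ds.y.tolist() == [0, 1, 2, 0, 1, 2]
        assert ds.coding_map == {"CFI": 0, "CRC": 1, "CLM": 2}

    def test_binary_scenario_merges_crc_and_clm(self):
        study = _study(["CFI", "CRC", "CLM"], [np.nan, 4, np.nan])
        ds = assemble_design(study, "CFI-mCRC")
        assert ds.y.tolist() == [0, 1, 1]

    def test_stage_scenario_uses_stage_codes(self):
        study = _study(["CFI", "CRC", "CRC", "CRC", "CRC", "CLM"],
                       [np.nan, 1, 2, 3, 4, np.nan])
        ds = assemble_design(study, "CFI-CRC")
        assert ds.y.tolist() == [0, 1, 2, 3, 4]
        assert "S5" not in ds.y.index  # CLM excluded from the staging scenario

    def test_stage0_excluded_by_default_included_on_flag(self):
        study = _study(["CFI", "CRC", "CRC", "CRC", "CRC", "CRC", "CFI"],
                       [np.nan, 0, 1, 2, 3, 4, np.nan])
        ds = assemble_design(study, "CFI-CRC")
        assert "S1" not in ds.y.index
        ds0 = assemble_design(study, "CFI-CRC", include_stage0=True)
        assert ds0.y.loc["S1"] == 0

    def test_clinical_columns_appended_and_coded(self):
        study = _study(["CFI", "CRC", "CLM", "CFI"], [np.nan, 2, np.nan, np.nan])
        ds = assemble_design(study, "CFI-mCRC", include_clinical=True)
        for col in ("age", "waist_cm", "gender_female", "il8", "kras"):
            assert col in ds.X.columns
        assert set(ds.X["kras"]) == {1.0}
        assert not ds.X.isna().any().any()

    def test_empty_class_rejected(self):
        study = _study(["CRC", "CRC"], [1, 2])
        with pytest.raises(AssemblyError):
            assemble_design(study, "CFI-CRC-CLM")

    def test_coding_map_is_bijection_onto_code_set(self, coded_three_class):
        ds = coded_three_class
        codes = sorted(ds.coding_map.values())
        assert codes == sorted(set(codes))
        assert sorted(set(ds.y)) == codes
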