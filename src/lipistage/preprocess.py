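"""Intensity scaling, replicate-outlier elimination, imputation and the
numeric coding of groups, stages and gene statuses into a model-ready design.

Conventions adopted here:

* peak intensities are divided by a scale factor (default 100,000) to bring
  them to order-unity magnitudes suitable for regularized regression;
* outliers among technical replicates are masked when their leave-one-out
  z-score (mean and SD of the other replicates) exceeds ``k_sd``;
* missing intensities are imputed with the feature mean over *all* samples,
  never per class, so imputation cannot leak class labels into features;
* ordinal class codes: controls 0 / cancer 1 / liver metastasis 2 in the
  three-group scenario; 0 plus stage number 1–4 in the staging scenario;
  control 0 / any disease 1 in the merged scenario;
* gene-mutation status is coded +1 (positive), −1 (negative), 0 (unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AssemblyError, CodingError, MappingError, ParameterError
from .ingest import (
    AlignedStudy,
    CHEMOKINE_COLUMNS,
    FeatureTable,
    GENE_COLUMNS,
)

logger = logging.getLogger(__name__)

SCENARIO_THREE_CLASS = "CFI-CRC-CLM"
SCENARIO_STAGE = "CFI-CRC"
SCENARIO_BINARY = "CFI-mCRC"
SCENARIOS = (SCENARIO_THREE_CLASS, SCENARIO_STAGE, SCENARIO_BINARY)

DEFAULT_SCALE_FACTOR = 100_000.0


@dataclass
class CodedDataset:
    """Numeric design matrix ``X`` and ordinal response ``y`` for one
    modelling scenario, plus the label → code map used to build ``y``."""

    X: pd.DataFrame
    y: pd.Series
    scenario: str
    coding_map: dict[str, int]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def classes(self) -> list[int]:
        return sorted(set(self.coding_map.values()))

    def subset(self, sample_ids) -> "CodedDataset":
        return CodedDataset(self.X.loc[sample_ids].copy(), self.y.loc[sample_ids].copy(),
                            self.scenario, dict(self.coding_map))


# ---------------------------------------------------------------------------
# intensity-level operations
# ---------------------------------------------------------------------------

def infer_replicate_map(sample_ids) -> dict[str, str]:
    """Infer replicate grouping from the ``<sample>_r<k>`` id convention.

    Rows named like ``S001_r2`` are treated as technical replicates of
    biological sample ``S001``; any other id maps to itself.
    """
    import re

    pattern = re.compile(r"^(.*)_r\d+$")
    out = {}
    for sid in sample_ids:
        m = pattern.match(str(sid))
        out[str(sid)] = m.group(1) if m else str(sid)
    return out


def scale_intensities(features: FeatureTable, factor: float = DEFAULT_SCALE_FACTOR) -> FeatureTable:
    """Divide every present intensity by ``factor``; missingness unchanged."""
    if factor <= 0:
        raise ParameterError(f"scale factor must be positive, got {factor}")
    return FeatureTable(features.intensities / factor,
                        None if features.annotations is None else features.annotations.copy())


def mask_replicate_outliers(
    features: FeatureTable,
    replicate_map: Mapping[str, str],
    k_sd: float = 3.0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Mask replicate values whose leave-one-out z-score exceeds ``k_sd``.

    For each feature and replicate group with at least 3 present values, each
    value is compared against the mean and SD of the *other* replicates in
    its group; values with ``|z| > k_sd`` are set missing.  Groups with fewer
    than 3 present values are left untouched.  All decisions are made on the
    original values simultaneously, so masking is invariant to replicate
    order.  Returns the masked table and the boolean audit mask.
    """
    if k_sd <= 0:
        raise ParameterError(f"k_sd must be positive, got {k_sd}")
    unknown = [s for s in features.sample_ids if s not in replicate_map]
    if unknown:
        raise MappingError(f"replicate_map lacks sample(s) {unknown}")

    values = features.intensities
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    groups = pd.Series({s: replicate_map[s] for s in features.sample_ids})
    for _, members in groups.groupby(groups).groups.items():
        block = values.loc[members].to_numpy(dtype=float)  # r × p
        r = block.shape[0]
        if r < 3:
            continue
        present = ~np.isnan(block)
        n_pres = present.sum(axis=0)
        filled = np.where(present, block, 0.0)
        tot = filled.sum(axis=0)
        tot_sq = (filled ** 2).sum(axis=0)
        # leave-one-out mean/SD per cell (ddof=1 over the remaining values)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = n_pres - present  # count excluding self where present
            loo_mean = (tot - filled) / m
            loo_var = (tot_sq - filled ** 2 - m * loo_mean ** 2) / (m - 1)
            loo_var = np.clip(loo_var, 0.0, None)
            z = np.abs(block - loo_mean) / np.sqrt(loo_var)
        eligible = present & (n_pres >= 3)
        # SD of zero with a discrepant value ⇒ infinite z ⇒ masked
        z = np.where(np.isnan(z) & eligible & (np.abs(block - loo_mean) > 0), np.inf, z)
        cell_mask = eligible & (z > k_sd)
        mask.loc[members] = cell_mask
    masked = values.where(~mask)
    out = FeatureTable(masked,
                       None if features.annotations is None else features.annotations.copy())
    return out, mask


def collapse_replicates(features: FeatureTable, replicate_map: Mapping[str, str]) -> FeatureTable:
    """Average unmasked replicate values into one row per biological sample;
    cells whose replicates are all masked become missing."""
    unknown = [s for s in features.sample_ids if s not in replicate_map]
    if unknown:
        raise MappingError(f"replicate_map lacks sample(s) {unknown}")
    groups = [replicate_map[s] for s in features.sample_ids]
    collapsed = features.intensities.groupby(pd.Index(groups, name="sample_id"), sort=False).mean()
    # preserve first-appearance order of biological samples
    order = list(dict.fromkeys(groups))
    collapsed = collapsed.loc[order]
    return FeatureTable(collapsed,
                        None if features.annotations is None else features.annotations.copy())


def impute_missing(features: FeatureTable, strategy: str = "feature-mean") -> FeatureTable:
    """Replace missing intensities; features with no present values at all
    are dropped with a logged warning."""
    if strategy != "feature-mean":
        raise ParameterError(f"unknown imputation strategy {strategy!r}")
    values = features.intensities
    all_missing = values.columns[values.isna().all(axis=0)]
    if len(all_missing):
        logger.warning("impute_missing: dropping %d fully-missing feature(s): %s",
                       len(all_missing), list(all_missing[:10]))
        values = values.drop(columns=all_missing)
    filled = values.fillna(values.mean(axis=0))
    ann = features.annotations
    if ann is not None:
        ann = ann.loc[[f for f in filled.columns if f in ann.index]].copy()
    return FeatureTable(filled, ann)


# ---------------------------------------------------------------------------
# categorical coding
# ---------------------------------------------------------------------------

_GENE_CODE = {"positive": 1, "negative": -1, "unknown": 0}


def code_gene_status(status: str) -> int:
    """Ternary gene-mutation coding: positive → +1, negative → −1,
    unknown → 0."""
    try:
        return _GENE_CODE[status]
    except KeyError:
        raise CodingError(f"unrecognized gene status {status!r}; "
                          f"expected one of {tuple(_GENE_CODE)}") from None


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def _class_codes(clinical: pd.DataFrame, scenario: str,
                 include_stage0: bool) -> tuple[pd.Series, dict[str, int]]:
    group = clinical["group"]
    if scenario == SCENARIO_THREE_CLASS:
        coding = {"CFI": 0, "CRC": 1, "CLM": 2}
        y = group.map(coding)
        keep = y.notna()
    elif scenario == SCENARIO_BINARY:
        coding = {"CFI": 0, "mCRC": 1}
        y = group.map({"CFI": 0, "CRC": 1, "CLM": 1})
        keep = y.notna()
    elif scenario == SCENARIO_STAGE:
        coding = {"CFI": 0, "stage-I": 1, "stage-II": 2, "stage-III": 3, "stage-IV": 4}
        y = pd.Series(np.nan, index=clinical.index)
        y[group == "CFI"] = 0
        crc = group == "CRC"
        stage = clinical.loc[crc, "stage"]
        y.loc[crc] = stage
        keep = y.notna() & (group != "CLM")
        if include_stage0:
            coding = {**coding, "stage-0": 0}
        else:
            keep &= ~(crc & (clinical["stage"] == 0))
    else:
        raise AssemblyError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    return y[keep].astype(int), coding


def assemble_design(
    study: AlignedStudy,
    scenario: str,
    include_clinical: bool = False,
    standardize_clinical: bool = True,
    include_stage0: bool = False,
) -> CodedDataset:
    """Merge (already scaled/imputed) lipid intensities and, optionally,
    clinical covariates into one numeric design with ordinal class codes.

    ``include_clinical`` appends age, waist, a {0,1} female indicator,
    chemokine concentrations and ternary gene codes; continuous clinical
    columns are z-scored when ``standardize_clinical`` so they are
    commensurate with the scaled lipid intensities.  In the staging scenario
    stage-0 cancers are excluded unless ``include_stage0`` maps them to
    code 0.
    """
    clinical = study.clinical.data
    y, coding_map = _class_codes(clinical, scenario, include_stage0)
    if len(y) == 0:
        raise AssemblyError(f"scenario {scenario!r}: no samples left after coding")
    expected_codes = sorted(set(coding_map.values()))
    present = sorted(set(y))
    empty = [c for c in expected_codes if c not in present]
    if empty:
        raise AssemblyError(
            f"scenario {scenario!r}: no samples in class code(s) {empty}"
        )

    X = study.features.intensities.loc[y.index].copy()
    if X.isna().any().any():
        raise AssemblyError("design assembly requires imputed intensities; "
                            "missing values remain")
    if include_clinical:
        clin = clinical.loc[y.index]
        extra = pd.DataFrame(index=y.index)
        extra["age"] = pd.to_numeric(clin["age"])
        extra["waist_cm"] = pd.to_numeric(clin["waist_cm"])
        extra["gender_female"] = (clin["gender"].astype(str).str.upper()
                                  .str.startswith("F")).astype(float)
        for chem in CHEMOKINE_COLUMNS:
            extra[chem] = pd.to_numeric(clin[chem])
        for gene in GENE_COLUMNS:
            extra[gene] = clin[gene].map(code_gene_status).astype(float)
        if standardize_clinical:
            for col in ("age", "waist_cm", *CHEMOKINE_COLUMNS):
                v = extra[col]
                sd = v.std(ddof=0)
                extra[col] = (v - v.mean()) / sd if sd > 0 else v - v.mean()
        if extra.isna().any().any():
            bad = list(extra.columns[extra.isna().any()])
            raise AssemblyError(f"clinical covariate(s) {bad} contain missing values")
        X = pd.concat([X, extra], axis=1)
    return CodedDataset(X, y.rename("class_code"), scenario, coding_map)
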