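"""Reading, validation and alignment of feature and clinical tables.

The canonical interchange format is plain CSV/TSV:

* feature table — header ``sample_id,<feature_1>,...``; one row per sample,
  blank cells (or the literal ``NA``) are missing intensities;
* annotation side-car — ``feature_id,lipid_class,mz,rt,adduct``;
* clinical table — ``sample_id,group,stage,age,gender,waist_cm,il8,pf4,
  midkine,kras,braf,mlh1,dfs_months,dfs_event,os_months,os_event``.

Sample identifiers are case-sensitive exact strings.  The mass window
[140, 1300] Da mirrors the acquisition range of the profiling experiment the
tables come from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: columns holding chemokine concentrations in the clinical table
CHEMOKINE_COLUMNS: tuple[str, ...] = ("il8", "pf4", "midkine")
#: columns holding ternary gene-mutation status in the clinical table
GENE_COLUMNS: tuple[str, ...] = ("kras", "braf", "mlh1")
#: full clinical column contract (after sample_id, which becomes the index)
CLINICAL_COLUMNS: tuple[str, ...] = (
    "group", "stage", "age", "gender", "waist_cm",
    *CHEMOKINE_COLUMNS, *GENE_COLUMNS,
    "dfs_months", "dfs_event", "os_months", "os_event",
)

GROUPS = ("CFI", "CRC", "CLM")
GENE_STATUS_LABELS = ("positive", "negative", "unknown")

MZ_WINDOW = (140.0, 1300.0)

_NA_STRINGS = ("", "NA")


@dataclass
class FeatureTable:
    """Samples × lipid-features intensity matrix with per-feature annotation.

    ``intensities`` is a float DataFrame indexed by sample identifier with one
    column per feature; NaN marks a missing intensity.  ``annotations``, when
    present, is indexed by feature identifier with columns
    ``lipid_class, mz, rt, adduct``.
    """

    intensities: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def copy(self) -> "FeatureTable":
        ann = None if self.annotations is None else self.annotations.copy()
        return FeatureTable(self.intensities.copy(), ann)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicate sample identifiers: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise FormatError(f"duplicate feature identifiers: {dupes}")
        values = self.intensities.to_numpy(dtype=float)
        neg = np.asarray(values < 0).nonzero()
        if neg[0].size:
            cells = [
                (str(idx[i]), str(cols[j]))
                for i, j in zip(neg[0][:10], neg[1][:10])
            ]
            raise ValidationError(f"negative intensities at cells {cells}")
        if self.annotations is not None and "mz" in self.annotations:
            mz = pd.to_numeric(self.annotations["mz"], errors="coerce")
            bad = mz.dropna()[(mz.dropna() < MZ_WINDOW[0]) | (mz.dropna() > MZ_WINDOW[1])]
            if len(bad):
                raise ValidationError(
                    f"m/z outside window {MZ_WINDOW}: {bad.to_dict()}"
                )


@dataclass
class ClinicalTable:
    """Per-sample clinical metadata: group/stage, demographics, chemokine
    concentrations, ternary gene-mutation statuses and DFS/OS endpoints."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(self.data.copy())

    def validate(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dupes = sorted(set(df.index[df.index.duplicated()]))
            raise FormatError(f"duplicate sample identifiers: {dupes}")
        missing_cols = [c for c in ("group",) if c not in df.columns]
        if missing_cols:
            raise FormatError(f"clinical table lacks required columns {missing_cols}")
        bad_groups = set(df["group"].dropna()) - set(GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown group labels {sorted(bad_groups)}")
        if "stage" in df.columns:
            staged = df["stage"].notna()
            non_crc = staged & (df["group"] != "CRC")
            if non_crc.any():
                raise ValidationError(
                    "stage present for non-CRC samples: "
                    f"{list(df.index[non_crc])}"
                )
            stages = df.loc[staged, "stage"]
            out = stages[(stages < 0) | (stages > 4) | (stages % 1 != 0)]
            if len(out):
                raise ValidationError(f"stage outside 0–4: {out.to_dict()}")
        for col in ("dfs_months", "os_months"):
            if col in df.columns:
                t = df[col].dropna()
                if (t < 0).any():
                    raise ValidationError(f"negative times in {col}")
        for col in ("dfs_event", "os_event"):
            if col in df.columns:
                e = df[col].dropna()
                if not e.isin([0, 1]).all():
                    raise ValidationError(f"non-binary events in {col}")
        for col in GENE_COLUMNS:
            if col in df.columns:
                bad = set(df[col].dropna()) - set(GENE_STATUS_LABELS)
                if bad:
                    raise ValidationError(
                        f"unknown {col} status labels {sorted(bad)}"
                    )


@dataclass
class AlignedStudy:
    """Feature and clinical tables restricted to their common samples, in
    identical order; samples present in only one table are listed in
    ``dropped_samples``."""

    features: FeatureTable
    clinical: ClinicalTable
    dropped_samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_feature_table(path: str | Path, annotations_path: str | Path | None = None) -> FeatureTable:
    """Read a samples × features intensity CSV/TSV.

    The first column is the sample identifier; blank cells and the literal
    ``NA`` become missing.  An optional annotation side-car
    (``feature_id,lipid_class,mz,rt,adduct``) is attached verbatim.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    dupes = sorted({c for c in header if c in seen or seen.add(c)})
    if dupes:
        raise FormatError(f"duplicated feature column name(s) {dupes} in {path}")
    raw = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, index_col=0
    )
    values = raw.where(~raw.isin(_NA_STRINGS))
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"unparseable intensity in {path}: {exc}") from exc
    values.index = values.index.astype(str)
    values.index.name = "sample_id"

    annotations = None
    if annotations_path is not None:
        apath = Path(annotations_path)
        annotations = pd.read_csv(apath, sep=_sep_for(apath), index_col="feature_id")
        annotations.index = annotations.index.astype(str)
    return FeatureTable(values, annotations)


def write_feature_table(table: FeatureTable, path: str | Path,
                        annotations_path: str | Path | None = None) -> None:
    """Write a feature table (and optionally its annotations); missing values
    are emitted as empty cells, preserving the missingness pattern."""
    path = Path(path)
    table.intensities.to_csv(path, sep=_sep_for(path), na_rep="")
    if annotations_path is not None and table.annotations is not None:
        table.annotations.to_csv(Path(annotations_path), index_label="feature_id")


_CLINICAL_NUMERIC = (
    "stage", "age", "waist_cm", *CHEMOKINE_COLUMNS,
    "dfs_months", "dfs_event", "os_months", "os_event",
)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read the per-sample clinical CSV/TSV.

    Empty gene-status cells are accepted as ``unknown``; empty numeric cells
    become missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False,
                     index_col="sample_id")
    df.index = df.index.astype(str)
    df = df.where(~df.isin(_NA_STRINGS))
    for col in _CLINICAL_NUMERIC:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                              & df[col].notna()]
                raise FormatError(
                    f"unparseable numeric in column '{col}' of {path} at rows "
                    f"{list(bad.index)}"
                ) from exc
    for col in GENE_COLUMNS:
        if col in df.columns:
            df[col] = df[col].fillna("unknown")
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(Path(path), na_rep="", index_label="sample_id")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align(features: FeatureTable, clinical: ClinicalTable) -> AlignedStudy:
    """Restrict both tables to their common samples, in feature-table order.

    Raises :class:`AlignmentError` when the tables share no samples.  Samples
    found in only one table are reported (and logged) in ``dropped_samples``.
    """
    common = [s for s in features.sample_ids if s in set(clinical.sample_ids)]
    if not common:
        raise AlignmentError("feature and clinical tables share no samples")
    dropped = sorted(
        (set(features.sample_ids) | set(clinical.sample_ids)) - set(common)
    )
    if dropped:
        logger.warning("align: dropping %d non-shared sample(s): %s",
                       len(dropped), dropped)
    feats = FeatureTable(features.intensities.loc[common].copy(),
                         None if features.annotations is None
                         else features.annotations.copy())
    clin = ClinicalTable(clinical.data.loc[common].copy())
    return AlignedStudy(feats, clin, dropped)
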