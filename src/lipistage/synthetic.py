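"""Seeded synthetic cohorts with the statistical structure the staging
analysis assumes.

The generator emulates a plasma-lipidomics case/control study: positive,
right-skewed LC-MS peak intensities (log-normal), a small panel of planted
discriminative lipids whose log-abundance shifts monotonically with an
ordinal disease-severity code, chemokine concentrations with class-dependent
means, ternary gene-mutation statuses, class-dependent exponential survival
times with random censoring, and missing values / multiplicative outliers
injected after technical replicates are expanded.

Three ready-made configurations mirror the cohort structures of the study
design this package implements:

* :func:`three_class_config` — 16 controls (CFI), 32 colorectal-cancer (CRC)
  and 18 liver-metastasis (CLM) samples over 333 lipid features;
* :func:`stage_config` — 13 CFI + 13/11/12/10 CRC stage-I…IV samples over
  289 features;
* :func:`multiomics_config` — 15 CFI, 24 CRC and 9 CLM samples over 344
  lipid features, to which the design-assembly step appends 9 clinical
  columns (age, waist, gender, 3 chemokines, 3 gene codes).

One global seed drives a root ``numpy.random.SeedSequence``; each component
(intensities, missingness, outliers, chemokines, genes, survival,
demographics) draws from its own deterministically spawned sub-stream, so
adding a component never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .ingest import (
    CHEMOKINE_COLUMNS,
    CLINICAL_COLUMNS,
    ClinicalTable,
    FeatureTable,
    GENE_COLUMNS,
)

LIPID_CLASSES = ("PS", "PE", "PC", "TG", "DG", "MG", "CE", "SM", "PA", "FA", "LacCer")

#: baseline log-concentration per chemokine (arbitrary plasma units)
_CHEMOKINE_BASELINE = {"il8": np.log(15.0), "pf4": np.log(5000.0), "midkine": np.log(500.0)}
_CHEMOKINE_SIGMA = 0.4

_ROMAN = {"0": 0, "I": 1, "II": 2, "III": 3, "IV": 4,
          "1": 1, "2": 2, "3": 3, "4": 4}


def _parse_class_label(label: str) -> tuple[str, int | None]:
    """Map a class label to (clinical group, stage).

    ``CFI`` and ``CLM`` carry no stage; ``CRC`` gets stages assigned
    cyclically at generation time; ``CRC-I`` … ``CRC-IV`` (or ``CRC-1`` …)
    pin the stage.
    """
    if label in ("CFI", "CLM"):
        return label, None
    if label == "CRC":
        return "CRC", None
    if label.startswith("CRC-"):
        suffix = label[4:]
        if suffix in _ROMAN:
            return "CRC", _ROMAN[suffix]
    raise ConfigurationError(f"n_per_class: unrecognized class label {label!r}")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the standardized log-scale mean shift per unit class
    code for each planted feature; ``noise_sigma`` the log-normal shape;
    ``survival_median_months`` gives the per-class median disease-free
    survival (overall survival uses ``os_median_factor`` × that median).
    """

    n_per_class: Mapping[str, int]
    n_features: int = 333
    n_informative: int = 9
    effect_size: float = 1.0
    noise_sigma: float = 0.5
    baseline_log_mean: float = 13.0
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    outlier_magnitude: float = 10.0
    chemokine_effects: Mapping[str, float] = field(
        default_factory=lambda: {"il8": 0.5, "pf4": 0.4}
    )
    gene_prevalence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"kras": (0.4, 0.2), "braf": (0.1, 0.3), "mlh1": (0.15, 0.3)}
    )
    survival_median_months: Mapping[str, float] = field(
        default_factory=lambda: {"CFI": 150.0, "CRC": 60.0, "CLM": 24.0}
    )
    os_median_factor: float = 1.5
    censor_rate: float = 0.2
    replicate_count: int = 1
    replicate_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.n_per_class:
            raise ConfigurationError("n_per_class: must name at least one class")
        for label, n in self.n_per_class.items():
            _parse_class_label(str(label))
            if int(n) != n or n <= 0:
                raise ConfigurationError(f"n_per_class[{label!r}]: count must be a positive integer")
        for name in ("n_features", "n_informative", "replicate_count"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                if not (name == "n_informative" and v == 0):
                    raise ConfigurationError(f"{name}: must be a positive integer")
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative: exceeds n_features")
        for name in ("missing_rate", "outlier_rate", "censor_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigurationError(f"{name}: must lie in [0, 1)")
        if self.outlier_magnitude <= 1:
            raise ConfigurationError("outlier_magnitude: must exceed 1")
        if self.noise_sigma < 0 or self.replicate_sigma < 0:
            raise ConfigurationError("noise_sigma: must be non-negative")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size: must be non-negative")
        for chem in self.chemokine_effects:
            if chem not in CHEMOKINE_COLUMNS:
                raise ConfigurationError(
                    f"chemokine_effects: unknown chemokine {chem!r}; "
                    f"known: {CHEMOKINE_COLUMNS}"
                )
        for gene, probs in self.gene_prevalence.items():
            if gene not in GENE_COLUMNS:
                raise ConfigurationError(f"gene_prevalence: unknown gene {gene!r}")
            p_pos, p_unknown = probs
            if p_pos < 0 or p_unknown < 0 or p_pos + p_unknown > 1:
                raise ConfigurationError(
                    f"gene_prevalence[{gene!r}]: probabilities must be non-negative "
                    "and sum to at most 1"
                )
        missing_medians = set(self.n_per_class) - set(self.survival_median_months)
        if missing_medians:
            raise ConfigurationError(
                f"survival_median_months: no median for class(es) {sorted(missing_medians)}"
            )
        for label, med in self.survival_median_months.items():
            if med <= 0:
                raise ConfigurationError(f"survival_median_months[{label!r}]: must be positive")

    # -- (de)serialization ----------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "gene_prevalence" in d:
            d["gene_prevalence"] = {k: tuple(v) for k, v in d["gene_prevalence"].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load a configuration from YAML or JSON."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class SyntheticCohort:
    """One generated cohort: intensities + clinical metadata + ground truth.

    ``planted_features`` lists (feature_id, direction) for the informative
    lipids, direction ∈ {+1, −1}.  When ``replicate_count > 1`` the feature
    table holds one row per technical replicate and ``replicate_map`` links
    each replicate row to its biological sample.
    """

    features: FeatureTable
    clinical: ClinicalTable
    planted_features: list[tuple[str, int]]
    replicate_map: dict[str, str]
    config: SyntheticConfig


def _survival_draw(rng: np.random.Generator, median: float, censor_rate: float,
                   n: int) -> tuple[np.ndarray, np.ndarray]:
    scale = median / np.log(2.0)
    t = rng.exponential(scale, size=n)
    censored = rng.random(n) < censor_rate
    u = rng.random(n)
    times = np.where(censored, t * u, t)
    events = (~censored).astype(int)
    return times, events


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate one fully reproducible synthetic cohort.

    Planted feature ``j`` with direction ``d_j`` has log-intensity mean
    ``baseline_log_mean + effect_size · class_code(s) · d_j`` (class codes
    run 0, 1, … in ``n_per_class`` insertion order); all other features sit
    at the baseline.  Missing values and multiplicative outliers are injected
    after replicate expansion.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (ss_plant, ss_intens, ss_missing, ss_outlier, ss_chem, ss_gene,
     ss_surv, ss_demo, ss_annot) = root.spawn(9)
    rng_plant = np.random.default_rng(ss_plant)
    rng_int = np.random.default_rng(ss_intens)
    rng_miss = np.random.default_rng(ss_missing)
    rng_out = np.random.default_rng(ss_outlier)
    rng_chem = np.random.default_rng(ss_chem)
    rng_gene = np.random.default_rng(ss_gene)
    rng_surv = np.random.default_rng(ss_surv)
    rng_demo = np.random.default_rng(ss_demo)
    rng_annot = np.random.default_rng(ss_annot)

    # --- samples and class codes ---------------------------------------
    class_labels = list(config.n_per_class)
    sample_ids: list[str] = []
    codes: list[int] = []
    groups: list[str] = []
    stages: list[float] = []
    crc_stage_cycle = (1, 2, 3, 4)
    counter = 0
    for code, label in enumerate(class_labels):
        group, fixed_stage = _parse_class_label(str(label))
        for i in range(int(config.n_per_class[label])):
            counter += 1
            sample_ids.append(f"S{counter:03d}")
            codes.append(code)
            groups.append(group)
            if group != "CRC":
                stages.append(np.nan)
            elif fixed_stage is not None:
                stages.append(float(fixed_stage))
            else:
                stages.append(float(crc_stage_cycle[i % len(crc_stage_cycle)]))
    n = len(sample_ids)
    code_arr = np.asarray(codes, dtype=float)

    # --- features and planted effects ----------------------------------
    feature_ids = [f"F{j + 1:04d}" for j in range(config.n_features)]
    planted_idx = rng_plant.choice(config.n_features, size=config.n_informative,
                                   replace=False)
    planted_idx.sort()
    directions = rng_plant.choice([-1, 1], size=config.n_informative)
    direction_vec = np.zeros(config.n_features)
    direction_vec[planted_idx] = directions

    log_mean = (config.baseline_log_mean
                + config.effect_size * np.outer(code_arr, direction_vec))
    log_bio = log_mean + config.noise_sigma * rng_int.standard_normal((n, config.n_features))

    if config.replicate_count > 1:
        rep_ids = [f"{sid}_r{r + 1}" for sid in sample_ids
                   for r in range(config.replicate_count)]
        replicate_map = {rid: rid.rsplit("_r", 1)[0] for rid in rep_ids}
        log_rep = (np.repeat(log_bio, config.replicate_count, axis=0)
                   + config.replicate_sigma
                   * rng_int.standard_normal((len(rep_ids), config.n_features)))
    else:
        rep_ids = list(sample_ids)
        replicate_map = {sid: sid for sid in sample_ids}
        log_rep = log_bio

    intensities = np.exp(log_rep)
    # outliers then missingness, both on the expanded (replicate-level) matrix
    out_mask = rng_out.random(intensities.shape) < config.outlier_rate
    intensities = np.where(out_mask, intensities * config.outlier_magnitude, intensities)
    miss_mask = rng_miss.random(intensities.shape) < config.missing_rate
    intensities = np.where(miss_mask, np.nan, intensities)

    annotations = pd.DataFrame(
        {
            "lipid_class": rng_annot.choice(LIPID_CLASSES, size=config.n_features),
            "mz": np.round(rng_annot.uniform(140.0, 1300.0, size=config.n_features), 4),
            "rt": np.round(rng_annot.uniform(1.0, 20.0, size=config.n_features), 2),
            "adduct": rng_annot.choice(["[M+H]", "[M-H]", "[M+NH4]"], size=config.n_features),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    features = FeatureTable(
        pd.DataFrame(intensities, index=pd.Index(rep_ids, name="sample_id"),
                     columns=feature_ids),
        annotations,
    )

    # --- clinical table -------------------------------------------------
    clin = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"),
                        columns=list(CLINICAL_COLUMNS), dtype=object)
    clin["group"] = groups
    clin["stage"] = stages
    clin["age"] = np.clip(np.round(rng_demo.normal(65, 10, size=n)), 30, 92)
    clin["gender"] = np.where(rng_demo.random(n) < 0.5, "F", "M")
    clin["waist_cm"] = np.round(np.clip(rng_demo.normal(103, 12, size=n), 70, 145), 1)
    for chem in CHEMOKINE_COLUMNS:
        shift = float(config.chemokine_effects.get(chem, 0.0))
        log_c = (_CHEMOKINE_BASELINE[chem] + shift * code_arr
                 + _CHEMOKINE_SIGMA * rng_chem.standard_normal(n))
        clin[chem] = np.round(np.exp(log_c), 3)
    for gene in GENE_COLUMNS:
        p_pos, p_unknown = config.gene_prevalence.get(gene, (0.0, 1.0))
        u = rng_gene.random(n)
        status = np.where(u < p_pos, "positive",
                          np.where(u < p_pos + p_unknown, "unknown", "negative"))
        clin[gene] = status
    dfs_t = np.empty(n)
    dfs_e = np.empty(n, dtype=int)
    os_t = np.empty(n)
    os_e = np.empty(n, dtype=int)
    for code, label in enumerate(class_labels):
        sel = code_arr == code
        med = float(config.survival_median_months[label])
        t, e = _survival_draw(rng_surv, med, config.censor_rate, int(sel.sum()))
        dfs_t[sel], dfs_e[sel] = t, e
        t, e = _survival_draw(rng_surv, med * config.os_median_factor,
                              config.censor_rate, int(sel.sum()))
        os_t[sel], os_e[sel] = t, e
    clin["dfs_months"] = np.round(dfs_t, 2)
    clin["dfs_event"] = dfs_e
    clin["os_months"] = np.round(os_t, 2)
    clin["os_event"] = os_e
    for col in ("stage", "age", "waist_cm", "dfs_months", "os_months"):
        clin[col] = pd.to_numeric(clin[col])

    planted = [(feature_ids[j], int(d)) for j, d in zip(planted_idx, directions)]
    return SyntheticCohort(features, ClinicalTable(clin), planted, replicate_map, config)


# ---------------------------------------------------------------------------
# ready-made study configurations
# ---------------------------------------------------------------------------

def three_class_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Control / cancer / liver-metastasis cohort: 66 samples, 333 lipid
    features, 9 planted effects."""
    params = dict(
        n_per_class={"CFI": 16, "CRC": 32, "CLM": 18},
        n_features=333,
        n_informative=9,
        effect_size=1.0,
        survival_median_months={"CFI": 150.0, "CRC": 60.0, "CLM": 24.0},
        replicate_count=3,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def stage_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Control + four cancer stages: 59 samples, 289 features, 16 planted
    effects; the per-unit-stage shift is halved because codes span 0–4."""
    params = dict(
        n_per_class={"CFI": 13, "CRC-I": 13, "CRC-II": 11, "CRC-III": 12, "CRC-IV": 10},
        n_features=289,
        n_informative=16,
        effect_size=0.5,
        survival_median_months={"CFI": 150.0, "CRC-I": 110.0, "CRC-II": 90.0,
                                "CRC-III": 60.0, "CRC-IV": 30.0},
        replicate_count=3,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def multiomics_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Control vs merged diseased cohort with clinical covariates: 48 samples,
    344 lipid features (353 columns once the 9 clinical covariates are
    appended by design assembly), 8 planted lipids plus informative
    chemokines."""
    params = dict(
        n_per_class={"CFI": 15, "CRC": 24, "CLM": 9},
        n_features=344,
        n_informative=8,
        effect_size=1.0,
        chemokine_effects={"il8": 0.6, "pf4": 0.5, "midkine": 0.2},
        survival_median_months={"CFI": 150.0, "CRC": 60.0, "CLM": 24.0},
        replicate_count=3,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def save_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as plain CSV (features, annotations, clinical) plus a
    JSON ground-truth sidecar; returns the paths written."""
    from .ingest import write_clinical_table, write_feature_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.csv",
        "annotations": out / "annotations.csv",
        "clinical": out / "clinical.csv",
        "truth": out / "ground_truth.json",
    }
    write_feature_table(cohort.features, paths["features"], paths["annotations"])
    write_clinical_table(cohort.clinical, paths["clinical"])
    paths["truth"].write_text(json.dumps(
        {
            "planted_features": [[f, d] for f, d in cohort.planted_features],
            "replicate_map": cohort.replicate_map,
            "seed": cohort.config.seed,
        },
        indent=2, sort_keys=True,
    ))
    return paths
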