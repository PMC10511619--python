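import logging

import pytest

from lipistage import (
    align,
    assemble_design,
    collapse_replicates,
    generate_cohort,
    impute_missing,
    mask_replicate_outliers,
    scale_intensities,
    three_class_config,
)

logging.getLogger("lipistage").setLevel(logging.ERROR)


def preprocess_cohort(cohort, scenario="CFI-CRC-CLM", **assemble_kwargs):
    """Standard preprocessing chain used across tests: scale, mask replicate
    outliers, collapse, impute, align, assemble."""
    f = scale_intensities(cohort.features)
    if cohort.config.replicate_count > 1:
        f, _ = mask_replicate_outliers(f, cohort.replicate_map)
        f = collapse_replicates(f, cohort.replicate_map)
    f = impute_missing(f)
    study = align(f, cohort.clinical)
    return assemble_design(study, scenario, **assemble_kwargs)


@pytest.fixture(scope="session")
def three_class_cohort():
    return generate_cohort(three_class_config(seed=11))


@pytest.fixture(scope="session")
def coded_three_class(three_class_cohort):
    return preprocess_cohort(three_class_cohort)
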