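import numpy as np
import pytest

from mci_convert.classification import SvmConfig, predict_cohort, train_svm
from mci_convert.pipeline import PipelineConfig, SelectionParams
from mci_convert.synthetic_cohort import (
    CohortConfig,
    default_mri_feature_names,
    generate_cohort,
)

# Strong disease markers used when a test needs a known-good feature set
# without re-running feature selection.
STRONG_FEATURES = [
    "lm_delayed_recall",
    "lm_immediate_recall",
    "avlt_trials_1_5",
    "faq",
    "avlt_delayed_recall",
    "ttau",
    "abeta42",
    "ptau181",
    "entorhinal_cortex_TA_L",
    "middle_temporal_gyrus_CV_R",
    "hippocampus_SV_R",
    "hippocampus_SV_L",
    "inferior_parietal_cortex_TA_R",
    "retrosplenial_cortex_TA_L",
    "middle_temporal_gyrus_TA_L",
]


def small_cohort_config(seed=0, **overrides):
    """Reduced cohort for fast tests: 40 MRI features, 3 planted markers."""
    names = default_mri_feature_names(40)
    informative = {names[0]: -1.4, names[9]: -1.3, names[17]: -1.2}
    defaults = dict(
        group_sizes={"NC": 40, "AD": 40, "MCInc": 30, "MCIc": 24},
        n_mri_features=40,
        informative_mri=informative,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def small_pipeline_config(seed=0, combos=(("NM", "CSF", "MRI"), ("CSF",)), **cohort_overrides):
    return PipelineConfig(
        cohort=small_cohort_config(**cohort_overrides),
        combos=tuple(combos),
        selection=SelectionParams(repeats=2, folds=5, max_subset_size=8),
        svm=SvmConfig(cv_folds=5),
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort shared across the suite (seed fixed)."""
    return generate_cohort(CohortConfig(seed=101))


@pytest.fixture(scope="session")
def default_model(default_cohort):
    """RBF-SVM trained on NC/AD with the strong known markers."""
    train = default_cohort.subset(["NC", "AD"])
    return train_svm(train.data.loc[:, STRONG_FEATURES], train.labels(), SvmConfig(seed=3))


@pytest.fixture(scope="session")
def default_predictions(default_model, default_cohort):
    return predict_cohort(default_model, default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
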