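"""Shared fixtures: phantom cohorts and trained models (session-scoped,
since LOOCV grid searches are the slow part of the suite)."""

import dataclasses
import warnings

import pytest

import minkrad as mk


@pytest.fixture(scope="session")
def train_df():
    """Default 10+10 phantom training cohort feature table."""
    cohort = mk.make_cohort(10, seed=0)
    return mk.features_to_frame(
        [mk.extract_features(img) for img in cohort.images]
    )


@pytest.fixture(scope="session")
def test_df():
    """Independent 10+10 phantom test cohort (different seed)."""
    cohort = mk.make_cohort(10, seed=1)
    return mk.features_to_frame(
        [mk.extract_features(img) for img in cohort.images]
    )


@pytest.fixture(scope="session")
def null_df():
    """Cohort whose two label groups share identical generative parameters."""
    null_prog = dataclasses.replace(
        mk.PSEUDOPROGRESSION_SPEC, label="progression"
    )
    cohort = mk.make_cohort(10, null_prog, mk.PSEUDOPROGRESSION_SPEC, seed=0)
    return mk.features_to_frame(
        [mk.extract_features(img) for img in cohort.images]
    )


@pytest.fixture(scope="session")
def svm_fit(train_df):
    return mk.train_model(train_df, method="ttest-svm", seed=0)


@pytest.fixture(scope="session")
def lasso_fit(train_df):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mk.train_model(train_df, method="rf-lasso", seed=0)
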