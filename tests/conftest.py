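"""Shared fixtures: synthetic cohorts at the sizes the checks need.

Heavy fixtures are session-scoped so the classifier suites and the
acceptance checks share one generation + preprocessing pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import skinraman as sr
from skinraman.preprocess import preprocess_dataset

#: fixture seed, chosen once for the whole suite
SEED = 11


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    return sr.synth.default_grid()


@pytest.fixture(scope="session")
def planted_processed():
    """20 patients per lesion, planted class effects, default noise."""
    ds = sr.generate_cohort(sr.CohortConfig.small(20, seed=SEED), sr.default_profiles())
    return preprocess_dataset(ds)


@pytest.fixture(scope="session")
def null_processed():
    """Same cohort shape with planted effects disabled (null classes)."""
    ds = sr.generate_cohort(
        sr.CohortConfig.small(20, seed=SEED), sr.default_profiles(effects=False)
    )
    return preprocess_dataset(ds)


@pytest.fixture(scope="session")
def tiny_processed():
    """10 patients per lesion — cheap fixture for contract tests."""
    ds = sr.generate_cohort(sr.CohortConfig.small(10, seed=SEED), sr.default_profiles())
    return preprocess_dataset(ds)


@pytest.fixture(scope="session")
def single_band_cv():
    """Two classes differing in exactly one band (1089 cm^-1, 2x), with a
    patient-grouped five-fold CNN cross-validation run on top.

    The CNN is trained for 30 epochs here (instead of the 100-epoch
    default) purely for runtime; the two classes are separated perfectly
    well before that.
    """
    from skinraman.evaluation import (
        CrossValidationResult,
        _report_from_scores,
        make_grouped_stratified_folds,
    )
    from skinraman.models import TrainingConfig, train

    profiles = sr.synth.two_class_single_band_profiles(1089.0, 2.0)
    cfg = sr.CohortConfig(
        n_patients_per_lesion={"BCC": 24},
        spectra_per_target={("BCC", "EPI-H"): 36, ("BCC", "LOB-T"): 36},
        seed=SEED,
    )
    ds = sr.generate_cohort(cfg, profiles)
    proc = preprocess_dataset(ds)
    X = proc.features
    y = proc.manifest["target"].to_numpy()
    folds = make_grouped_stratified_folds(
        proc.manifest["patient_id"].to_numpy(), y, k=5, seed=SEED
    )
    oof = np.zeros((len(y), 2))
    models = []
    for f in range(5):
        val = folds.spectrum_fold == f
        m = train("cnn", X[~val], y[~val], TrainingConfig(epochs=30, seed=SEED))
        oof[val] = m.predict_scores(X[val])
        models.append(m)
    report = _report_from_scores(oof, y, ("EPI-H", "LOB-T"), 0)
    cv = CrossValidationResult(
        report, oof, y, folds, ("EPI-H", "LOB-T"), proc.manifest, models, None
    )
    return cv, proc


class ConstantScoreEstimator:
    """Probe estimator whose output ignores the input entirely."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        return np.tile(self.scores, (np.asarray(X).shape[0], 1))


class SingleChannelEstimator:
    """Probe estimator that is a deterministic function of one channel."""

    def __init__(self, channel: int):
        self.channel = channel

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        p = 1.0 / (1.0 + np.exp(-X[:, self.channel]))
        return np.column_stack([1.0 - p, p])


@pytest.fixture
def constant_model():
    from skinraman.models import TrainedModel

    return TrainedModel(
        ConstantScoreEstimator([0.25, 0.75]), ("a", "b"), n_features=100, kind="probe"
    )


@pytest.fixture
def channel40_model():
    from skinraman.models import TrainedModel

    return TrainedModel(
        SingleChannelEstimator(40), ("a", "b"), n_features=100, kind="probe"
    )
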