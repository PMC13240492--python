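import dataclasses

import numpy as np
import pandas as pd
import pytest

import eswtcea as e
from eswtcea.survival import COEF_NAMES


def make_fit(shape=1.0, coeffs=None, vcov=None, family="weibull",
             loglik=0.0, n_events=10, n_censored=5) -> e.WeibullFit:
    """Hand-built fit object for controlled model runs."""
    if coeffs is None:
        coeffs = {}
    series = pd.Series({name: coeffs.get(name, 0.0) for name in COEF_NAMES})
    k = len(series) + (1 if family == "weibull" else 0)
    if vcov is None:
        vcov = np.zeros((k, k))
    return e.WeibullFit(shape=shape, coeffs=series, vcov=np.asarray(vcov),
                        loglik=loglik, n_events=n_events,
                        n_censored=n_censored, family=family)


def cohort_mean_profile(dataset: e.TrialDataset) -> e.CovariateProfile:
    frame = dataset.to_frame()
    return e.CovariateProfile(
        ulcer_age_days=float(frame["ulcer_age_days"].mean()),
        ulcer_area_cm2=float(frame["ulcer_area_cm2"].mean()),
        infected=float(frame["infected"].mean()),
    )


@pytest.fixture(scope="session")
def default_dataset() -> e.TrialDataset:
    """The default 74-patient synthetic trial."""
    return e.generate_trial(e.TrialConfig())


@pytest.fixture(scope="session")
def default_fit(default_dataset) -> e.WeibullFit:
    return e.fit_weibull_ph(default_dataset)


@pytest.fixture(scope="session")
def default_model(default_dataset, default_fit) -> e.DecisionModel:
    return e.DecisionModel(fit=default_fit,
                           profile=cohort_mean_profile(default_dataset))


@pytest.fixture(scope="session")
def big_dataset() -> e.TrialDataset:
    """A large trial (n=5000) so fitted coefficients sit close to truth."""
    cfg = dataclasses.replace(e.TrialConfig(), n_patients=5000, seed=11)
    return e.generate_trial(cfg)


@pytest.fixture(scope="session")
def big_fit(big_dataset) -> e.WeibullFit:
    return e.fit_weibull_ph(big_dataset)


@pytest.fixture(scope="session")
def big_model(big_dataset, big_fit) -> e.DecisionModel:
    return e.DecisionModel(fit=big_fit,
                           profile=cohort_mean_profile(big_dataset))


@pytest.fixture(scope="session")
def published_dists() -> e.ParameterDistributions:
    return e.ParameterDistributions.published()
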