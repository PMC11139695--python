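from hypothesis import settings

import numpy as np
import pandas as pd
import pytest

from dietclust import bdhq_schema, generate_cohort, study_like_preset
from dietclust.cohort import Cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def schema():
    return bdhq_schema()


@pytest.fixture(scope="session")
def preset_cohort():
    """One study-like synthetic cohort with latent labels (seed 0)."""
    scenario = study_like_preset(seed=0)
    return generate_cohort(scenario)


def make_cohort(schema, responses: dict, covariates: dict | None = None,
                n: int | None = None) -> Cohort:
    """Small cohort builder: ``responses`` maps variable id -> list of
    labels (or a single label broadcast to n); unspecified variables get
    their lowest category."""
    sizes = [len(v) for v in responses.values() if isinstance(v, (list, tuple))]
    if covariates:
        sizes += [len(v) for v in covariates.values()
                  if isinstance(v, (list, tuple, np.ndarray))]
    n = n or (sizes[0] if sizes else 1)
    data = {}
    for var in schema:
        spec = responses.get(var.id, var.scale_labels[0])
        vals = list(spec) if isinstance(spec, (list, tuple)) else [spec] * n
        data[var.id] = pd.Categorical(
            vals, categories=list(var.scale_labels), ordered=True)
    for key, spec in (covariates or {}).items():
        data[key] = (list(spec) if isinstance(spec, (list, tuple, np.ndarray))
                     else [spec] * n)
    df = pd.DataFrame(data, index=pd.Index([f"p{i}" for i in range(n)],
                                           name="id"))
    return Cohort(schema, df)


@pytest.fixture
def cohort_factory(schema):
    def factory(responses, covariates=None, n=None):
        return make_cohort(schema, responses, covariates, n)
    return factory
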