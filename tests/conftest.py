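import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

import pharmscreen as ps
from pharmscreen.feature_matrix import FeatureMatrix


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return ps.generate_cohort(ps.CohortSpec(n_lines=60, seed=3))


@pytest.fixture(scope="session")
def noiseless_screen(small_cohort):
    """A 60-line screen with zero measurement noise and known truth."""
    spec = ps.ScreenSpec(noise_sd=0.0)
    wells, truth = ps.generate_screen(small_cohort, None, spec, seed=7)
    return wells, truth, spec


def make_feature_matrix(X: pd.DataFrame, y: pd.Series) -> FeatureMatrix:
    """Wrap a prefixed design matrix and response into a FeatureMatrix."""
    counts: dict[str, int] = {}
    for c in X.columns:
        counts[c.split("_", 1)[0]] = counts.get(c.split("_", 1)[0], 0) + 1
    return FeatureMatrix(X=X, y=y,
                         censored_mask=pd.Series(False, index=X.index),
                         type_counts=counts)


def null_feature_matrix(n: int, p: int, seed: int) -> FeatureMatrix:
    """Gaussian X and a response independent of every feature."""
    rng = np.random.default_rng(seed)
    idx = [f"CL{i:04d}" for i in range(n)]
    X = pd.DataFrame(rng.standard_normal((n, p)), index=idx,
                     columns=[f"EXP_G{i:04d}" for i in range(p)])
    y = pd.Series(rng.standard_normal(n), index=idx)
    return make_feature_matrix(X, y)
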