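import numpy as np
import pandas as pd
import pytest

from dsign import Cohort, TransformSpec, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def _mvn_cohort(n, p, seed, mean=None, cov=None, label="mvn", marker_names=None):
    """Cohort whose biomarkers are a raw multivariate-normal draw.

    Used with identity transforms so distributional statements about the
    Mahalanobis distance (chi-square law, moment identities) hold exactly.
    """
    rng = np.random.default_rng(seed)
    mean = np.zeros(p) if mean is None else np.asarray(mean, dtype=float)
    cov = np.eye(p) if cov is None else np.asarray(cov, dtype=float)
    X = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    names = marker_names or [f"m{j}" for j in range(p)]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "subject_id", [f"{label}_{i}" for i in range(n)])
    df.insert(1, "age", rng.uniform(30, 80, size=n))
    return Cohort(label, df, names)


@pytest.fixture(scope="session")
def mvn_cohort():
    return _mvn_cohort


@pytest.fixture(scope="session")
def identity_spec():
    def make(names):
        return TransformSpec.identity(names)

    return make


def random_pd_cov(p, rng):
    """Random well-conditioned positive-definite covariance."""
    A = rng.standard_normal((p, p))
    S = A @ A.T + p * np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
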