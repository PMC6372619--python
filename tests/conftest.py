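"""Shared fixtures: small matrices and one full-scale decomposition run."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from olsa import OLSAConfig, SyntheticSpec, generate, run_olsa
from olsa.io import ExpressionMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: study conditions of the recovery suite; the seed is fixed once
RECOVERY_SPEC = SyntheticSpec(
    n_genes=2000,
    n_samples=150,
    k_factors=6,
    sparsity=0.05,
    noise_sd=0.1,
    seed=0,
)


@pytest.fixture(scope="session")
def recovery_data():
    """Synthetic matrix + ground truth under the recovery study conditions."""
    return generate(RECOVERY_SPEC)


@pytest.fixture(scope="session")
def recovery_run(recovery_data):
    """Full decomposition of the recovery matrix (shared, read-only)."""
    d, gt = recovery_data
    return d, gt, run_olsa(d, OLSAConfig())


@pytest.fixture
def tiny_expression():
    """6 genes x 6 samples with 3 controls, values well spread per sample."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(size=(6, 6)) * 10,
        index=[f"g{i}" for i in range(6)],
        columns=["c1", "c2", "c3", "t1", "t2", "t3"],
    )
    mask = np.array([True, True, True, False, False, False])
    return ExpressionMatrix(data, mask)


@pytest.fixture
def small_response():
    """A 30-gene x 12-sample response matrix with mild factor structure."""
    rng = np.random.default_rng(7)
    w = np.zeros((30, 2))
    w[:10, 0] = rng.normal(size=10)
    w[10:20, 1] = rng.normal(size=10)
    w /= np.linalg.norm(w, axis=0)
    s = rng.laplace(scale=3.0, size=(2, 12))
    d = w @ s + rng.normal(scale=0.05, size=(30, 12))
    return pd.DataFrame(
        d, index=[f"g{i:02d}" for i in range(30)], columns=[f"s{i:02d}" for i in range(12)]
    )
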