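import numpy as np
import pytest

import cohortlasso as cl


@pytest.fixture(scope="session")
def csdh_cohort() -> cl.CohortTable:
    """One realization of the 93 x 30 preset cohort, with missingness."""
    return cl.make_cohort(cl.csdh93(seed=11))


@pytest.fixture(scope="session")
def collapsed_cohort(csdh_cohort) -> cl.CohortTable:
    """The preset cohort imputed (m=15) and collapsed to a single table."""
    return cl.chained_imputation(csdh_cohort, m=15, iterations=10, seed=7).collapsed


@pytest.fixture(scope="session")
def rrr_design(collapsed_cohort) -> cl.StandardizedDesign:
    return cl.standardize(collapsed_cohort, "rrr")


def random_gaussian_design(rng, n=60, p=8, sparsity=3, noise=0.5):
    """Small well-conditioned regression problem on standardized predictors."""
    x = rng.standard_normal((n, p)) * rng.uniform(0.5, 2.0, size=p) + rng.normal(
        0, 1, size=p
    )
    beta = np.zeros(p)
    beta[:sparsity] = rng.normal(0, 1, size=sparsity)
    y = x @ beta + rng.normal(0, noise, size=n)
    return cl.standardize_matrix(x, y)


def orthonormal_design(rng, n=64, p=6, noise=0.5):
    """Design with z.T @ z / n exactly the identity and mean-zero columns."""
    raw = rng.standard_normal((n, p + 1))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    z = q[:, :p] * np.sqrt(n)
    beta = rng.normal(0, 1.5, size=p)
    y = z @ beta + rng.normal(0, noise, size=n)
    design = cl.StandardizedDesign(
        z=z,
        centers=np.zeros(p),
        scales=np.ones(p),
        y=y,
        predictor_names=[f"x{j}" for j in range(p)],
    )
    return design
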