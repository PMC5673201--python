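"""From-scratch L1-penalized (lasso) regression.

For k standardized predictors z_1..z_k and outcome y the solver minimizes
the Lagrangian (penalty) form of the lasso,

    gaussian:  (1/(2n)) sum_i (y_i - b0 - z_i b)^2 + lam * sum_j |b_j|
    binomial:  (1/n) * [binomial negative log-likelihood] + lam * sum_j |b_j|

by pathwise cyclic coordinate descent (binomial outcomes via iteratively
reweighted least squares with an inner coordinate-descent solve of each
quadratic subproblem), warm-started along a decreasing lambda grid. The
intercept is never penalized, and the binary outcome itself is not
standardized. Coefficients are reported on both the standardized scale (the
scale the penalty acts on) and the original predictor scale.

Predictors are standardized to mean 0 and SD 1 (population denominator n)
before fitting; lambda is on the penalty scale, so lambda_max — the
smallest penalty with an all-zero solution — is max_j |<z_j, y - ybar>| / n
for the gaussian family and max_j |<z_j, y - pbar>| / n for the binomial
family (pbar the event prevalence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._solver import binomial_path, gaussian_path
from .cohort import CohortTable

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100_000
_IRLS_MAX = 100
_W_FLOOR = 1e-5
_P_SAT = 1e-5


def soft_threshold(value: float, threshold: float) -> float:
    """sign(value) * max(|value| - threshold, 0) — the scalar L1 update."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if value > threshold:
        return value - threshold
    if value < -threshold:
        return value + threshold
    return 0.0


@dataclass
class StandardizedDesign:
    """Predictor matrix standardized to column mean 0, SD 1.

    Keeps the original column means (``centers``) and SDs (``scales``) so
    fitted coefficients can be mapped back to the original scale.
    """

    z: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    y: np.ndarray
    predictor_names: list[str]
    outcome_name: str = "y"

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def k(self) -> int:
        return self.z.shape[1]

    def rows(self, idx: np.ndarray) -> "StandardizedDesign":
        """Row subset sharing the full-data standardization."""
        return StandardizedDesign(
            z=self.z[idx],
            centers=self.centers,
            scales=self.scales,
            y=self.y[idx],
            predictor_names=self.predictor_names,
            outcome_name=self.outcome_name,
        )


def standardize_matrix(
    x: np.ndarray,
    y: np.ndarray,
    predictor_names: list[str] | None = None,
    outcome_name: str = "y",
) -> StandardizedDesign:
    """Standardize a raw predictor matrix column-wise: (x - mean) / SD,
    with the population (denominator n) SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(x).any():
        raise ValueError("predictor matrix contains missing values")
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(x.shape[1])]
    centers = x.mean(axis=0)
    scales = x.std(axis=0)
    if (scales == 0).any():
        bad = predictor_names[int(np.argmax(scales == 0))]
        raise ValueError(f"zero-variance predictor column {bad!r}")
    return StandardizedDesign(
        z=(x - centers) / scales,
        centers=centers,
        scales=scales,
        y=y,
        predictor_names=list(predictor_names),
        outcome_name=outcome_name,
    )


def standardize(table: CohortTable, outcome: str) -> StandardizedDesign:
    """Standardize a complete cohort's biomarkers against outcome ``outcome``."""
    if outcome not in table.outcome_names:
        raise ValueError(f"unknown outcome column {outcome!r}")
    if table.missing_mask.any().any():
        raise ValueError("standardize requires a complete biomarker matrix")
    return standardize_matrix(
        table.biomarkers.to_numpy(dtype=float),
        table.outcomes[outcome].to_numpy(dtype=float),
        predictor_names=table.biomarker_names,
        outcome_name=outcome,
    )


def lambda_max(design: StandardizedDesign, family: str) -> float:
    """Smallest penalty at which every penalized coefficient is zero."""
    y = design.y
    if family == "gaussian":
        resid = y - y.mean()
    elif family == "binomial":
        _check_binary(y)
        resid = y - y.mean()
    else:
        raise ValueError(f"unknown family {family!r}")
    # The relative nudge keeps the all-zero solution exactly optimal at
    # lambda_max under a different floating-point summation order.
    return float(np.abs(design.z.T @ resid).max() / design.n) * (1.0 + 1e-12)


def lambda_grid(
    design: StandardizedDesign,
    family: str = "gaussian",
    n_lambda: int = 100,
    min_ratio: float = 1e-4,
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max to min_ratio * lambda_max."""
    if np.ptp(design.y) == 0:
        raise ValueError("constant outcome: no penalized model to fit")
    lmax = lambda_max(design, family)
    if n_lambda == 1:
        return np.array([lmax])
    return lmax * np.logspace(0.0, np.log10(min_ratio), n_lambda)


def _check_binary(y: np.ndarray) -> None:
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial family requires a {0,1} outcome")
    if y.min() == y.max():
        raise ValueError("binomial family requires both outcome classes")


@dataclass
class LassoPath:
    """Solutions along a decreasing lambda grid.

    ``coef_std``/``intercept_std`` are on the standardized-predictor scale;
    ``coef_raw``/``intercept_raw`` are mapped back to the original predictor
    scale. ``deviance`` is the mean training deviance at each lambda (MSE
    for gaussian; -2 * mean log-likelihood for binomial). ``converged`` and
    ``saturated`` flag solver trouble per lambda; both feed the downstream
    robustness screen.
    """

    lambdas: np.ndarray
    family: str
    coef_std: np.ndarray
    intercept_std: np.ndarray
    coef_raw: np.ndarray
    intercept_raw: np.ndarray
    deviance: np.ndarray
    converged: np.ndarray
    saturated: np.ndarray
    predictor_names: list[str]
    centers: np.ndarray
    scales: np.ndarray

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)

    def index_of(self, at_lambda: float) -> int:
        """Index of an exact grid value (no interpolation)."""
        hits = np.flatnonzero(
            np.isclose(self.lambdas, at_lambda, rtol=1e-12, atol=0.0)
        )
        if len(hits) == 0:
            raise KeyError(f"lambda {at_lambda!r} is not on the fitted grid")
        return int(hits[0])

    def n_nonzero(self) -> np.ndarray:
        return (self.coef_std != 0).sum(axis=1)


def _deviance(eta: np.ndarray, y: np.ndarray, family: str) -> float:
    if family == "gaussian":
        return float(np.mean((y - eta) ** 2))
    prob = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def fit_path(
    design: StandardizedDesign,
    grid: np.ndarray | None = None,
    family: str = "gaussian",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LassoPath:
    """Fit the lasso path over a decreasing lambda grid with warm starts."""
    z, y = design.z, design.y
    if not (np.isfinite(z).all() and np.isfinite(y).all()):
        raise ValueError("design contains NaN or Inf")
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    if grid is None:
        grid = lambda_grid(design, family)
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and not (np.diff(grid) < 0).all():
        raise ValueError("lambda grid must be strictly decreasing")

    if family == "gaussian":
        coefs, intercepts, converged = gaussian_path(
            np.ascontiguousarray(z), np.ascontiguousarray(y), grid, tol, max_iter
        )
        saturated = np.zeros(len(grid), dtype=bool)
    else:
        _check_binary(y)
        coefs, intercepts, converged, saturated = binomial_path(
            np.ascontiguousarray(z), np.ascontiguousarray(y), grid, tol, max_iter,
            _IRLS_MAX, _W_FLOOR, _P_SAT,
        )

    deviance = np.array(
        [_deviance(intercepts[l] + z @ coefs[l], y, family) for l in range(len(grid))]
    )
    coef_raw = coefs / design.scales
    intercept_raw = intercepts - coef_raw @ design.centers
    return LassoPath(
        lambdas=grid,
        family=family,
        coef_std=coefs,
        intercept_std=intercepts,
        coef_raw=coef_raw,
        intercept_raw=intercept_raw,
        deviance=deviance,
        converged=converged,
        saturated=saturated,
        predictor_names=design.predictor_names,
        centers=design.centers,
        scales=design.scales,
    )


@dataclass
class Prediction:
    """Linear predictor (original scale) and, for binomial fits,
    inverse-logit probabilities."""

    linear: np.ndarray
    prob: np.ndarray | None = None


def predict(path: LassoPath, at_lambda: float, new_data) -> Prediction:
    """Score new observations at an exact grid lambda.

    ``new_data`` may be a CohortTable (biomarker columns are matched by
    name) or a raw (original-scale) matrix with columns in path order.
    """
    idx = path.index_of(at_lambda)
    if isinstance(new_data, CohortTable):
        x = new_data.biomarkers[path.predictor_names].to_numpy(dtype=float)
    else:
        x = np.asarray(new_data, dtype=float)
    eta = path.intercept_raw[idx] + x @ path.coef_raw[idx]
    if path.family == "binomial":
        return Prediction(linear=eta, prob=1.0 / (1.0 + np.exp(-eta)))
    return Prediction(linear=eta)
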