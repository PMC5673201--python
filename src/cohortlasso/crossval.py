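"""K-fold cross-validation, the repeated-CV robustness screen and AUC.

The protocol mirrors how the analysis establishes a *robust* biomarker-
outcome association:

1. A screening phase of ``n_screen`` (default 50) independent 10-fold
   cross-validated lasso fits. If any round either selects the null model
   (optimal lambda at the top of the path, every coefficient zero) or hits
   solver convergence/saturation trouble, the association is declared not
   robust and no coefficient table is produced.
2. Otherwise a recording phase of ``n_record`` (default 100) fresh rounds;
   per biomarker the mean, SD, min, max and median of the full-data refit
   coefficients at each round's optimal lambda are summarized, together
   with the optimal-lambda and in-sample AUC distributions and each
   biomarker's selection frequency (fraction of rounds with a nonzero
   coefficient).

Lambda is selected as the strict minimizer of the cross-validation error
curve (ties resolved toward the larger, more parsimonious lambda). AUC is
the rank-based Mann-Whitney concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .lasso import LassoPath, StandardizedDesign, _deviance, fit_path, lambda_grid

__all__ = [
    "kfold_split",
    "auc",
    "cross_validate",
    "stability_protocol",
    "CVRound",
    "StabilitySummary",
]


def kfold_split(n: int, k: int, seed, labels: np.ndarray | None = None) -> np.ndarray:
    """Random partition of ``range(n)`` into k folds of near-equal size.

    With binary ``labels`` the split is stratified: each fold's event count
    differs from exact proportionality by at most 1 (dealt round-robin with
    a carried offset, so fold sizes still differ by at most 1). Raises if
    the rarer class has fewer members than k, since a zero-event fold would
    then be unavoidable — use a smaller k.
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    if labels is None:
        perm = rng.permutation(n)
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        start = 0
        for f, size in enumerate(sizes):
            fold[perm[start:start + size]] = f
            start += size
        return fold
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratified split impossible: class {classes[np.argmin(counts)]!r} "
            f"has {counts.min()} members < k={k}; choose a smaller k"
        )
    offset = int(rng.integers(k))
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for i, t in enumerate(idx):
            fold[t] = (offset + i) % k
        offset = (offset + len(idx)) % k
    return fold


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance: P(score_event > score_nonevent) + ties/2.

    Computed from midranks, so exactly equal to the pairwise count
    (concordant pairs + half the tied pairs) / (n1 * n0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be in {0, 1}")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both outcome classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CVRound:
    """One repetition of k-fold cross-validation over a lambda grid."""

    seed: object
    fold_assignment: np.ndarray
    cv_error: np.ndarray
    optimal_lambda: float
    optimal_index: int
    coef_std: np.ndarray
    coef_raw: np.ndarray
    intercept_std: float
    intercept_raw: float
    auc: float | None
    all_zero: bool
    convergence_failure: bool


def cross_validate(
    design: StandardizedDesign,
    grid: np.ndarray | None = None,
    family: str = "gaussian",
    k: int = 10,
    seed=0,
    stratify: bool | None = None,
    full_path: LassoPath | None = None,
    tol: float = 1e-7,
) -> CVRound:
    """One round of k-fold CV: held-out deviance per lambda, optimal-lambda
    refit on the full data, and (binomial) in-sample AUC of the refit.

    ``full_path`` may carry a precomputed full-data path (it is
    deterministic given the design and grid), in which case the refit is
    read off it. A training fold with a constant outcome is reported via
    ``convergence_failure`` rather than an exception.
    """
    if grid is None:
        grid = lambda_grid(design, family)
    if stratify is None:
        stratify = family == "binomial"
    labels = design.y if stratify else None
    fold = kfold_split(design.n, k, seed, labels=labels)

    fold_dev = np.zeros((k, len(grid)))
    constant_fold = False
    for f in range(k):
        test = fold == f
        train = ~test
        y_train = design.y[train]
        if np.ptp(y_train) == 0:
            constant_fold = True
            fold_dev[f] = np.nan
            continue
        sub = design.rows(train)
        path = fit_path(sub, grid=grid, family=family, tol=tol)
        eta = path.intercept_std[:, None] + path.coef_std @ design.z[test].T
        y_test = design.y[test]
        for l in range(len(grid)):
            fold_dev[f, l] = _deviance(eta[l], y_test, family)

    cv_error = np.nanmean(fold_dev, axis=0)
    if full_path is None:
        full_path = fit_path(design, grid=grid, family=family, tol=tol)
    # The usable path ends where the full-data fit saturates (the binomial
    # solutions diverge beyond it); the CV optimum is chosen on the usable
    # part, as the first minimum (= largest lambda on ties).
    eligible = ~full_path.saturated
    opt = int(np.argmin(np.where(eligible, cv_error, np.inf)))
    coef_std = full_path.coef_std[opt]
    all_zero = bool((coef_std == 0).all())
    # Trouble counts against the model actually reported: non-convergence or
    # saturation of the full-data refit at the selected lambda, or a fold
    # whose training outcome was constant. Fold fits saturating deep in the
    # path is routine near-separation and does not impugn the refit.
    refit_trouble = bool(
        (not full_path.converged[opt]) or full_path.saturated[opt]
    )
    fold_trouble = constant_fold
    auc_value = None
    if family == "binomial":
        eta_full = full_path.intercept_std[opt] + design.z @ coef_std
        auc_value = auc(eta_full, design.y)
    return CVRound(
        seed=seed,
        fold_assignment=fold,
        cv_error=cv_error,
        optimal_lambda=float(grid[opt]),
        optimal_index=opt,
        coef_std=coef_std.copy(),
        coef_raw=full_path.coef_raw[opt].copy(),
        intercept_std=float(full_path.intercept_std[opt]),
        intercept_raw=float(full_path.intercept_raw[opt]),
        auc=auc_value,
        all_zero=all_zero,
        convergence_failure=fold_trouble or refit_trouble,
    )


def _summary(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return {
        "mean": float(values.mean()),
        "sd": sd,
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
    }


@dataclass
class StabilitySummary:
    """Across-round summaries and the robustness verdict."""

    robust: bool
    n_screen: int
    n_record: int
    screen_failures: list[dict] = field(default_factory=list)
    coef_table: pd.DataFrame | None = None
    coef_table_std: pd.DataFrame | None = None
    lambda_summary: dict | None = None
    auc_summary: dict | None = None
    rounds: pd.DataFrame | None = None


def _coef_table(
    names: list[str], coefs: np.ndarray
) -> pd.DataFrame:
    rows = []
    for j, name in enumerate(names):
        stats = _summary(coefs[:, j])
        stats["selection_frequency"] = float((coefs[:, j] != 0).mean())
        rows.append({"term": name, **stats})
    return pd.DataFrame(rows)[
        ["term", "mean", "sd", "min", "max", "median", "selection_frequency"]
    ]


def stability_protocol(
    design: StandardizedDesign,
    grid: np.ndarray | None = None,
    family: str = "gaussian",
    k: int = 10,
    n_screen: int = 50,
    n_record: int = 100,
    seed=0,
    stop_early: bool = True,
    tol: float = 1e-7,
) -> StabilitySummary:
    """Run the two-phase repeated-CV robustness protocol.

    Screening and recording rounds draw from disjoint seed streams spawned
    from ``seed``; the recording rounds are fresh draws, not a reuse of the
    screen. With ``stop_early`` the screen halts at the first disqualifying
    round (the verdict is already decided).
    """
    if n_screen < 1 or n_record < 1:
        raise ValueError("n_screen and n_record must be >= 1")
    if grid is None:
        grid = lambda_grid(design, family)
    if family == "binomial":
        counts = np.unique(design.y, return_counts=True)[1]
        if counts.min() < k:
            # stratified k-fold CV cannot even be formed: no clean
            # cross-validated model exists, hence no robust association
            return StabilitySummary(
                robust=False,
                n_screen=n_screen,
                n_record=n_record,
                screen_failures=[
                    {
                        "round": -1,
                        "all_zero": False,
                        "convergence_failure": True,
                        "reason": (
                            f"stratified {k}-fold split infeasible: rarer "
                            f"outcome class has only {int(counts.min())} members"
                        ),
                    }
                ],
            )
    screen_ss, record_ss = np.random.SeedSequence(seed).spawn(2)
    full_path = fit_path(design, grid=grid, family=family, tol=tol)

    failures = []
    for i, child in enumerate(screen_ss.spawn(n_screen)):
        rnd = cross_validate(
            design, grid=grid, family=family, k=k, seed=child,
            full_path=full_path, tol=tol,
        )
        if rnd.all_zero or rnd.convergence_failure:
            failures.append(
                {
                    "round": i,
                    "all_zero": rnd.all_zero,
                    "convergence_failure": rnd.convergence_failure,
                    "optimal_lambda": rnd.optimal_lambda,
                }
            )
            if stop_early:
                break
    if failures:
        return StabilitySummary(
            robust=False,
            n_screen=n_screen,
            n_record=n_record,
            screen_failures=failures,
        )

    names = design.predictor_names
    records = []
    coef_raw = np.zeros((n_record, len(names)))
    coef_std = np.zeros((n_record, len(names)))
    for i, child in enumerate(record_ss.spawn(n_record)):
        rnd = cross_validate(
            design, grid=grid, family=family, k=k, seed=child,
            full_path=full_path, tol=tol,
        )
        coef_raw[i] = rnd.coef_raw
        coef_std[i] = rnd.coef_std
        rec = {"round": i, "optimal_lambda": rnd.optimal_lambda}
        if rnd.auc is not None:
            rec["auc"] = rnd.auc
        rec.update({name: rnd.coef_raw[j] for j, name in enumerate(names)})
        records.append(rec)
    rounds = pd.DataFrame(records)
    lambdas = rounds["optimal_lambda"].to_numpy()
    return StabilitySummary(
        robust=True,
        n_screen=n_screen,
        n_record=n_record,
        coef_table=_coef_table(names, coef_raw),
        coef_table_std=_coef_table(names, coef_std),
        lambda_summary=_summary(lambdas),
        auc_summary=_summary(rounds["auc"].to_numpy()) if "auc" in rounds else None,
        rounds=rounds,
    )
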