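"""Chained-equations multiple imputation and its Cohen's d audit.

Missing biomarker cells are filled by multiple imputation with chained
equations using linear regression: each incomplete column is regressed on
all other biomarker columns and its missing cells replaced by the predicted
mean plus Gaussian residual noise (proper imputation). The M completed
matrices are then collapsed into one analysis table by the cell-wise mean,
and the impact of the procedure on each biomarker's distribution is audited
with Cohen's d — the standardized difference between the observed-data mean
and the post-imputation full-cohort mean, scaled by the pooled SD

    d = (mean_before - mean_after) / s,
    s = sqrt(((n1 - 1) s1^2 + (n2 - 1) s2^2) / (n1 + n2 - 2)),

with sample SDs (denominator n - 1). Outcome columns are never imputed and
never used as predictors, so no outcome information leaks into the filled
values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable

logger = logging.getLogger(__name__)

_RIDGE = 1e-6


# -- Cohen's d from summary statistics -------------------------------------


def pooled_sd(n1: int, sd1: float, n2: int, sd2: float) -> float:
    """Two-sample pooled SD with n1 + n2 - 2 degrees of freedom."""
    if n1 + n2 < 3:
        raise ValueError("pooled SD requires n1 + n2 >= 3")
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


def cohens_d(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> float:
    """Cohen's d standardized mean difference, (mean1 - mean2) / pooled SD."""
    if mean1 == mean2:
        return 0.0
    return (mean1 - mean2) / pooled_sd(n1, sd1, n2, sd2)


# -- chained equations -----------------------------------------------------


@dataclass
class ImputationResult:
    """M completed biomarker matrices plus their cell-wise-mean collapse.

    Observed cells are bit-identical across all M matrices and equal the
    input; each collapsed cell lies inside [min, max] of its M draws.
    ``max_changes`` logs, per imputation and chained-equation cycle, the
    largest absolute change of any imputed cell (a convergence monitor).
    """

    imputations: list[pd.DataFrame]
    collapsed: CohortTable
    m: int
    iterations: int
    seed: int
    max_changes: list[list[float]] = field(default_factory=list)


def _regress(design: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; ridge-stabilized on rank deficiency.

    Returns (coefficients including intercept, residual SD). The residual SD
    uses RSS / max(n - rank, 1) so perfectly collinear predictors yield an
    exact (noise-free) imputation.
    """
    a = np.column_stack([np.ones(len(design)), design])
    coef, rss_arr, rank, _ = np.linalg.lstsq(a, response, rcond=None)
    if rank < a.shape[1]:
        logger.debug("rank-deficient imputation design; ridge fallback (%g)", _RIDGE)
        gram = a.T @ a + _RIDGE * np.eye(a.shape[1])
        coef = np.linalg.solve(gram, a.T @ response)
    resid = response - a @ coef
    rss = float(resid @ resid)
    dof = max(len(response) - rank, 1)
    return coef, math.sqrt(max(rss, 0.0) / dof)


def chained_imputation(
    table: CohortTable, m: int = 15, iterations: int = 10, seed: int = 0
) -> ImputationResult:
    """Run M chained-equation imputations of the biomarker columns.

    Each imputation initializes missing cells at the column's observed mean,
    then performs ``iterations`` cycles visiting incomplete columns in order
    of ascending missing count (ties by column order); within a cycle the
    column's observed values are regressed on all other biomarker columns at
    their current working values, and its missing cells are redrawn as
    predicted mean + N(0, residual SD). Imputations use independent child
    streams spawned from ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    names = table.biomarker_names
    if len(names) < 2:
        raise ValueError("chained imputation needs at least 2 biomarker columns")
    x = table.biomarkers.to_numpy(dtype=float)
    mask = np.isnan(x)
    n_missing = mask.sum(axis=0)
    if (len(x) - n_missing < 2).any():
        bad = names[int(np.argmax(len(x) - n_missing < 2))]
        raise ValueError(f"biomarker {bad!r} has fewer than 2 observed values")

    visit = [j for j in np.argsort(n_missing, kind="stable") if n_missing[j] > 0]
    col_means = np.nanmean(x, axis=0)
    children = np.random.SeedSequence(seed).spawn(m)

    imputations: list[pd.DataFrame] = []
    max_changes: list[list[float]] = []
    for child in children:
        rng = np.random.default_rng(child)
        work = x.copy()
        for j in range(work.shape[1]):
            work[mask[:, j], j] = col_means[j]
        changes = []
        for _ in range(iterations):
            cycle_max = 0.0
            for j in visit:
                obs = ~mask[:, j]
                others = np.delete(np.arange(work.shape[1]), j)
                coef, resid_sd = _regress(work[obs][:, others], x[obs, j])
                pred = coef[0] + work[~obs][:, others] @ coef[1:]
                draw = pred + rng.normal(0.0, resid_sd, size=pred.shape)
                lo, hi = x[obs, j].min(), x[obs, j].max()
                n_out = int(((draw < lo) | (draw > hi)).sum())
                if n_out:
                    logger.debug(
                        "%d imputed value(s) outside observed range for column %s",
                        n_out, names[j],
                    )
                delta = np.abs(draw - work[~obs, j]).max()
                cycle_max = max(cycle_max, float(delta))
                work[~obs, j] = draw
            changes.append(cycle_max)
        imputations.append(
            pd.DataFrame(work, index=table.patient_ids, columns=names)
        )
        max_changes.append(changes)

    collapsed_values = np.mean([imp.to_numpy() for imp in imputations], axis=0)
    collapsed_values[~mask] = x[~mask]  # observed cells pass through exactly
    collapsed = CohortTable(
        patient_ids=table.patient_ids.copy(),
        biomarkers=pd.DataFrame(
            collapsed_values, index=table.patient_ids, columns=names
        ),
        outcomes=table.outcomes.copy(),
    )
    return ImputationResult(
        imputations=imputations,
        collapsed=collapsed,
        m=m,
        iterations=iterations,
        seed=seed,
        max_changes=max_changes,
    )


def collapse_to_single(
    result: ImputationResult, table: CohortTable | None = None
) -> CohortTable:
    """Collapse M imputations to one table by the cell-wise arithmetic mean.

    Observed cells of the source table pass through unchanged
    (bit-identical); missing cells take the mean of the M imputed draws.
    When ``table`` is omitted the collapse computed at imputation time is
    returned.
    """
    if table is None:
        return result.collapsed
    x = table.biomarkers.to_numpy(dtype=float)
    mask = np.isnan(x)
    values = np.mean([imp.to_numpy() for imp in result.imputations], axis=0)
    values[~mask] = x[~mask]
    return CohortTable(
        patient_ids=table.patient_ids.copy(),
        biomarkers=pd.DataFrame(
            values, index=table.patient_ids, columns=table.biomarker_names
        ),
        outcomes=table.outcomes.copy(),
    )


# -- audit -----------------------------------------------------------------


def cohen_d_audit(before: CohortTable, after: CohortTable) -> pd.DataFrame:
    """Per-biomarker before/after imputation audit (Cohen's d effect size).

    Returns a DataFrame with one row per biomarker: ``n1``/``mean1``/``sd1``
    on the observed data, ``n2``/``mean2``/``sd2`` on the completed data,
    the pooled SD and ``cohen_d``. Biomarkers without missing data carry a
    NaN d (imputation cannot have affected them); a biomarker with fewer
    than 2 observed values is flagged (``d_defined`` False).
    """
    if before.biomarker_names != after.biomarker_names:
        raise ValueError("before/after tables have different biomarker columns")
    if after.missing_mask.any().any():
        raise ValueError("after table must be complete")
    rows = []
    for col in before.biomarker_names:
        obs = before.biomarkers[col].dropna().to_numpy()
        full = after.biomarkers[col].to_numpy()
        n1, n2 = len(obs), len(full)
        rec: dict = {"biomarker": col, "n1": n1, "n2": n2}
        rec["mean2"] = full.mean()
        rec["sd2"] = full.std(ddof=1)
        if n1 < 2:
            rec.update(mean1=np.nan, sd1=np.nan, pooled_sd=np.nan,
                       cohen_d=np.nan, d_defined=False)
        else:
            rec["mean1"] = obs.mean()
            rec["sd1"] = obs.std(ddof=1)
            if n1 == n2:  # no missing data: imputation is a no-op here
                rec.update(pooled_sd=np.nan, cohen_d=np.nan, d_defined=False)
            else:
                rec["pooled_sd"] = pooled_sd(n1, rec["sd1"], n2, rec["sd2"])
                rec["cohen_d"] = cohens_d(
                    n1, rec["mean1"], rec["sd1"], n2, rec["mean2"], rec["sd2"]
                )
                rec["d_defined"] = True
        rows.append(rec)
    cols = ["biomarker", "n1", "mean1", "sd1", "n2", "mean2", "sd2",
            "pooled_sd", "cohen_d", "d_defined"]
    return pd.DataFrame(rows)[cols]
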