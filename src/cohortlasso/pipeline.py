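"""End-to-end pipeline: cohort -> imputation -> audit -> lasso stability.

Runs the full analysis from a single config: load a cohort CSV (or generate
the ``csdh93`` synthetic preset), impute missing biomarkers by chained
equations and collapse to a single table, audit the imputation with Cohen's
d, then run the repeated-CV lasso stability protocol for every requested
outcome in one or both analysis arms:

- ``all``: every biomarker, on the imputed (collapsed) table;
- ``complete``: only biomarkers observed for every patient (no imputation
  enters these columns; cohort rows are unchanged).

Outputs per run directory: ``audit.csv`` (full precision) and
``audit_rounded.csv``, per outcome x arm a rendered ``summary_*.csv``
(coefficients/effect sizes to 2 decimals, lambda to 3, AUC to 2), a
full-precision ``summary_*_full.csv``, a per-round ``rounds_*.csv`` log,
and ``run.log`` recording the operation and child seed behind every random
draw. For a non-robust outcome the summary file is replaced by a stamped
"not presented" record listing the disqualifying rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .cohort import CohortTable, read_cohort, write_cohort
from .crossval import stability_protocol
from .impute import chained_imputation, cohen_d_audit
from .lasso import lambda_grid, standardize

logger = logging.getLogger(__name__)

_PRESETS = {"csdh93": synthetic.csdh93}


@dataclass
class RunConfig:
    """Pipeline settings; mirrors the YAML config layout."""

    outcomes: list[dict]  # each {"name": ..., "family": "binomial"|"gaussian"}
    input: str | None = None
    preset: str | None = None
    arms: list[str] = field(default_factory=lambda: ["all", "complete"])
    m: int = 15
    iterations: int = 10
    n_lambda: int = 100
    min_ratio: float = 1e-4
    tol: float = 1e-7
    k: int = 10
    n_screen: int = 50
    n_record: int = 100
    seed: int = 0
    outdir: str = "runs/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate(self) -> None:
        if (self.input is None) == (self.preset is None):
            raise ValueError("config: exactly one of 'input' or 'preset' required")
        if self.preset is not None and self.preset not in _PRESETS:
            raise ValueError(f"config.preset: unknown preset {self.preset!r}")
        for i, out in enumerate(self.outcomes):
            if "name" not in out or "family" not in out:
                raise ValueError(f"config.outcomes[{i}]: needs 'name' and 'family'")
            if out["family"] not in ("binomial", "gaussian"):
                raise ValueError(
                    f"config.outcomes[{i}].family: {out['family']!r} invalid"
                )
        for arm in self.arms:
            if arm not in ("all", "complete"):
                raise ValueError(f"config.arms: unknown arm {arm!r}")
        if not (self.m >= 1 and self.iterations >= 1 and self.k >= 2):
            raise ValueError("config: m, iterations >= 1 and k >= 2 required")


def _round_summary(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in ("mean", "sd", "min", "max", "median"):
        out[col] = out[col].round(2)
    out["selection_frequency"] = out["selection_frequency"].round(2)
    return out


def _seed_int(ss: np.random.SeedSequence) -> str:
    return "/".join(str(k) for k in ss.spawn_key) or "root"


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured pipeline; returns paths of written artifacts."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root_logger = logging.getLogger("cohortlasso")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir, artifacts)
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, artifacts: dict[str, Path]) -> dict[str, Path]:
    root_ss = np.random.SeedSequence(config.seed)
    cohort_ss, impute_ss, analysis_ss = root_ss.spawn(3)

    if config.preset is not None:
        spec = _PRESETS[config.preset](seed=cohort_ss.generate_state(1)[0] % 2**31)
        logger.info(
            "op=generate_cohort preset=%s seed_stream=%s",
            config.preset, _seed_int(cohort_ss),
        )
        table = synthetic.make_cohort(spec)
        cohort_path = outdir / "cohort.csv"
        write_cohort(table, cohort_path)
        artifacts["cohort"] = cohort_path
    else:
        logger.info("op=read_cohort path=%s", config.input)
        table = read_cohort(config.input)

    impute_seed = int(impute_ss.generate_state(1)[0] % 2**31)
    logger.info(
        "op=chained_imputation m=%d iterations=%d seed=%d seed_stream=%s",
        config.m, config.iterations, impute_seed, _seed_int(impute_ss),
    )
    result = chained_imputation(
        table, m=config.m, iterations=config.iterations, seed=impute_seed
    )
    collapsed = result.collapsed
    collapsed_path = outdir / "collapsed.csv"
    write_cohort(collapsed, collapsed_path)
    artifacts["collapsed"] = collapsed_path

    audit = cohen_d_audit(table, collapsed)
    audit_path = outdir / "audit.csv"
    audit.to_csv(audit_path, index=False, float_format="%.10g")
    rounded = audit.copy()
    for col in ("mean1", "sd1", "mean2", "sd2", "pooled_sd", "cohen_d"):
        rounded[col] = rounded[col].round(2)
    rounded.to_csv(outdir / "audit_rounded.csv", index=False)
    logger.info("op=cohen_d_audit biomarkers=%d", len(audit))
    artifacts["audit"] = audit_path

    complete_cols = table.complete_biomarkers()
    logger.info(
        "op=complete_data_arm n_complete=%d of %d",
        len(complete_cols), len(table.biomarker_names),
    )

    for out in config.outcomes:
        name, family = out["name"], out["family"]
        for arm in config.arms:
            arm_ss = analysis_ss.spawn(1)[0]
            arm_seed = int(arm_ss.generate_state(1)[0] % 2**31)
            arm_table = (
                collapsed if arm == "all" else collapsed.select_biomarkers(complete_cols)
            )
            design = standardize(arm_table, name)
            grid = lambda_grid(
                design, family, n_lambda=config.n_lambda, min_ratio=config.min_ratio
            )
            logger.info(
                "op=stability_protocol outcome=%s arm=%s family=%s k=%d "
                "n_screen=%d n_record=%d seed=%d seed_stream=%s",
                name, arm, family, config.k, config.n_screen, config.n_record,
                arm_seed, _seed_int(arm_ss),
            )
            summary = stability_protocol(
                design, grid=grid, family=family, k=config.k,
                n_screen=config.n_screen, n_record=config.n_record,
                seed=arm_seed, tol=config.tol,
            )
            stem = f"{name}_{arm}"
            summary_path = outdir / f"summary_{stem}.csv"
            if not summary.robust:
                logger.warning(
                    "op=robustness_verdict outcome=%s arm=%s robust=false "
                    "failures=%s", name, arm, summary.screen_failures,
                )
                fails = pd.DataFrame(summary.screen_failures)
                with open(summary_path, "w") as fh:
                    fh.write("# not presented: robustness criterion failed\n")
                    fails.to_csv(fh, index=False)
            else:
                logger.info(
                    "op=robustness_verdict outcome=%s arm=%s robust=true", name, arm
                )
                table_out = summary.coef_table.copy()
                extra = [
                    {"term": "optimal_lambda", **summary.lambda_summary,
                     "selection_frequency": np.nan},
                ]
                if summary.auc_summary is not None:
                    extra.append(
                        {"term": "auc", **summary.auc_summary,
                         "selection_frequency": np.nan}
                    )
                full = pd.concat(
                    [table_out, pd.DataFrame(extra)], ignore_index=True
                )
                full.to_csv(
                    outdir / f"summary_{stem}_full.csv", index=False,
                    float_format="%.10g",
                )
                shown = _round_summary(table_out)
                shown_extra = pd.DataFrame(extra)
                for col in ("mean", "sd", "min", "max", "median"):
                    shown_extra.loc[shown_extra.term == "optimal_lambda", col] = (
                        shown_extra.loc[shown_extra.term == "optimal_lambda", col]
                        .astype(float).round(3)
                    )
                    shown_extra.loc[shown_extra.term == "auc", col] = (
                        shown_extra.loc[shown_extra.term == "auc", col]
                        .astype(float).round(2)
                    )
                pd.concat([shown, shown_extra], ignore_index=True).to_csv(
                    summary_path, index=False
                )
                summary.rounds.to_csv(
                    outdir / f"rounds_{stem}.csv", index=False,
                    float_format="%.10g",
                )
                artifacts[f"rounds_{stem}"] = outdir / f"rounds_{stem}.csv"
            artifacts[f"summary_{stem}"] = summary_path
    artifacts["log"] = outdir / "run.log"
    return artifacts
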