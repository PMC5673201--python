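"""Cohort table container and CSV round-trip I/O.

A cohort is a rectangular patient table: one row per patient, biomarker
concentration columns on a log10 pg/mL scale (missing values allowed) and
outcome columns (binary {0,1} or continuous, never missing).

On disk the format is a plain UTF-8 CSV with a ``patient_id`` first column,
biomarker columns prefixed ``bm_``, outcome columns prefixed ``y_`` and an
empty cell denoting a missing biomarker value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIOMARKER_PREFIX = "bm_"
OUTCOME_PREFIX = "y_"


class CohortParseError(ValueError):
    """Raised when a cohort CSV violates the format contract.

    Carries human-readable row/column coordinates of the offending cell.
    """


def _is_binary(values: np.ndarray) -> bool:
    return bool(np.isin(values, (0.0, 1.0)).all())


@dataclass
class CohortTable:
    """Patients x (biomarkers + outcomes) with an explicit missingness mask.

    Parameters
    ----------
    patient_ids:
        Unique patient identifiers, one per row.
    biomarkers:
        Float DataFrame of log10 pg/mL concentrations; ``NaN`` marks a
        missing measurement.
    outcomes:
        Float DataFrame of outcome columns; binary outcomes contain only
        {0, 1}. Outcomes are never missing.
    """

    patient_ids: pd.Index
    biomarkers: pd.DataFrame
    outcomes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.patient_ids = pd.Index(self.patient_ids, name="patient_id")
        self.biomarkers = self.biomarkers.astype(float)
        self.biomarkers.index = self.patient_ids
        if self.outcomes is None or len(self.outcomes.columns) == 0:
            self.outcomes = pd.DataFrame(index=self.patient_ids)
        else:
            self.outcomes = self.outcomes.astype(float)
            self.outcomes.index = self.patient_ids
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def biomarker_names(self) -> list[str]:
        return list(self.biomarkers.columns)

    @property
    def outcome_names(self) -> list[str]:
        return list(self.outcomes.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True exactly where a biomarker value is absent."""
        return self.biomarkers.isna()

    def validate(self) -> None:
        if self.patient_ids.has_duplicates:
            raise ValueError("duplicated patient_id values")
        if self.outcomes.isna().any().any():
            col = self.outcomes.columns[self.outcomes.isna().any()][0]
            raise ValueError(f"missing values in outcome column {col!r}")

    def is_binary_outcome(self, name: str) -> bool:
        return _is_binary(self.outcomes[name].to_numpy())

    def complete_biomarkers(self) -> list[str]:
        """Names of biomarker columns with no missing values."""
        mask = self.missing_mask
        return [c for c in self.biomarkers.columns if not mask[c].any()]

    def select_biomarkers(self, names: list[str]) -> "CohortTable":
        """Restrict to a subset of biomarker columns (rows unchanged)."""
        return CohortTable(
            patient_ids=self.patient_ids.copy(),
            biomarkers=self.biomarkers[list(names)].copy(),
            outcomes=self.outcomes.copy(),
        )

    def copy(self) -> "CohortTable":
        return CohortTable(
            patient_ids=self.patient_ids.copy(),
            biomarkers=self.biomarkers.copy(),
            outcomes=self.outcomes.copy(),
        )


# -- CSV round trip --------------------------------------------------------


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort CSV (``patient_id``, ``bm_*``, ``y_*`` columns).

    Floats are rendered at 10 significant digits; missing biomarker cells
    are written as empty strings.
    """
    df = pd.DataFrame(index=table.patient_ids)
    for col in table.biomarker_names:
        df[BIOMARKER_PREFIX + col] = table.biomarkers[col]
    for col in table.outcome_names:
        df[OUTCOME_PREFIX + col] = table.outcomes[col]
    df.to_csv(path, float_format="%.10g", na_rep="")


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort`.

    Raises
    ------
    CohortParseError
        On duplicated column names, non-numeric biomarker cells or missing
        outcome values, with row/column coordinates in the message.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    seen: set[str] = set()
    for c in cols:
        base = c.split(".")[0] if c.count(".") == 1 and c.split(".")[-1].isdigit() else c
        if base in seen:
            raise CohortParseError(f"duplicated column name {base!r}")
        seen.add(base)
    if cols[0] != "patient_id":
        raise CohortParseError("first column must be 'patient_id'")
    patient_ids = pd.Index(raw["patient_id"], name="patient_id")

    bm = {}
    outs = {}
    for c in cols[1:]:
        series = raw[c].str.strip()
        numeric = pd.to_numeric(series.mask(series == ""), errors="coerce")
        bad = numeric.isna() & (series != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric value {series.iloc[row]!r} in column {c!r}, row {row + 2}"
            )
        if c.startswith(BIOMARKER_PREFIX):
            bm[c[len(BIOMARKER_PREFIX):]] = numeric
        elif c.startswith(OUTCOME_PREFIX):
            if numeric.isna().any():
                row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
                raise CohortParseError(
                    f"missing outcome value in column {c!r}, row {row + 2}"
                )
            outs[c[len(OUTCOME_PREFIX):]] = numeric
        else:
            raise CohortParseError(
                f"column {c!r} has neither '{BIOMARKER_PREFIX}' nor "
                f"'{OUTCOME_PREFIX}' prefix"
            )
    return CohortTable(
        patient_ids=patient_ids,
        biomarkers=pd.DataFrame(bm),
        outcomes=pd.DataFrame(outs),
    )
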