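"""Data model and design arithmetic for multiplex bead-immunoassay plates.

The analysis substrate is a long table with one row per well reading:
a patient sample, a standard-curve well, or a blank, each carrying a median
fluorescence intensity (MFI) and, once a standard curve has been applied,
an optional concentration with a censoring status.  All downstream analyses
work on the log2 scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOG_BASE = 2

#: Canonical column order for plate tables.
COLUMNS = [
    "patient_id",
    "tissue",
    "condition",
    "plate",
    "analyte",
    "well_role",
    "standard_level",
    "fluorescence",
    "concentration",
    "censor_status",
]

WELL_ROLES = {"sample", "standard", "blank"}
CENSOR_STATUSES = {"in_range", "extrapolated", "oor_low", "oor_high", "unset"}


class SchemaError(ValueError):
    """A required column is missing or cannot be resolved."""


class ValidationError(ValueError):
    """Well records violate the data-model invariants."""


class ConfigurationError(ValueError):
    """An impossible plate configuration was requested."""


@dataclass
class PlateDataset:
    """Long-format collection of well records.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per well with the columns in :data:`COLUMNS`.
    log_base : int
        Base of the logarithm used by every transformed analysis (fixed at 2).
    """

    df: pd.DataFrame
    log_base: int = LOG_BASE

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)

    # -- role views ---------------------------------------------------------
    def samples(self) -> pd.DataFrame:
        return self.df[self.df["well_role"] == "sample"]

    def standards(self) -> pd.DataFrame:
        return self.df[self.df["well_role"] == "standard"]

    def blanks(self) -> pd.DataFrame:
        return self.df[self.df["well_role"] == "blank"]

    @property
    def analytes(self) -> list[str]:
        return sorted(self.df["analyte"].unique())

    @property
    def plates(self) -> list[str]:
        return sorted(self.df["plate"].unique())

    def __len__(self) -> int:
        return len(self.df)

    # -- i/o ----------------------------------------------------------------
    def write_csv(self, path) -> None:
        """Write the canonical CSV representation (empty field = missing)."""
        self.df.to_csv(path, index=False)

    def copy(self) -> "PlateDataset":
        return PlateDataset(self.df.copy(), self.log_base)


@dataclass
class DesignSummary:
    """Counts describing the experimental design of the sample wells."""

    cell_counts: pd.Series  # index (analyte, tissue, condition) -> readings
    plate_group_count: int  # distinct nonempty Plate:Condition:Tissue triples
    paired_patient_sets: dict = field(default_factory=dict)


def _validate_frame(df: pd.DataFrame) -> list[str]:
    """Return a list of human-readable validation problems with row numbers."""
    problems = []
    bad_role = df.index[~df["well_role"].isin(WELL_ROLES)]
    if len(bad_role):
        problems.append(f"invalid well_role at rows {list(bad_role[:20])}")
    fl = pd.to_numeric(df["fluorescence"], errors="coerce")
    bad_fl = df.index[fl.isna() | (fl <= 0)]
    if len(bad_fl):
        problems.append(
            f"non-positive or missing fluorescence at rows {list(bad_fl[:20])}"
        )
    is_std = df["well_role"] == "standard"
    lvl = pd.to_numeric(df["standard_level"], errors="coerce")
    bad_lvl = df.index[(is_std & lvl.isna()) | (~is_std & lvl.notna())]
    if len(bad_lvl):
        problems.append(
            "standard_level must be present exactly on standard wells; "
            f"violations at rows {list(bad_lvl[:20])}"
        )
    cs = df["censor_status"].fillna("unset")
    bad_cs = df.index[~cs.isin(CENSOR_STATUSES)]
    if len(bad_cs):
        problems.append(f"invalid censor_status at rows {list(bad_cs[:20])}")
    return problems


def read_plate_table(path, schema: dict | None = None) -> PlateDataset:
    """Read a long-format plate table from delimited text.

    Parameters
    ----------
    path : str or file-like
        CSV file with a header row; missing numerics are empty fields.
    schema : dict, optional
        Map from canonical column names (:data:`COLUMNS`) to the names used
        in the file, for files exported with different headers.

    Raises
    ------
    SchemaError
        If a required column cannot be resolved.
    ValidationError
        If rows violate the well-record invariants (offenders are listed
        with their row numbers).
    """
    raw = pd.read_csv(path, dtype={"patient_id": str})
    schema = schema or {}
    rename = {v: k for k, v in schema.items() if v in raw.columns}
    raw = raw.rename(columns=rename)
    missing = [c for c in ("patient_id", "tissue", "condition", "plate",
                           "analyte", "well_role", "fluorescence")
               if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for opt in ("standard_level", "concentration", "censor_status"):
        if opt not in raw.columns:
            raw[opt] = np.nan
    if raw.empty:
        warnings.warn("plate table contains no data rows", stacklevel=2)
        logger.warning("plate table %s contains no data rows", path)
        empty = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
        empty["fluorescence"] = empty["fluorescence"].astype(float)
        empty["concentration"] = empty["concentration"].astype(float)
        return PlateDataset(empty)

    raw["censor_status"] = raw["censor_status"].fillna("unset")
    for col in ("patient_id", "tissue", "condition", "plate", "analyte"):
        raw[col] = raw[col].fillna("").astype(str)
    problems = _validate_frame(raw)
    if problems:
        raise ValidationError("; ".join(problems))
    raw["fluorescence"] = raw["fluorescence"].astype(float)
    raw["concentration"] = pd.to_numeric(raw["concentration"], errors="coerce")
    raw["standard_level"] = pd.to_numeric(raw["standard_level"], errors="coerce")
    return PlateDataset(raw)


def aggregate_duplicates(ds: PlateDataset) -> PlateDataset:
    """Average duplicate sample wells into one observation per sample x analyte.

    The arithmetic mean of the fluorescence (and, where present, the
    concentration) is taken over wells sharing (patient, tissue, condition,
    plate, analyte).  Standard and blank wells pass through untouched.
    """
    keys = ["patient_id", "tissue", "condition", "plate", "analyte"]
    samples = ds.samples()
    agg = (
        samples.groupby(keys, dropna=False, sort=False, observed=True)
        .agg(
            fluorescence=("fluorescence", "mean"),
            concentration=("concentration", "mean"),
            censor_status=("censor_status", "first"),
        )
        .reset_index()
    )
    agg["well_role"] = "sample"
    agg["standard_level"] = np.nan
    rest = ds.df[ds.df["well_role"] != "sample"]
    out = pd.concat([agg[COLUMNS], rest], ignore_index=True)
    return PlateDataset(out, ds.log_base)


def design_summary(ds: PlateDataset) -> DesignSummary:
    """Summarise the sample-well design (standards and blanks excluded)."""
    samples = ds.samples()
    if samples.empty:
        raise ValidationError("dataset has no sample wells")
    cell_counts = samples.groupby(
        ["analyte", "tissue", "condition"], observed=True
    ).size()
    plate_groups = samples[["plate", "condition", "tissue"]].drop_duplicates()
    tissues_per_patient = samples.groupby("patient_id", observed=True)["tissue"].nunique()
    paired = {}
    multi = tissues_per_patient[tissues_per_patient > 1].index
    if len(multi):
        sub = samples[samples["patient_id"].isin(multi)]
        for cond, grp in sub.groupby("condition", observed=True):
            paired[cond] = sorted(grp["patient_id"].unique())
    return DesignSummary(
        cell_counts=cell_counts,
        plate_group_count=len(plate_groups),
        paired_patient_sets=paired,
    )


def filter_estimable_analytes(
    ds: PlateDataset,
    response: str = "fluorescence",
    min_per_cell: int = 1,
) -> tuple[list[str], dict[str, list[tuple]]]:
    """Drop analytes whose design cells are too sparse for a full-rank fit.

    A cell is an (analyte, tissue, condition) triple restricted to the
    tissue x condition combinations present in the sample design.  An analyte
    is dropped iff any of its cells holds fewer than ``min_per_cell``
    non-missing values of ``response``.

    Returns
    -------
    kept, dropped : list, dict
        Retained analyte labels, and a map from dropped analyte to its
        offending (tissue, condition) cells.
    """
    if response not in ("fluorescence", "concentration"):
        raise ValueError(f"unknown response {response!r}")
    samples = ds.samples()
    design_cells = samples[["tissue", "condition"]].drop_duplicates()
    counts = (
        samples.dropna(subset=[response])
        .groupby(["analyte", "tissue", "condition"], observed=True)
        .size()
    )
    kept, dropped = [], {}
    for analyte in sorted(samples["analyte"].unique()):
        offending = []
        for _, (tissue, condition) in design_cells.iterrows():
            n = counts.get((analyte, tissue, condition), 0)
            if n < min_per_cell:
                offending.append((tissue, condition))
        if offending:
            dropped[analyte] = offending
            logger.info("analyte %s dropped: empty cells %s", analyte, offending)
        else:
            kept.append(analyte)
    return kept, dropped


def plate_capacity(
    wells: int = 96,
    replicates: int = 2,
    include_standard_curve: bool = True,
    n_standards: int = 8,
    n_blanks: int = 1,
) -> int:
    """Number of samples that fit on a plate.

    With duplicate wells a 96-well plate holds 39 samples when a standard
    curve (8 standards + 1 blank) is run, and 47 when fluorescence-only
    analysis makes the curve unnecessary.
    """
    if wells % replicates:
        raise ConfigurationError(
            f"{wells} wells not divisible by {replicates} replicates"
        )
    capacity = wells // replicates - n_blanks
    if include_standard_curve:
        capacity -= n_standards
    if capacity < 0:
        raise ConfigurationError("plate overhead exceeds well count")
    return capacity
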