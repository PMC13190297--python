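"""In-memory containers for cohort and proteomic data.

The cohort table is a plain :class:`pandas.DataFrame` indexed by subject id
with the columns documented in :func:`validate_cohort`.  Protein abundances
travel in a lightweight :class:`ProteinMatrix` that bundles the subjects ×
analytes value matrix with per-analyte metadata (gene symbol, platform,
limit of detection) and an optional below-LOD flag matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4")
PLATFORMS = ("aptamer", "pea", "ms")

__all__ = ["GENOTYPES", "PLATFORMS", "ProteinMatrix", "validate_cohort",
           "read_cohort", "write_cohort"]


@dataclass
class ProteinMatrix:
    """Subjects × analytes log2-abundance matrix with analyte metadata.

    Parameters
    ----------
    values : DataFrame
        Numeric matrix, rows indexed by subject id, columns by analyte id.
        Missing measurements are NaN; infinite values are rejected.
    analytes : DataFrame
        One row per analyte (index = analyte id).  Recognised columns:
        ``gene`` (gene symbol), ``platform`` (one of {aptamer, pea, ms}),
        ``lod`` (limit of detection on the log2 scale, optional).
    below_lod : DataFrame, optional
        Boolean matrix aligned with ``values``; True marks a measurement
        below the analyte's limit of detection.  Values are retained, the
        flag only records censoring.
    """

    values: pd.DataFrame
    analytes: pd.DataFrame = field(default=None)
    below_lod: pd.DataFrame | None = None

    def __post_init__(self):
        if self.analytes is None:
            self.analytes = pd.DataFrame(index=self.values.columns)
            self.analytes.index.name = "analyte_id"
        if not self.values.columns.equals(self.analytes.index):
            self.analytes = self.analytes.reindex(self.values.columns)
        if np.isinf(self.values.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValueError("protein matrix contains infinite values")
        if self.below_lod is not None:
            if (not self.below_lod.index.equals(self.values.index)
                    or not self.below_lod.columns.equals(self.values.columns)):
                raise ValueError("below_lod flags not aligned with values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            self.values.copy(),
            self.analytes.copy(),
            None if self.below_lod is None else self.below_lod.copy(),
        )

    def select_analytes(self, keep) -> "ProteinMatrix":
        keep = list(keep)
        return ProteinMatrix(
            self.values[keep],
            self.analytes.loc[keep],
            None if self.below_lod is None else self.below_lod[keep],
        )

    def select_subjects(self, keep) -> "ProteinMatrix":
        keep = list(keep)
        return ProteinMatrix(
            self.values.loc[keep],
            self.analytes,
            None if self.below_lod is None else self.below_lod.loc[keep],
        )

    # ------------------------------------------------------------------ io
    def write(self, directory: str | Path, prefix: str = "") -> None:
        """Write ``{prefix}proteins.tsv`` / ``{prefix}analytes.tsv`` (and
        below-LOD flags if present) as tab-separated text."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(directory / f"{prefix}proteins.tsv", sep="\t",
                           float_format="%.10g")
        self.analytes.to_csv(directory / f"{prefix}analytes.tsv", sep="\t",
                             float_format="%.10g")
        if self.below_lod is not None:
            self.below_lod.astype(int).to_csv(
                directory / f"{prefix}below_lod.tsv", sep="\t")

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "") -> "ProteinMatrix":
        directory = Path(directory)
        values = pd.read_csv(directory / f"{prefix}proteins.tsv", sep="\t",
                             index_col=0)
        analytes = pd.read_csv(directory / f"{prefix}analytes.tsv", sep="\t",
                               index_col=0)
        lod_path = directory / f"{prefix}below_lod.tsv"
        below = None
        if lod_path.exists():
            below = pd.read_csv(lod_path, sep="\t", index_col=0).astype(bool)
        return cls(values, analytes, below)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table and return it unchanged.

    Required: unique subject-id index, ``genotype`` in the six-level APOE
    set, positive ``age``, ``sex`` in {male, female}.  Optional columns
    (``cohort``, ``diagnosis``, ``abeta_status``, ``abeta_ratio``, extra
    numeric covariates) are passed through.
    """
    if not cohort.index.is_unique:
        raise ValueError("subject ids are not unique")
    bad = set(cohort["genotype"].dropna()) - set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotypes: {sorted(bad)}")
    if (cohort["age"] <= 0).any():
        raise ValueError("age must be positive")
    bad_sex = set(cohort["sex"].dropna()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
    if "diagnosis" in cohort:
        bad_dx = set(cohort["diagnosis"].dropna()) - {"CU", "MCI", "AD"}
        if bad_dx:
            raise ValueError(f"unknown diagnoses: {sorted(bad_dx)}")
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", float_format="%.10g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", index_col=0)
    return validate_cohort(cohort)
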