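"""Harmonized proteomic quality control and assay classification rules.

Implements the QC chain used throughout the analysis: analyte missingness
filtering (strictly >15% missing removed), LOD-based retention (kept when
above the limit of detection in at least 70% of subjects), subject
missingness filtering, the per-subject mean-abundance covariate (restricted
to analytes above LOD in >90% of subjects on the PEA platform), the
analysis-local >5 SD outlier rule, assay-specific amyloid-status cutoffs,
and the bulk RNA-seq FPKM → TPM → log2 → z-score normalization chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ProteinMatrix

__all__ = [
    "QCReport", "ProteinQC", "filter_analytes", "compute_mean_abundance",
    "exclude_outlier_values", "classify_amyloid", "AMYLOID_CUTOFFS",
    "RNASeqNormalizer", "rnaseq_normalize",
]


@dataclass
class QCReport:
    """Record of what the QC filter removed and why."""

    analytes_removed_missing: dict[str, float] = field(default_factory=dict)
    analytes_removed_lod: dict[str, float] = field(default_factory=dict)
    subjects_removed_missing: dict[str, float] = field(default_factory=dict)
    missing_threshold: float = 0.15
    lod_min_above: float = 0.70

    def to_dict(self) -> dict:
        return {
            "missing_threshold": self.missing_threshold,
            "lod_min_above": self.lod_min_above,
            "analytes_removed_missing": self.analytes_removed_missing,
            "analytes_removed_lod": self.analytes_removed_lod,
            "subjects_removed_missing": self.subjects_removed_missing,
        }


class ProteinQC(BaseEstimator):
    """Analyte/subject retention filter for a protein matrix.

    Order of operations: (1) drop analytes with strictly more than
    ``missing_threshold`` missing values; (2) when below-LOD flags are
    present, drop analytes above the LOD in fewer than ``lod_min_above`` of
    subjects; (3) drop subjects with strictly more than
    ``missing_threshold`` missing values over the retained analytes.  The
    subject filter runs last so the final analyte set determines it, and
    the mean-abundance covariate downstream reflects the filtered set.

    Fitted attributes: ``analytes_removed_missing_``,
    ``analytes_removed_lod_``, ``subjects_removed_missing_`` (mapping id →
    triggering fraction), ``report_``.
    """

    def __init__(self, missing_threshold: float = 0.15,
                 lod_min_above: float = 0.70):
        self.missing_threshold = missing_threshold
        self.lod_min_above = lod_min_above

    def fit(self, matrix: ProteinMatrix, y=None):
        if not 0 <= self.missing_threshold <= 1:
            raise ValueError("missing_threshold must lie in [0, 1]")
        if not 0 <= self.lod_min_above <= 1:
            raise ValueError("lod_min_above must lie in [0, 1]")
        vals = matrix.values
        n_subj = len(vals)

        miss_frac = vals.isna().mean(axis=0)
        drop_missing = miss_frac[miss_frac > self.missing_threshold]

        drop_lod = pd.Series(dtype=float)
        if matrix.below_lod is not None:
            above = (vals.notna() & ~matrix.below_lod).sum(axis=0) / n_subj
            keep_candidates = above.drop(index=drop_missing.index)
            drop_lod = keep_candidates[keep_candidates < self.lod_min_above]

        kept_analytes = vals.columns.difference(
            drop_missing.index.union(drop_lod.index), sort=False)
        subj_miss = vals[kept_analytes].isna().mean(axis=1)
        drop_subj = subj_miss[subj_miss > self.missing_threshold]

        if len(kept_analytes) == 0 or len(drop_subj) == n_subj:
            raise ValueError(
                f"QC removed everything: {len(drop_missing)} analytes by "
                f"missingness, {len(drop_lod)} by LOD, "
                f"{len(drop_subj)}/{n_subj} subjects")

        self.analytes_removed_missing_ = drop_missing.to_dict()
        self.analytes_removed_lod_ = drop_lod.to_dict()
        self.subjects_removed_missing_ = drop_subj.to_dict()
        self.kept_analytes_ = list(kept_analytes)
        self.kept_subjects_ = list(vals.index.difference(drop_subj.index,
                                                         sort=False))
        self.report_ = QCReport(
            self.analytes_removed_missing_, self.analytes_removed_lod_,
            self.subjects_removed_missing_, self.missing_threshold,
            self.lod_min_above)
        return self

    def transform(self, matrix: ProteinMatrix) -> ProteinMatrix:
        return (matrix.select_analytes(self.kept_analytes_)
                .select_subjects(self.kept_subjects_))

    def fit_transform(self, matrix: ProteinMatrix, y=None) -> ProteinMatrix:
        return self.fit(matrix).transform(matrix)


def filter_analytes(matrix: ProteinMatrix, missing_threshold: float = 0.15,
                    lod_min_above: float = 0.70):
    """Functional wrapper over :class:`ProteinQC`; returns
    ``(filtered_matrix, QCReport)``."""
    qc = ProteinQC(missing_threshold, lod_min_above)
    out = qc.fit_transform(matrix)
    return out, qc.report_


def compute_mean_abundance(matrix: ProteinMatrix,
                           lod_frac_for_mean: float = 0.90) -> pd.Series:
    """Per-subject mean protein abundance, used as a model covariate.

    On the PEA platform the mean is computed over analytes above the LOD in
    strictly more than ``lod_frac_for_mean`` of subjects; if no analyte
    qualifies the mean falls back to all retained analytes (with a
    warning).  Other platforms, or matrices without LOD flags, average all
    retained analytes.  Missing entries are ignored per subject.
    """
    vals = matrix.values
    cols = vals.columns
    platforms = matrix.analytes.get("platform")
    is_pea = platforms is not None and (platforms == "pea").any()
    if is_pea and matrix.below_lod is not None:
        above = (vals.notna() & ~matrix.below_lod).sum(axis=0) / len(vals)
        eligible = above[above > lod_frac_for_mean].index
        if len(eligible) == 0:
            warnings.warn(
                "no analyte above the LOD in >{:.0%} of subjects; mean "
                "abundance computed over all retained analytes".format(
                    lod_frac_for_mean))
        else:
            cols = eligible
    mean = vals[cols].mean(axis=1, skipna=True)
    mean.name = "mean_abundance"
    return mean


def exclude_outlier_values(values, k: float = 5.0):
    """Single-pass >k SD outlier rule applied immediately before a fit.

    z-scores come from the mean and SD of the full non-missing vector (no
    re-iteration after exclusion); entries with \\|z\\| strictly greater
    than ``k`` are excluded.  Returns ``(retained, excluded_index)`` as a
    pandas Series / Index.  A zero-variance vector excludes nothing.
    """
    s = pd.Series(values).astype(float)
    obs = s.dropna()
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return s, s.index[:0]
    z = (s - obs.mean()) / sd
    excluded = s.index[z.abs() > k]
    return s.drop(index=excluded), excluded


#: Assay-specific amyloid-positivity cutoffs.  Ratio assays (CSF Aβ42/40):
#: positive when the ratio is strictly below the cutoff.  The Aβ42
#: concentration assay: positive strictly below 880 pg/ml.
AMYLOID_CUTOFFS = {
    "roche_ratio": 0.080,
    "lumipulse_ratio": 0.072,
    "msd_ratio": 0.077,
    "adni_ab42": 880.0,
}


def classify_amyloid(measurement: float, assay: str) -> str:
    """Classify amyloid status from a CSF measurement.

    All comparisons are strict ``<``: a ratio (or Aβ42 level) below the
    assay's cutoff is ``"positive"``, otherwise ``"negative"``.
    """
    if assay not in AMYLOID_CUTOFFS:
        raise ValueError(f"unknown assay {assay!r}; "
                         f"expected one of {sorted(AMYLOID_CUTOFFS)}")
    if not np.isfinite(measurement) or measurement <= 0:
        raise ValueError("measurement must be positive and finite")
    return "positive" if measurement < AMYLOID_CUTOFFS[assay] else "negative"


class RNASeqNormalizer(BaseEstimator):
    """FPKM → TPM → log2(x+1) → per-gene z-score chain for bulk RNA-seq.

    Genes with FPKM strictly above ``min_fpkm`` in at least ``min_fraction``
    of samples are retained; per-sample TPM renormalizes over the retained
    genes; the z-score (ddof=1, matching R ``scale``) uses gene statistics
    learned at fit time.

    Input orientation is genes × samples.
    """

    def __init__(self, min_fpkm: float = 0.1, min_fraction: float = 0.85):
        self.min_fpkm = min_fpkm
        self.min_fraction = min_fraction

    def fit(self, fpkm: pd.DataFrame, y=None):
        if (fpkm < 0).any().any():
            raise ValueError("FPKM values must be non-negative")
        frac = (fpkm > self.min_fpkm).mean(axis=1)
        self.retained_genes_ = list(fpkm.index[frac >= self.min_fraction])
        if not self.retained_genes_:
            raise ValueError("no gene passes the retention rule")
        logtpm = self._log_tpm(fpkm)
        self.gene_mean_ = logtpm.mean(axis=1)
        self.gene_sd_ = logtpm.std(axis=1, ddof=1)
        return self

    def _log_tpm(self, fpkm: pd.DataFrame) -> pd.DataFrame:
        sub = fpkm.loc[self.retained_genes_]
        colsum = sub.sum(axis=0)
        if (colsum == 0).any():
            bad = list(colsum.index[colsum == 0])
            raise ValueError(f"all-zero sample(s) after retention: {bad}")
        tpm = sub.div(colsum, axis=1) * 1e6
        return np.log2(tpm + 1.0)

    def transform(self, fpkm: pd.DataFrame) -> pd.DataFrame:
        logtpm = self._log_tpm(fpkm)
        sd = self.gene_sd_.replace(0.0, np.nan)
        return logtpm.sub(self.gene_mean_, axis=0).div(sd, axis=0)

    def fit_transform(self, fpkm: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(fpkm).transform(fpkm)


def rnaseq_normalize(fpkm: pd.DataFrame, min_fpkm: float = 0.1,
                     min_fraction: float = 0.85) -> pd.DataFrame:
    """Functional wrapper over :class:`RNASeqNormalizer`."""
    return RNASeqNormalizer(min_fpkm, min_fraction).fit_transform(fpkm)
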