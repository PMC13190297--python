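"""QC rules: boundary conventions on missingness, LOD retention, the
mean-abundance covariate, outlier exclusion, amyloid cutoffs, and the
RNA-seq normalization chain."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from apoeprot import (ProteinQC, RNASeqNormalizer, classify_amyloid,
                      compute_mean_abundance, exclude_outlier_values,
                      filter_analytes, rnaseq_normalize)
from apoeprot.containers import ProteinMatrix


def _matrix(values: pd.DataFrame, below_lod=None, platform="pea"):
    analytes = pd.DataFrame({"gene": values.columns, "platform": platform},
                            index=values.columns)
    return ProteinMatrix(values, analytes, below_lod)


def _with_missing(n_subjects, missing_per_analyte: dict):
    rng = np.random.default_rng(0)
    cols = {}
    for name, n_miss in missing_per_analyte.items():
        v = rng.normal(0, 1, n_subjects)
        v[:n_miss] = np.nan
        rng.shuffle(v)
        cols[name] = v
    return _matrix(pd.DataFrame(
        cols, index=[f"S{i}" for i in range(n_subjects)]))


class TestAnalyteFilter:
    def test_missingness_boundary_16_removed_15_retained(self):
        pm = _with_missing(100, {"A16": 16, "A15": 15, "A0": 0})
        out, report = filter_analytes(pm)
        assert "A16" not in out.values.columns
        assert "A15" in out.values.columns
        assert report.analytes_removed_missing == {"A16": 0.16}

    def test_lod_boundary_70_retained_69_removed(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(0, 1, (100, 2)),
                              columns=["A70", "A69"])
        below = pd.DataFrame(False, index=values.index,
                             columns=values.columns)
        below.iloc[:30, 0] = True      # above LOD in exactly 70
        below.iloc[:31, 1] = True      # above LOD in 69
        out, report = filter_analytes(_matrix(values, below))
        assert "A70" in out.values.columns
        assert "A69" not in out.values.columns
        assert report.analytes_removed_lod == {"A69": 0.69}

    def test_subject_filter_applied_after_analyte_filter(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(0, 1, (10, 10)),
                              index=[f"S{i}" for i in range(10)])
        values.columns = [f"A{i}" for i in range(10)]
        # S0 misses 2/10 analytes (20% > 15%) -> removed
        values.iloc[0, :2] = np.nan
        out, report = filter_analytes(_matrix(values))
        assert "S0" not in out.values.index
        assert report.subjects_removed_missing == {"S0": 0.2}

    def test_idempotent(self):
        pm = _with_missing(60, {"A": 12, "B": 5, "C": 0})
        once, _ = filter_analytes(pm)
        twice, _ = filter_analytes(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_everything_removed_is_an_error(self):
        pm = _with_missing(10, {"A": 10})
        with pytest.raises(ValueError, match="QC removed everything"):
            filter_analytes(pm)


class TestMeanAbundance:
    def test_pea_above_lod_90pct_rule(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(5, 1, (100, 3)),
                              columns=["A91", "A90", "A89"])
        below = pd.DataFrame(False, index=values.index,
                             columns=values.columns)
        below.iloc[:9, 0] = True    # above LOD in 91% -> included
        below.iloc[:10, 1] = True   # exactly 90% -> excluded (strict >)
        below.iloc[:11, 2] = True   # 89% -> excluded
        mean = compute_mean_abundance(_matrix(values, below))
        pd.testing.assert_series_equal(
            mean, values["A91"].rename("mean_abundance"))

    def test_fallback_to_all_when_none_eligible(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(5, 1, (20, 2)), columns=["A", "B"])
        below = pd.DataFrame(True, index=values.index, columns=values.columns)
        with pytest.warns(UserWarning, match="all retained analytes"):
            mean = compute_mean_abundance(_matrix(values, below))
        pd.testing.assert_series_equal(
            mean, values.mean(axis=1).rename("mean_abundance"))

    def test_single_analyte_equals_itself(self):
        values = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        mean = compute_mean_abundance(_matrix(values))
        np.testing.assert_allclose(mean, [1.0, 2.0, 3.0])

    def test_three_by_three_hand_computed_and_order_invariant(self):
        values = pd.DataFrame({"A": [1.0, np.nan, 3.0],
                               "B": [2.0, 4.0, 6.0],
                               "C": [3.0, 5.0, np.nan]})
        mean = compute_mean_abundance(_matrix(values))
        np.testing.assert_allclose(mean, [2.0, 4.5, 4.5])
        mean_perm = compute_mean_abundance(_matrix(values[["C", "A", "B"]]))
        np.testing.assert_allclose(mean_perm, mean)


class TestOutlierExclusion:
    def _vector_with_z(self, z_target):
        """Append a point whose single-pass z-score equals z_target."""
        base = np.concatenate([np.linspace(-1, 1, 40)] * 2)

        def z_of(t):
            v = np.append(base, t)
            return (t - v.mean()) / v.std(ddof=1)

        t = brentq(lambda t: z_of(t) - z_target, 0.1, 100.0)
        return np.append(base, t), len(base)

    def test_above_five_sd_excluded(self):
        v, idx = self._vector_with_z(5.2)
        retained, excluded = exclude_outlier_values(v)
        assert list(excluded) == [idx]

    def test_exactly_k_sd_retained(self):
        # strict >: a point sitting exactly at the threshold stays in
        v, idx = self._vector_with_z(5.0)
        s = pd.Series(v)
        z_exact = (s[idx] - s.mean()) / s.std(ddof=1)
        retained, excluded = exclude_outlier_values(v, k=z_exact)
        assert len(excluded) == 0
        _, excluded = exclude_outlier_values(v, k=np.nextafter(z_exact, 0))
        assert list(excluded) == [idx]

    def test_zero_variance_excludes_nothing(self):
        retained, excluded = exclude_outlier_values([2.0] * 10)
        assert len(excluded) == 0 and len(retained) == 10

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            exclude_outlier_values([1.0, 2.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_zscore_scan(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_t(df=2, size=200)       # heavy tails
        retained, excluded = exclude_outlier_values(v, k=3)
        z = (v - v.mean()) / np.std(v, ddof=1)
        np.testing.assert_array_equal(np.sort(excluded),
                                      np.flatnonzero(np.abs(z) > 3))


class TestAmyloidClassification:
    @pytest.mark.parametrize("value,assay,expected", [
        (0.079, "roche_ratio", "positive"),
        (0.080, "roche_ratio", "negative"),     # strict <
        (0.073, "lumipulse_ratio", "negative"),
        (0.071, "lumipulse_ratio", "positive"),
        (0.076, "msd_ratio", "positive"),
        (900.0, "adni_ab42", "negative"),
        (879.0, "adni_ab42", "positive"),
    ])
    def test_cutoffs(self, value, assay, expected):
        assert classify_amyloid(value, assay) == expected

    def test_unknown_assay_rejected(self):
        with pytest.raises(ValueError, match="unknown assay"):
            classify_amyloid(0.08, "elisa")

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError):
            classify_amyloid(-1.0, "roche_ratio")


class TestRNASeqNormalize:
    def test_retention_boundary(self):
        rng = np.random.default_rng(5)
        fpkm = pd.DataFrame(rng.uniform(1, 5, (2, 100)),
                            index=["keep85", "drop84"])
        fpkm.iloc[0, :15] = 0.05    # >0.1 in 85% of samples -> retained
        fpkm.iloc[1, :16] = 0.05    # 84% -> removed
        norm = RNASeqNormalizer()
        norm.fit(fpkm)
        assert norm.retained_genes_ == ["keep85"]

    def test_two_gene_arithmetic(self):
        fpkm = pd.DataFrame({"s1": [3.0, 1.0]}, index=["g1", "g2"])
        norm = RNASeqNormalizer(min_fraction=0.0)
        norm.retained_genes_ = ["g1", "g2"]
        logtpm = norm._log_tpm(fpkm)
        np.testing.assert_allclose(logtpm["s1"],
                                   [np.log2(750_001), np.log2(250_001)])

    def test_single_gene_tpm_is_one_million(self):
        fpkm = pd.DataFrame({"s1": [4.2], "s2": [0.7]}, index=["g"])
        norm = RNASeqNormalizer(min_fpkm=0.0, min_fraction=0.0)
        norm.retained_genes_ = ["g"]
        logtpm = norm._log_tpm(fpkm)
        np.testing.assert_allclose(logtpm.loc["g"], np.log2(1e6 + 1))

    def test_tpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(6)
        fpkm = pd.DataFrame(rng.uniform(0.2, 10, (30, 8)))
        norm = RNASeqNormalizer().fit(fpkm)
        tpm = 2 ** norm._log_tpm(fpkm) - 1.0
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, atol=1e-6)

    def test_full_chain_zscores_rows(self):
        rng = np.random.default_rng(7)
        fpkm = pd.DataFrame(rng.uniform(0.2, 10, (10, 20)))
        z = rnaseq_normalize(fpkm)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_all_zero_sample_is_an_error(self):
        fpkm = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]})
        with pytest.raises(ValueError, match="all-zero sample"):
            rnaseq_normalize(fpkm, min_fpkm=0.0, min_fraction=0.0)

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            rnaseq_normalize(pd.DataFrame({"s": [-1.0]}))
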