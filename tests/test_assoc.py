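"""Association module: contrast coding, OLS against a normal-equations
oracle, BH against a brute-force step-up, Welch/Holm comparisons, and
effect-size concordance."""

import numpy as np
import pandas as pd
import pytest

from apoeprot import (E2_CONTRAST, E4_CONTRAST, ProteinAssociation, bh_fdr,
                      effect_concordance, make_contrast_groups,
                      residualize_and_compare, run_assoc)
from apoeprot.assoc import fit_protein_model
from apoeprot.containers import ProteinMatrix
from apoeprot.simulate import AnalyteSpec, SimConfig, simulate_cohort


def _toy_cohort(genotypes, ages=None, sexes=None):
    n = len(genotypes)
    return pd.DataFrame({
        "genotype": genotypes,
        "age": ages if ages is not None else np.linspace(60, 80, n),
        "sex": sexes if sexes is not None else ["male", "female"] * (n // 2)
        + ["male"] * (n % 2),
        "diagnosis": ["CU", "AD"] * (n // 2) + ["CU"] * (n % 2),
    }, index=[f"S{i}" for i in range(n)])


class TestContrastGroups:
    @pytest.mark.parametrize("genotype,expected", [
        ("e4e4", 1.0), ("e3e4", 1.0), ("e3e3", 0.0),
        ("e2e4", np.nan), ("e2e2", np.nan), ("e2e3", np.nan),
    ])
    def test_e4_coding(self, genotype, expected):
        cohort = _toy_cohort([genotype, "e3e3", "e3e3"])
        coded = make_contrast_groups(cohort, E4_CONTRAST)
        if np.isnan(expected):
            assert np.isnan(coded.iloc[0])
        else:
            assert coded.iloc[0] == expected

    @pytest.mark.parametrize("genotype,expected", [
        ("e2e2", 1.0), ("e2e3", 1.0), ("e3e3", 0.0),
        ("e3e4", np.nan), ("e4e4", np.nan), ("e2e4", np.nan),
    ])
    def test_e2_coding(self, genotype, expected):
        cohort = _toy_cohort([genotype, "e3e3", "e3e3"])
        coded = make_contrast_groups(cohort, E2_CONTRAST)
        if np.isnan(expected):
            assert np.isnan(coded.iloc[0])
        else:
            assert coded.iloc[0] == expected

    def test_descriptive_mode_merges_e2_groups(self):
        cohort = _toy_cohort(["e2e2", "e2e3", "e3e3", "e4e4"])
        groups = make_contrast_groups(cohort, E4_CONTRAST,
                                      descriptive_six_group=True)
        assert groups.iloc[0] == groups.iloc[1] == "22/23"
        assert set(groups) == {"22/23", "e3e3", "e4e4"}

    def test_empty_reference_raises(self):
        cohort = _toy_cohort(["e3e4", "e4e4"])
        with pytest.raises(ValueError, match="empty reference"):
            make_contrast_groups(cohort, E4_CONTRAST)


class TestProteinModel:
    def _toy_data(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        cohort = _toy_cohort(["e3e4", "e3e3"] * (n // 2),
                             ages=rng.uniform(55, 85, n),
                             sexes=list(rng.choice(["male", "female"], n)))
        values = pd.DataFrame({"P1": rng.normal(0, 1, n)},
                              index=cohort.index)
        return ProteinMatrix(values), cohort

    def test_coefficients_match_normal_equations(self):
        matrix, cohort = self._toy_data()
        res = fit_protein_model(matrix, cohort, model_type=1,
                                covariates=["age", "sex"], zscore=False,
                                min_n=2)
        # independent oracle: solve the normal equations directly
        x = (cohort["genotype"] == "e3e4").astype(float)
        sex = cohort["sex"].map({"female": 0.0, "male": 1.0})
        X = np.column_stack([np.ones(8), x, cohort["age"], sex])
        y = matrix.values["P1"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.loc[res.term == "apoe", "beta"].iloc[0] == \
            pytest.approx(beta[1], abs=1e-10)

    def test_constant_outcome_degenerate_record(self):
        matrix, cohort = self._toy_data()
        matrix.values["P1"] = 3.14
        res = fit_protein_model(matrix, cohort, model_type=1,
                                covariates=["age"], min_n=2)
        row = res.iloc[0]
        assert row["beta"] == 0.0 and np.isnan(row["p"])
        assert row["note"] == "constant_outcome"

    def test_model3_contains_both_terms(self):
        matrix, cohort = self._toy_data(n=40)
        res = fit_protein_model(matrix, cohort, model_type=3,
                                covariates=["age"], min_n=5)
        assert set(res["term"]) == {"apoe", "disease"}

    def test_interaction_term_reported(self):
        matrix, cohort = self._toy_data(n=60)
        res = fit_protein_model(matrix, cohort, model_type=1,
                                interaction="age", covariates=["sex"],
                                min_n=5)
        assert "apoe:age" in set(res["term"])

    def test_single_sex_stratum_drops_covariate_with_warning(self):
        matrix, cohort = self._toy_data(n=40)
        cohort["sex"] = "female"
        with pytest.warns(UserWarning, match="dropped constant"):
            res = fit_protein_model(matrix, cohort, model_type=1,
                                    covariates=["age", "sex"], min_n=5)
        assert "dropped_constant:sex" in res.iloc[0]["note"]

    def test_model1_equals_model3_when_disease_independent(self):
        # with no genotype->disease path the disease adjustment cannot
        # move the genotype coefficient (checked at large n)
        cfg = SimConfig(
            n_subjects=50_000, master_seed=4, direct_e4=0.0, direct_e2=0.0,
            age_disease_logodds=0.0,
            analyte_plan=[AnalyteSpec("X", "nonspecific", a_e4=0.3, d=0.5)])
        sim = simulate_cohort(cfg)
        b1 = run_assoc(sim.matrix, sim.cohort, model_type=1,
                       covariates=["age", "sex"])
        b3 = run_assoc(sim.matrix, sim.cohort, model_type=3,
                       covariates=["age", "sex"])
        beta1 = b1.loc[b1.term == "apoe", "beta"].iloc[0]
        beta3 = b3.loc[b3.term == "apoe", "beta"].iloc[0]
        assert beta1 == pytest.approx(beta3, abs=0.02)

    def test_small_stratum_skipped_with_warning(self, small_sim):
        with pytest.warns(UserWarning, match="skipped"):
            res = run_assoc(sim_matrix := small_sim.matrix, small_sim.cohort,
                            strata=("all",), min_n=10**6)
        assert res.empty

    def test_empty_matrix_gives_empty_table(self):
        _, cohort = self._toy_data(n=40)
        empty = ProteinMatrix(pd.DataFrame(index=cohort.index))
        res = run_assoc(empty, cohort, covariates=["age"], min_n=5)
        assert res.empty


def _bh_bruteforce(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBHFDR:
    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.05]), [0.05])

    def test_hand_worked_examples(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr([1.0, 0.5]), [1.0, 1.0])

    def test_nan_propagates(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], _bh_bruteforce([0.01, 0.5]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_stepup_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 50))
        q = bh_fdr(p)
        np.testing.assert_allclose(q, _bh_bruteforce(p), atol=1e-12)
        perm = rng.permutation(len(p))
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestResidualizedComparison:
    def _groups_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        genotypes = ["e3e3"] * 5 + ["e4e4"] * 5
        cohort = _toy_cohort(genotypes)
        values = pd.DataFrame({"P1": rng.normal(0, 1, 10)},
                              index=cohort.index)
        values.iloc[5:, 0] = rng.normal(2, 3, 5)     # unequal variance
        return ProteinMatrix(values), cohort

    def test_no_covariates_residuals_are_centered(self):
        matrix, cohort = self._groups_matrix()
        res = residualize_and_compare(matrix, cohort, covariates=[])
        # Welch t on centered values equals Welch t on raw values
        from scipy import stats
        a = matrix.values.iloc[:5, 0]
        b = matrix.values.iloc[5:, 0]
        t_raw, _ = stats.ttest_ind(a - matrix.values["P1"].mean(),
                                   b - matrix.values["P1"].mean(),
                                   equal_var=False)
        assert res.iloc[0]["t"] == pytest.approx(t_raw, abs=1e-12)

    def test_welch_statistic_matches_textbook_formula(self):
        matrix, cohort = self._groups_matrix()
        res = residualize_and_compare(matrix, cohort, covariates=[])
        a = matrix.values.iloc[:5, 0] - matrix.values["P1"].mean()
        b = matrix.values.iloc[5:, 0] - matrix.values["P1"].mean()
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_formula = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_formula = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        row = res.iloc[0]
        assert abs(row["t"]) == pytest.approx(abs(t_formula), abs=1e-10)
        assert row["df"] == pytest.approx(df_formula, abs=1e-10)

    def test_identical_groups_t_zero_p_one(self):
        cohort = _toy_cohort(["e3e3"] * 4 + ["e4e4"] * 4)
        v = [1.0, 2.0, 3.0, 4.0] * 2
        matrix = ProteinMatrix(pd.DataFrame({"P1": v}, index=cohort.index))
        res = residualize_and_compare(matrix, cohort, covariates=[])
        assert res.iloc[0]["t"] == pytest.approx(0.0, abs=1e-12)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_residuals_orthogonal_to_covariates(self, small_sim):
        import statsmodels.api as sm
        cohort = small_sim.cohort
        y = small_sim.matrix.values.iloc[:, 0]
        X = sm.add_constant(pd.DataFrame({
            "age": cohort["age"],
            "sex": cohort["sex"].map({"female": 0.0, "male": 1.0})}))
        resid = y - sm.OLS(y, X).fit().fittedvalues
        for col in ("age", "sex"):
            scaled = (X[col] - X[col].mean()) / X[col].std()
            assert abs(resid @ scaled) / len(resid) < 1e-8

    def test_holm_adjustment_across_pairs(self):
        from statsmodels.stats.multitest import multipletests
        cohort = _toy_cohort(["e3e3"] * 4 + ["e3e4"] * 4 + ["e4e4"] * 4)
        rng = np.random.default_rng(1)
        matrix = ProteinMatrix(pd.DataFrame(
            {"P1": np.concatenate([rng.normal(m, 1, 4) for m in (0, 1, 3)])},
            index=cohort.index))
        res = residualize_and_compare(matrix, cohort, covariates=[])
        assert len(res) == 3           # all pairs of three groups
        np.testing.assert_allclose(
            np.sort(res["p_holm"]),
            np.sort(multipletests(res["p"], method="holm")[1]))


class TestEffectConcordance:
    def _table(self, betas, qs):
        return pd.DataFrame({
            "analyte_id": [f"A{i}" for i in range(len(betas))],
            "term": "apoe", "beta": betas, "q": qs})

    def test_identical_tables_rho_one(self):
        t = self._table([0.1, 0.5, -0.3, 0.2], [0.01] * 4)
        rho, p, sig = effect_concordance(t, t)
        assert rho == pytest.approx(1.0)
        assert sig == [f"A{i}" for i in range(4)]

    def test_sign_flip_rho_minus_one(self):
        t = self._table([0.1, 0.5, -0.3, 0.2], [0.5] * 4)
        t2 = t.copy()
        t2["beta"] = -t2["beta"]
        rho, _, sig = effect_concordance(t, t2)
        assert rho == pytest.approx(-1.0)
        assert sig == []

    def test_matches_rank_formula_on_ten_rows(self):
        rng = np.random.default_rng(8)
        a = self._table(rng.normal(0, 1, 10), rng.random(10))
        b = self._table(rng.normal(0, 1, 10), rng.random(10))
        rho, _, _ = effect_concordance(a, b)
        ra = pd.Series(a["beta"]).rank()
        rb = pd.Series(b["beta"]).rank()
        d2 = ((ra - rb) ** 2).sum()
        rho_formula = 1 - 6 * d2 / (10 * (100 - 1))     # no ties
        assert rho == pytest.approx(rho_formula, abs=1e-12)

    def test_fewer_than_three_shared_raises(self):
        with pytest.raises(ValueError, match="shared"):
            effect_concordance(self._table([1, 2], [0.1, 0.1]),
                               self._table([1, 2], [0.1, 0.1]).iloc[:2])
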