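"""Differential protein abundance, stratified contrasts, and moderation.

Three nested linear model types relate each protein (z-scored, so betas are
in protein-SD units) to APOE carrier status and/or disease status:

* type 1 — protein ~ APOE + covariates
* type 2 — protein ~ disease + covariates
* type 3 — protein ~ APOE + disease + covariates

with age, sex, per-subject mean abundance (and cohort, when multi-cohort)
as covariates, optional APOE×age / APOE×diagnosis / APOE×sex interaction
terms, strata (all / CU / AD / amyloid-negative / amyloid-positive /
median-age halves), Benjamini–Hochberg FDR per (stratum × term) family,
residualized six-group Welch comparisons with Holm adjustment, Spearman
concordance of effect sizes between strata, and a moderation scan with
simple slopes and Johnson–Neyman intervals for the genotype × protein
interaction on amyloid status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import GENOTYPES, ProteinMatrix
from .preprocess import compute_mean_abundance, exclude_outlier_values

__all__ = [
    "ContrastSpec", "E4_CONTRAST", "E2_CONTRAST", "get_contrast",
    "make_contrast_groups", "bh_fdr", "ProteinAssociation", "run_assoc",
    "residualize_and_compare", "effect_concordance", "ModerationScan",
    "moderation_scan",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Carrier/reference/excluded genotype partition for one allele."""

    allele: str
    carriers: frozenset
    reference: frozenset
    excluded: frozenset

    def __post_init__(self):
        parts = self.carriers | self.reference | self.excluded
        if parts != set(GENOTYPES):
            raise ValueError("contrast sets must partition the six genotypes")
        if (self.carriers & self.reference or self.carriers & self.excluded
                or self.reference & self.excluded):
            raise ValueError("contrast sets must be disjoint")


#: ε4 carriers (ε3/ε4, ε4/ε4) versus ε3/ε3; ε2 genotypes excluded
#: (ε2/ε4 would confound the two allele effects).
E4_CONTRAST = ContrastSpec("E4", frozenset({"e3e4", "e4e4"}),
                           frozenset({"e3e3"}),
                           frozenset({"e2e2", "e2e3", "e2e4"}))
#: ε2 carriers (ε2/ε2, ε2/ε3) versus ε3/ε3; ε4 genotypes excluded.
E2_CONTRAST = ContrastSpec("E2", frozenset({"e2e2", "e2e3"}),
                           frozenset({"e3e3"}),
                           frozenset({"e3e4", "e4e4", "e2e4"}))


def get_contrast(allele: str) -> ContrastSpec:
    try:
        return {"e4": E4_CONTRAST, "E4": E4_CONTRAST,
                "e2": E2_CONTRAST, "E2": E2_CONTRAST}[allele]
    except KeyError:
        raise ValueError(f"unknown allele {allele!r}; use 'e4' or 'e2'")


def make_contrast_groups(cohort: pd.DataFrame, contrast: ContrastSpec,
                         descriptive_six_group: bool = False) -> pd.Series:
    """Per-subject group assignment for an allele contrast.

    Default: 1.0 for carriers, 0.0 for the reference genotype, NaN for
    excluded genotypes.  In descriptive mode, returns the six genotype
    labels with ε2/ε2 and ε2/ε3 merged into ``"22/23"`` (the ε2/ε2 group is
    tiny in realistic cohorts).
    """
    if cohort["genotype"].isna().any():
        raise ValueError("genotype missing for some subjects")
    g = cohort["genotype"]
    if descriptive_six_group:
        merged = g.replace({"e2e2": "22/23", "e2e3": "22/23"})
        return merged.rename("genotype_group")
    coded = pd.Series(np.nan, index=cohort.index, name="apoe")
    coded[g.isin(contrast.carriers)] = 1.0
    coded[g.isin(contrast.reference)] = 0.0
    if (coded == 0).sum() == 0:
        raise ValueError("empty reference group for contrast "
                         f"{contrast.allele}")
    return coded


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.  NaN p propagates NaN q."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


# --------------------------------------------------------------------------
# model fitting

_STRATA = ("all", "cu", "ad", "abneg", "abpos", "age_low", "age_high")


def _stratum_mask(cohort: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=cohort.index)
    if stratum in ("cu", "ad"):
        return cohort["diagnosis"] == stratum.upper()
    if stratum in ("abneg", "abpos"):
        label = "negative" if stratum == "abneg" else "positive"
        return cohort["abeta_status"] == label
    if stratum in ("age_low", "age_high"):
        med = cohort["age"].median()
        return cohort["age"] <= med if stratum == "age_low" \
            else cohort["age"] > med
    raise ValueError(f"unknown stratum {stratum!r}; expected one of {_STRATA}")


def _disease_indicator(cohort: pd.DataFrame, disease_variable: str) -> pd.Series:
    """0/1 disease coding.  ``dx``: AD=1, CU=0, MCI dropped (NaN);
    ``abeta``: positive=1, negative=0."""
    if disease_variable == "dx":
        d = cohort["diagnosis"].map({"CU": 0.0, "AD": 1.0})
    elif disease_variable == "abeta":
        d = cohort["abeta_status"].map({"negative": 0.0, "positive": 1.0})
    else:
        raise ValueError(f"unknown disease variable {disease_variable!r}")
    return d.rename("disease")


def _covariate_frame(cohort: pd.DataFrame, matrix: ProteinMatrix,
                     covariates) -> pd.DataFrame:
    """Numeric covariate design block.  Sex female=0/male=1; cohort
    treatment-coded against the largest cohort; mean abundance computed
    from the matrix when requested and not already a cohort column."""
    if covariates is None:
        covariates = ["age", "sex", "mean_abundance"]
        if "cohort" in cohort and cohort["cohort"].nunique() > 1:
            covariates.append("cohort")
    cols = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = cohort["sex"].map({"female": 0.0, "male": 1.0})
        elif cov == "cohort":
            counts = cohort["cohort"].value_counts()
            for level in counts.index[1:]:
                cols[f"cohort[{level}]"] = (
                    cohort["cohort"] == level).astype(float)
        elif cov == "mean_abundance" and cov not in cohort:
            cols[cov] = compute_mean_abundance(matrix)
        else:
            cols[cov] = pd.to_numeric(cohort[cov])
    return pd.DataFrame(cols, index=cohort.index)


def _ols_records(y: np.ndarray, X: pd.DataFrame, terms: list[str],
                 analyte_id: str, stratum: str, note: str = "") -> list[dict]:
    fit = sm.OLS(y, X).fit()
    recs = []
    for term in terms:
        recs.append({
            "analyte_id": analyte_id, "term": term,
            "beta": fit.params[term], "se": fit.bse[term],
            "t": fit.tvalues[term], "p": fit.pvalues[term],
            "n": int(len(y)), "stratum": stratum, "note": note,
        })
    return recs


class ProteinAssociation(BaseEstimator):
    """Per-analyte linear model of one model type within one stratum.

    Parameters mirror the analysis grid: ``model_type`` in {1, 2, 3},
    ``contrast`` ('e4'/'e2'), ``disease_variable`` ('dx'/'abeta'),
    ``stratum`` (see module docstring), ``interaction`` in
    {'none', 'age', 'dx', 'sex'} added to the APOE term.  Proteins are
    z-scored within the analysis sample by default so betas are in SD
    units; the raw scale is available with ``zscore=False``.

    After :meth:`fit`, ``results_`` holds one row per analyte × term with
    beta, se, t, two-sided p, and BH q within each (stratum × term) family.
    """

    def __init__(self, model_type: int = 1, contrast: str = "e4",
                 disease_variable: str = "dx", stratum: str = "all",
                 interaction: str = "none", covariates=None,
                 zscore: bool = True, outlier_sd: float = 5.0,
                 min_n: int = 30):
        self.model_type = model_type
        self.contrast = contrast
        self.disease_variable = disease_variable
        self.stratum = stratum
        self.interaction = interaction
        self.covariates = covariates
        self.zscore = zscore
        self.outlier_sd = outlier_sd
        self.min_n = min_n

    # term layout per model type
    def _terms(self) -> list[str]:
        terms = {1: ["apoe"], 2: ["disease"], 3: ["apoe", "disease"]}[
            self.model_type]
        if self.interaction != "none":
            if self.model_type == 2:
                raise ValueError("interaction requires an APOE term")
            terms = terms + [f"apoe:{self.interaction}"]
        return terms

    def fit(self, matrix: ProteinMatrix, cohort: pd.DataFrame):
        if self.model_type not in (1, 2, 3):
            raise ValueError("model_type must be 1, 2, or 3")
        contrast = get_contrast(self.contrast)
        mask = _stratum_mask(cohort, self.stratum)
        sub = cohort[mask]
        base = _covariate_frame(sub, matrix.select_subjects(sub.index),
                                self.covariates)
        design = pd.DataFrame({"const": 1.0}, index=sub.index)
        if self.model_type in (1, 3):
            design["apoe"] = make_contrast_groups(sub, contrast)
        if self.model_type in (2, 3):
            design["disease"] = _disease_indicator(sub, self.disease_variable)
        if self.interaction != "none":
            mod = {"age": pd.to_numeric(sub["age"]),
                   "sex": sub["sex"].map({"female": 0.0, "male": 1.0}),
                   "dx": _disease_indicator(sub, self.disease_variable)}[
                       self.interaction]
            if self.interaction == "dx" and "disease" not in design:
                design["disease"] = mod
            design[f"apoe:{self.interaction}"] = design["apoe"] * mod
        design = pd.concat([design, base], axis=1)

        terms = self._terms()
        records: list[dict] = []
        vals = matrix.values.reindex(sub.index)
        for analyte in vals.columns:
            records.extend(self._fit_one(vals[analyte], design, terms,
                                         analyte))
        res = pd.DataFrame(records)
        if len(res):
            for term in terms:
                sel = res["term"] == term
                res.loc[sel, "q"] = bh_fdr(res.loc[sel, "p"])
        else:
            res = pd.DataFrame(columns=["analyte_id", "term", "beta", "se",
                                        "t", "p", "q", "n", "stratum",
                                        "note"])
        self.results_ = res
        self.n_stratum_ = int(mask.sum())
        return self

    def _fit_one(self, y: pd.Series, design: pd.DataFrame, terms, analyte):
        frame = design.copy()
        frame["y"] = y
        frame = frame.dropna()
        note = ""
        if len(frame) < self.min_n:
            return []
        retained, excluded = exclude_outlier_values(frame["y"],
                                                    self.outlier_sd)
        if len(excluded):
            frame = frame.drop(index=excluded)
            note = f"outliers_excluded={len(excluded)}"
        yv = frame.pop("y")
        if yv.std(ddof=1) == 0 or not np.isfinite(yv.std(ddof=1)):
            return [{"analyte_id": analyte, "term": t, "beta": 0.0,
                     "se": np.nan, "t": np.nan, "p": np.nan,
                     "n": int(len(yv)), "stratum": self.stratum,
                     "note": "constant_outcome"} for t in terms]
        if self.zscore:
            yv = (yv - yv.mean()) / yv.std(ddof=1)
        X = frame
        # drop covariate columns that are constant in this analysis sample
        # (e.g. a single-sex stratum) to keep the design full rank
        const_cols = [c for c in X.columns
                      if c != "const" and c not in terms
                      and X[c].nunique() <= 1]
        if const_cols:
            X = X.drop(columns=const_cols)
            note = (note + ";" if note else "") + \
                "dropped_constant:" + ",".join(const_cols)
            warnings.warn(f"{analyte}: dropped constant covariates "
                          f"{const_cols} in stratum {self.stratum}")
        for t in terms:
            if X[t].nunique() <= 1:
                return [{"analyte_id": analyte, "term": tt, "beta": 0.0,
                         "se": np.nan, "t": np.nan, "p": np.nan,
                         "n": int(len(yv)), "stratum": self.stratum,
                         "note": "constant_predictor"} for tt in terms]
        return _ols_records(yv.to_numpy(), X, list(terms), analyte,
                            self.stratum, note)


def fit_protein_model(matrix: ProteinMatrix, cohort: pd.DataFrame,
                      **params) -> pd.DataFrame:
    """Fit one :class:`ProteinAssociation` configuration and return its
    results table."""
    est = ProteinAssociation(**params)
    est.fit(matrix, cohort)
    return est.results_


def run_assoc(matrix: ProteinMatrix, cohort: pd.DataFrame,
              contrast: str = "e4", model_type: int = 1,
              disease_variable: str = "dx", strata=("all",),
              min_n: int = 30, **params) -> pd.DataFrame:
    """Run one model type across strata; BH is applied within each
    (stratum × term) family.  Strata with fewer than ``min_n`` subjects
    are skipped with a warning."""
    tables = []
    for stratum in strata:
        mask = _stratum_mask(cohort, stratum)
        if mask.sum() < min_n:
            warnings.warn(f"stratum {stratum!r} has n={int(mask.sum())} "
                          f"< {min_n}; skipped")
            continue
        est = ProteinAssociation(model_type=model_type, contrast=contrast,
                                 disease_variable=disease_variable,
                                 stratum=stratum, min_n=min_n, **params)
        est.fit(matrix, cohort)
        tables.append(est.results_)
    if not tables:
        return pd.DataFrame(columns=["analyte_id", "term", "beta", "se",
                                     "t", "p", "q", "n", "stratum", "note"])
    return pd.concat(tables, ignore_index=True)


# --------------------------------------------------------------------------
# residualized group comparisons and concordance

def residualize_and_compare(matrix: ProteinMatrix, cohort: pd.DataFrame,
                            covariates=None,
                            groups: pd.Series | None = None) -> pd.DataFrame:
    """Welch comparisons of covariate-residualized protein levels between
    genotype groups, Holm-adjusted across the pairs of each analyte.

    ``groups`` defaults to the descriptive six-group coding with ε2/ε2 and
    ε2/ε3 merged.  Residuals come from a covariate-only regression (no
    group term); with no covariates they are centered values.
    """
    if groups is None:
        groups = make_contrast_groups(cohort, E4_CONTRAST,
                                      descriptive_six_group=True)
    base = _covariate_frame(cohort, matrix, covariates) \
        if covariates is None or len(covariates) else \
        pd.DataFrame(index=cohort.index)
    if covariates is not None and len(covariates) == 0:
        base = pd.DataFrame(index=cohort.index)
    rows = []
    for analyte in matrix.values.columns:
        y = matrix.values[analyte].reindex(cohort.index)
        frame = pd.concat([base, y.rename("y"), groups.rename("g")], axis=1)
        frame = frame.dropna(subset=[c for c in frame if c != "g"])
        X = sm.add_constant(frame.drop(columns=["y", "g"]), has_constant="add")
        resid = frame["y"] - sm.OLS(frame["y"], X).fit().fittedvalues
        labels = [g for g in pd.unique(frame["g"].dropna())]
        pairs, stats_rows = [], []
        for i, ga in enumerate(labels):
            for gb in labels[i + 1:]:
                ra = resid[frame["g"] == ga]
                rb = resid[frame["g"] == gb]
                if len(ra) < 2 or len(rb) < 2:
                    continue
                if ra.var(ddof=1) == 0 and rb.var(ddof=1) == 0:
                    t, p = (0.0, 1.0) if ra.mean() == rb.mean() \
                        else (np.inf, 0.0)
                    df = len(ra) + len(rb) - 2.0
                else:
                    t, p = stats.ttest_ind(ra, rb, equal_var=False)
                    va, vb = ra.var(ddof=1) / len(ra), rb.var(ddof=1) / len(rb)
                    df = (va + vb) ** 2 / (va**2 / (len(ra) - 1)
                                           + vb**2 / (len(rb) - 1))
                pairs.append((ga, gb))
                stats_rows.append((t, p, df, len(ra), len(rb)))
        if not pairs:
            continue
        padj = multipletests([r[1] for r in stats_rows], method="holm")[1]
        for (ga, gb), (t, p, df, na, nb), ph in zip(pairs, stats_rows, padj):
            rows.append({"analyte_id": analyte, "group_a": ga, "group_b": gb,
                         "t": t, "df": df, "p": p, "p_holm": ph,
                         "n_a": na, "n_b": nb})
    return pd.DataFrame(rows)


def effect_concordance(assoc_a: pd.DataFrame, assoc_b: pd.DataFrame,
                       term: str = "apoe", alpha_q: float = 0.05):
    """Spearman concordance of effect sizes between two association tables.

    Returns ``(rho, p, shared_significant)`` over the analytes present in
    both tables for ``term``; ``shared_significant`` lists analytes with
    q < ``alpha_q`` in both.
    """
    a = assoc_a[assoc_a["term"] == term].set_index("analyte_id")
    b = assoc_b[assoc_b["term"] == term].set_index("analyte_id")
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared analytes; need >= 3")
    rho, p = stats.spearmanr(a.loc[shared, "beta"], b.loc[shared, "beta"])
    sig = [an for an in shared
           if a.loc[an, "q"] < alpha_q and b.loc[an, "q"] < alpha_q]
    return float(rho), float(p), sig


# --------------------------------------------------------------------------
# moderation: simple slopes and Johnson–Neyman intervals

def _johnson_neyman(bg: float, bi: float, vgg: float, vgi: float,
                    vii: float, crit: float):
    """Solve |bg + bi·m| = crit·SE(m) for the moderator m.

    Returns ``(lower, upper, region)`` where region is 'inside' (the
    conditional effect is significant between the bounds), 'outside'
    (significant beyond them), 'all', or 'none'.
    """
    A = bi**2 - crit**2 * vii
    B = 2.0 * (bg * bi - crit**2 * vgi)
    C = bg**2 - crit**2 * vgg

    def sig(m):
        return (bg + bi * m) ** 2 - crit**2 * (vgg + 2 * m * vgi
                                               + m**2 * vii) > 0

    if abs(A) < 1e-300:
        if B == 0.0:
            return (np.nan, np.nan, "all" if C > 0 else "none")
        root = -C / B
        return ((root, np.nan, "outside") if sig(root + 1.0)
                else (np.nan, root, "outside"))
    disc = B**2 - 4 * A * C
    if disc <= 0:
        return (np.nan, np.nan, "all" if sig(0.0) else "none")
    r1 = (-B - np.sqrt(disc)) / (2 * A)
    r2 = (-B + np.sqrt(disc)) / (2 * A)
    lo, hi = min(r1, r2), max(r1, r2)
    inside_sig = sig(0.5 * (lo + hi))
    return (lo, hi, "inside" if inside_sig else "outside")


class ModerationScan(BaseEstimator):
    """Genotype × protein interaction models for a binary outcome.

    For each analyte fits
    ``outcome ~ APOE + protein + APOE×protein + covariates`` with the
    chosen link (``logistic`` default; ``linear_probability`` matches a
    printed linear-model formulation), then reports the interaction term,
    simple slopes of the genotype effect at protein = mean and ±1 SD, and
    Johnson–Neyman bounds on the (z-scored) protein scale where the
    conditional genotype effect's CI excludes zero.  The critical value is
    the normal quantile for the logistic link and the t quantile for the
    linear-probability link.
    """

    def __init__(self, outcome: str = "abeta", contrast: str = "e4",
                 link: str = "logistic", alpha: float = 0.05,
                 covariates=None, outlier_sd: float = 5.0):
        self.outcome = outcome
        self.contrast = contrast
        self.link = link
        self.alpha = alpha
        self.covariates = covariates
        self.outlier_sd = outlier_sd

    def fit(self, matrix: ProteinMatrix, cohort: pd.DataFrame):
        if self.link not in ("logistic", "linear_probability"):
            raise ValueError(f"unknown link {self.link!r}")
        contrast = get_contrast(self.contrast)
        y = _disease_indicator(cohort, self.outcome)
        g = make_contrast_groups(cohort, contrast)
        base = _covariate_frame(cohort, matrix, self.covariates)
        rows = []
        for analyte in matrix.values.columns:
            rows.append(self._fit_one(matrix.values[analyte], y, g, base,
                                      analyte))
        self.results_ = pd.DataFrame(rows)
        return self

    def _fit_one(self, protein: pd.Series, y: pd.Series, g: pd.Series,
                 base: pd.DataFrame, analyte: str) -> dict:
        frame = pd.concat([y.rename("y"), g.rename("g"),
                           protein.rename("m"), base], axis=1).dropna()
        retained, excluded = exclude_outlier_values(frame["m"],
                                                    self.outlier_sd)
        frame = frame.drop(index=excluded)
        m = frame["m"]
        frame["m"] = (m - m.mean()) / m.std(ddof=1)
        frame["g:m"] = frame["g"] * frame["m"]
        X = sm.add_constant(
            frame[["g", "m", "g:m"] + list(base.columns)], has_constant="add")
        rec = {"analyte_id": analyte, "n": int(len(frame)),
               "alpha": self.alpha, "link": self.link, "unstable": False}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if self.link == "logistic":
                    fit = sm.Logit(frame["y"], X).fit(disp=0, maxiter=100)
                    if not fit.mle_retvals["converged"]:
                        raise RuntimeError("no convergence")
                    crit = stats.norm.ppf(1 - self.alpha / 2)
                else:
                    fit = sm.OLS(frame["y"], X).fit()
                    crit = stats.t.ppf(1 - self.alpha / 2, fit.df_resid)
        except Exception:
            rec.update({"beta_int": np.nan, "se_int": np.nan, "p_int": np.nan,
                        "jn_lower": np.nan, "jn_upper": np.nan,
                        "jn_region": "none", "unstable": True})
            for tag in ("m1sd", "mean", "p1sd"):
                rec[f"slope_{tag}"] = np.nan
                rec[f"slope_{tag}_lo"] = np.nan
                rec[f"slope_{tag}_hi"] = np.nan
            return rec

        cov = fit.cov_params()
        bg, bi = fit.params["g"], fit.params["g:m"]
        vgg = cov.loc["g", "g"]
        vgi = cov.loc["g", "g:m"]
        vii = cov.loc["g:m", "g:m"]
        rec.update({"beta_int": bi, "se_int": np.sqrt(vii),
                    "p_int": fit.pvalues["g:m"], "crit": crit})
        for mval, tag in ((-1.0, "m1sd"), (0.0, "mean"), (1.0, "p1sd")):
            eff = bg + bi * mval
            se = np.sqrt(vgg + 2 * mval * vgi + mval**2 * vii)
            rec[f"slope_{tag}"] = eff
            rec[f"slope_{tag}_lo"] = eff - crit * se
            rec[f"slope_{tag}_hi"] = eff + crit * se
        lo, hi, region = _johnson_neyman(bg, bi, vgg, vgi, vii, crit)
        rec.update({"jn_lower": lo, "jn_upper": hi, "jn_region": region})
        return rec


def moderation_scan(matrix: ProteinMatrix, cohort: pd.DataFrame,
                    **params) -> pd.DataFrame:
    """Functional wrapper over :class:`ModerationScan`."""
    est = ModerationScan(**params)
    est.fit(matrix, cohort)
    return est.results_
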