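"""Synthetic genotype–protein–disease cohort generator with known truth.

The generator reproduces the causal structure the downstream analysis
assumes: APOE genotype (six diplotypes at population-realistic frequencies)
and demographic covariates are drawn first; "upstream" proteins respond to
genotype and covariates; disease status follows a logistic model driven by
genotype, age, and the planted mediator proteins, with its intercept
calibrated by root-finding so the expected prevalence matches the target;
"downstream" proteins are then perturbed by disease status.  That ordering
— genotype → covariates → upstream proteins → disease → downstream
proteins — is the only one compatible with testing both mediation
directions (genotype → protein → disease and genotype → disease → protein)
against a known truth.

Every analyte draws from its own named random stream derived from the
master seed, so runs are bit-reproducible and adding an analyte to the plan
never perturbs the values of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._utils import child_rng, child_seed
from .containers import GENOTYPES, ProteinMatrix

__all__ = [
    "AnalyteSpec", "SimConfig", "SimResult", "OracleResult",
    "default_genotype_freqs", "default_analyte_plan", "simulate_cohort",
    "plant_missingness", "expected_mediation_oracle",
]

TRUTH_CLASSES = ("mediator", "pathology_mediated", "genotype_specific",
                 "disease_specific", "nonspecific", "null")

#: Hardy–Weinberg genotype frequencies at allele frequencies
#: ε2 = 0.08, ε3 = 0.78, ε4 = 0.14 — typical of populations of European
#: ancestry and close to the diplotype mix of the memory-clinic cohorts
#: this generator emulates.
_DEFAULT_FREQS = {
    "e2e2": 0.0064, "e2e3": 0.1248, "e2e4": 0.0224,
    "e3e3": 0.6084, "e3e4": 0.2184, "e4e4": 0.0196,
}


def default_genotype_freqs() -> dict[str, float]:
    return dict(_DEFAULT_FREQS)


@dataclass
class AnalyteSpec:
    """Planted generative parameters for one analyte.

    Effects are expressed per protein standard deviation (noise SD 1 means
    the marginal protein SD is ≈1, so ``a``/``d`` read as SD-unit shifts and
    ``b`` as log-odds of disease per protein SD).

    a_e4 / a_e2
        Genotype→protein effects for ε4 and ε2 carriage.
    b
        Protein→disease effect on the disease log-odds.
    d
        Disease→protein effect added to affected subjects.
    """

    analyte_id: str
    truth_class: str
    a_e4: float = 0.0
    a_e2: float = 0.0
    b: float = 0.0
    d: float = 0.0
    age_load: float = 0.0
    sex_load: float = 0.0
    cohort_load: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.truth_class not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth class {self.truth_class!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        a = max(abs(self.a_e4), abs(self.a_e2))
        cls = self.truth_class
        ok = {
            "mediator": a != 0 and self.b != 0 and self.d == 0,
            "pathology_mediated": self.d != 0 and self.b == 0 and a <= 0.1,
            "genotype_specific": a != 0 and self.b == 0 and self.d == 0,
            "disease_specific": a == 0 and self.b == 0 and self.d != 0,
            "nonspecific": a != 0 and self.d != 0 and self.b == 0,
            "null": a == 0 and self.b == 0 and self.d == 0,
        }[cls]
        if not ok:
            raise ValueError(
                f"parameters of {self.analyte_id!r} inconsistent with "
                f"truth class {cls!r}: a={a}, b={self.b}, d={self.d}")


def default_analyte_plan(
    n_mediator: int = 3,
    n_pathology: int = 5,
    n_genotype: int = 5,
    n_disease: int = 5,
    n_nonspecific: int = 5,
    n_null: int = 377,
) -> list[AnalyteSpec]:
    """The default planted-effect plan: a mostly-null 400-plex panel.

    The large null fraction matters: the per-subject mean-abundance
    covariate used downstream averages the whole panel, so the fraction of
    genotype-affected analytes must be small (as it is on real multiplex
    platforms) or the covariate itself carries genotype signal and biases
    every fit.

    Mediators carry a 0.7 SD genotype effect and 0.3 log-odds/SD disease
    effect — strong enough that their upstream mediation share clearly
    exceeds the reverse-regression downstream share.  Pathology-mediated
    proteins shift 1.5 SD with disease (their marginal genotype
    association, induced through disease, must clear the causal-steps
    gate).  Genotype-specific proteins shift 0.4 SD with ε4 carriage;
    disease-specific proteins shift 0.25 SD with disease (small enough
    that the induced genotype association stays sub-threshold);
    nonspecific proteins combine a 0.3 SD genotype effect with an
    under-powered 0.05 SD disease effect; nulls are pure noise.
    """
    plan: list[AnalyteSpec] = []
    i = 0

    def add(n, cls, **kw):
        nonlocal i
        for _ in range(n):
            plan.append(AnalyteSpec(f"A{i:04d}", cls, **kw))
            i += 1

    add(n_mediator, "mediator", a_e4=0.7, b=0.3)
    add(n_pathology, "pathology_mediated", d=1.5)
    add(n_genotype, "genotype_specific", a_e4=0.4)
    add(n_disease, "disease_specific", d=0.25)
    add(n_nonspecific, "nonspecific", a_e4=0.3, d=0.05)
    add(n_null, "null")
    return plan


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    direct_e4 / direct_e2 are the genotype→disease log-odds not carried by
    any protein.  Together with the mediated paths of the default plan the
    total ε4 effect is ≈0.9 log-odds (odds ratio ≈2.5); the direct share
    is kept modest so the planted mediators account for a clearly
    identifiable fraction of the genotype–disease association.
    """

    n_subjects: int = 4000
    genotype_freqs: dict[str, float] = field(
        default_factory=default_genotype_freqs)
    age_mean: float = 70.0
    age_sd: float = 8.0
    sex_prob_male: float = 0.47
    n_cohorts: int = 3
    cohort_shift_sd: float = 0.15
    target_prevalence: float = 0.35
    direct_e4: float = 0.3
    direct_e2: float = -0.3
    age_disease_logodds: float = 0.05
    analyte_plan: list[AnalyteSpec] = field(default_factory=default_analyte_plan)
    missing_rate: float = 0.0
    lod_quantile: float = 0.0
    master_seed: int = 0
    oracle_draws: int = 100_000

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        freqs = self.genotype_freqs
        if set(freqs) != set(GENOTYPES):
            raise ValueError("genotype_freqs must cover the six genotypes")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"genotype_freqs sum to {total}, not 1")
        if any(not 0 <= p <= 1 for p in freqs.values()):
            raise ValueError("genotype frequencies must lie in [0, 1]")
        if freqs["e3e3"] == 0:
            raise ValueError(
                "reference genotype e3e3 has zero frequency; the carrier "
                "versus e3e3 contrasts downstream would be undefined")
        for p, name in [(self.sex_prob_male, "sex_prob_male"),
                        (self.target_prevalence, "target_prevalence"),
                        (self.missing_rate, "missing_rate"),
                        (self.lod_quantile, "lod_quantile")]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        ids = [a.analyte_id for a in self.analyte_plan]
        if len(ids) != len(set(ids)):
            raise ValueError("analyte ids must be unique")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analyte_plan"] = [asdict(a) for a in self.analyte_plan]
        return d


@dataclass
class SimResult:
    cohort: pd.DataFrame
    matrix: ProteinMatrix
    truth: pd.DataFrame
    intercept: float
    realized_prevalence: float

    def __iter__(self):
        return iter((self.cohort, self.matrix, self.truth))


def _carrier_indicators(genotype: np.ndarray):
    # e2/e4 heterozygotes carry both alleles; they receive both allele
    # effects generatively and are excluded from either carrier contrast
    # at analysis time.
    x4 = np.isin(genotype, ("e3e4", "e4e4", "e2e4")).astype(float)
    x2 = np.isin(genotype, ("e2e2", "e2e3", "e2e4")).astype(float)
    return x4, x2


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate a cohort table, protein matrix, and truth table.

    Returns a :class:`SimResult`; iterating it yields
    ``(cohort, matrix, truth)``.
    """
    n = config.n_subjects
    seed = config.master_seed

    rng_g = child_rng(seed, "genotype")
    probs = np.array([config.genotype_freqs[g] for g in GENOTYPES])
    genotype = rng_g.choice(GENOTYPES, size=n, p=probs / probs.sum())
    x4, x2 = _carrier_indicators(genotype)

    rng_c = child_rng(seed, "covariates")
    age = np.clip(rng_c.normal(config.age_mean, config.age_sd, n), 30.0, 95.0)
    male = (rng_c.random(n) < config.sex_prob_male).astype(int)
    cohort_idx = rng_c.integers(0, config.n_cohorts, n)
    cohort_shift = rng_c.normal(0.0, config.cohort_shift_sd, config.n_cohorts)

    age_z = (age - config.age_mean) / config.age_sd

    # pre-disease protein component for every analyte
    pre = {}
    for spec in config.analyte_plan:
        rng_a = child_rng(seed, "analyte", spec.analyte_id)
        noise = rng_a.normal(0.0, spec.noise_sd, n)
        pre[spec.analyte_id] = (
            spec.a_e4 * x4 + spec.a_e2 * x2
            + spec.age_load * age_z + spec.sex_load * male
            + spec.cohort_load * cohort_shift[cohort_idx] + noise
        )

    # disease from a logistic model; intercept calibrated so the expected
    # prevalence over this cohort equals the target
    eta = (config.direct_e4 * x4 + config.direct_e2 * x2
           + config.age_disease_logodds * (age - config.age_mean))
    for spec in config.analyte_plan:
        if spec.b != 0.0:
            eta = eta + spec.b * pre[spec.analyte_id]
    alpha = _calibrate_intercept(eta, config.target_prevalence)
    rng_d = child_rng(seed, "disease")
    disease = (rng_d.random(n) < expit(alpha + eta)).astype(int)

    values = {}
    for spec in config.analyte_plan:
        values[spec.analyte_id] = pre[spec.analyte_id] + spec.d * disease

    subject_id = [f"S{i:05d}" for i in range(n)]
    rng_ab = child_rng(seed, "abeta")
    abeta_ratio = np.clip(
        0.092 - 0.022 * disease + rng_ab.normal(0.0, 0.008, n), 0.02, 0.18)
    cohort_tbl = pd.DataFrame(
        {
            "genotype": genotype,
            "age": age,
            "sex": np.where(male == 1, "male", "female"),
            "cohort": [f"cohort{c}" for c in cohort_idx],
            "diagnosis": np.where(disease == 1, "AD", "CU"),
            "abeta_status": np.where(disease == 1, "positive", "negative"),
            "abeta_ratio": abeta_ratio,
        },
        index=pd.Index(subject_id, name="subject_id"),
    )

    matrix = ProteinMatrix(
        pd.DataFrame(values, index=cohort_tbl.index),
        pd.DataFrame(
            {
                "gene": [f"GENE{i:04d}" for i in range(len(config.analyte_plan))],
                "platform": "pea",
            },
            index=pd.Index([a.analyte_id for a in config.analyte_plan],
                           name="analyte_id"),
        ),
    )
    if config.missing_rate > 0 or config.lod_quantile > 0:
        matrix = plant_missingness(matrix, config.missing_rate,
                                   config.lod_quantile,
                                   seed=child_seed(seed, "missingness"))

    contrast_mask = np.isin(genotype, ("e3e3", "e3e4", "e4e4"))
    truth = _truth_table(config, eta, x4, pre, contrast_mask)
    truth["realized_prevalence"] = disease.mean()
    truth["master_seed"] = seed
    for g in GENOTYPES:
        truth[f"n_{g}"] = int((genotype == g).sum())

    return SimResult(cohort_tbl, matrix, truth, alpha, float(disease.mean()))


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    if target <= 0.0 or target >= 1.0:
        return -np.inf if target <= 0 else np.inf

    def gap(alpha):
        return expit(alpha + eta).mean() - target

    return brentq(gap, -40.0, 40.0, xtol=1e-10)


def _truth_table(config: SimConfig, eta: np.ndarray, x4: np.ndarray,
                 pre: dict, contrast_mask: np.ndarray) -> pd.DataFrame:
    rows = []
    for spec in config.analyte_plan:
        prop = np.nan
        if spec.b != 0.0 and spec.a_e4 != 0.0 and config.oracle_draws > 0:
            # covariate offsets for the carrier-vs-e3e3 estimand: the
            # disease linear predictor minus the exposure term and minus
            # this analyte's own mediated path, over contrast subjects only
            offsets = (eta - config.direct_e4 * x4
                       - spec.b * pre[spec.analyte_id])[contrast_mask]
            p_carrier = (config.genotype_freqs["e3e4"]
                         + config.genotype_freqs["e4e4"])
            p_exp = p_carrier / (p_carrier + config.genotype_freqs["e3e3"])
            prop = expected_mediation_oracle(
                spec.a_e4, spec.b, config.direct_e4, "logistic",
                covariate_design=offsets, exposure_prob=p_exp,
                target_prevalence=config.target_prevalence,
                noise_sd=spec.noise_sd, n_mc=config.oracle_draws,
                seed=child_seed(config.master_seed, "oracle",
                                spec.analyte_id),
            ).prop_mediated
        elif spec.b == 0.0:
            prop = 0.0
        rows.append({
            "analyte_id": spec.analyte_id,
            "truth_class": spec.truth_class,
            "a_e4": spec.a_e4, "a_e2": spec.a_e2,
            "b": spec.b, "d": spec.d,
            "expected_prop_upstream": prop,
        })
    return pd.DataFrame(rows).set_index("analyte_id")


def plant_missingness(matrix: ProteinMatrix, missing_rate: float,
                      lod_quantile: float, seed: int = 0) -> ProteinMatrix:
    """Apply PEA-style missingness and LOD censoring to a protein matrix.

    Entries go missing independently at ``missing_rate``.  When
    ``lod_quantile`` > 0, each analyte's LOD is set at that quantile of its
    observed values, recorded in the analyte metadata, and values strictly
    below it are flagged (values are kept — retention rules are the QC
    module's job, not the generator's).
    """
    if not 0 <= missing_rate <= 1 or not 0 <= lod_quantile <= 1:
        raise ValueError("rates must lie in [0, 1]")
    out = matrix.copy()
    if missing_rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(out.values.shape) < missing_rate
        vals = out.values.to_numpy(dtype=float, na_value=np.nan)
        vals[mask] = np.nan
        out.values = pd.DataFrame(vals, index=out.values.index,
                                  columns=out.values.columns)
    if lod_quantile > 0:
        lod = out.values.quantile(lod_quantile)
        out.analytes = out.analytes.copy()
        out.analytes["lod"] = lod
        out.below_lod = out.values.lt(lod, axis=1)
    return out


@dataclass
class OracleResult:
    """Expected mediation decomposition for planted effects."""

    acme: float
    ade: float
    total: float
    prop_mediated: float
    se_prop: float
    n_mc: int


def expected_mediation_oracle(
    a: float,
    b: float,
    direct: float,
    outcome_kind: Literal["linear", "logistic"],
    covariate_design: Sequence[float] | None = None,
    exposure_prob: float = 0.5,
    intercept: float | None = None,
    target_prevalence: float | None = 0.35,
    noise_sd: float = 1.0,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> OracleResult:
    """Expected proportion mediated for a single exposure→mediator→outcome
    chain with exposure→outcome effect ``direct``.

    For a linear outcome the closed form ``a·b / (a·b + direct)`` applies
    exactly.  For a logistic outcome the counterfactual decomposition on
    the risk-difference scale is computed by Monte-Carlo g-computation:
    mediator M(x) = a·x + σε, outcome probability
    expit(α + direct·x + b·m + offset), arms averaged with equal weight.
    ``covariate_design`` supplies an empirical sample of linear-predictor
    offsets (resampled with replacement); ``intercept`` fixes α directly,
    otherwise α is calibrated so the population event rate matches
    ``target_prevalence``.
    """
    if not all(np.isfinite([a, b, direct])):
        raise ValueError("effects must be finite")
    if outcome_kind == "linear":
        denom = a * b + direct
        if denom == 0.0:
            raise ZeroDivisionError(
                "proportion mediated undefined: a*b + direct == 0")
        prop = a * b / denom
        return OracleResult(a * b, direct, denom, prop, 0.0, 0)
    if outcome_kind != "logistic":
        raise ValueError(f"unknown outcome kind {outcome_kind!r}")

    rng = np.random.default_rng(seed)
    x = (rng.random(n_mc) < exposure_prob).astype(float)
    eps = rng.normal(0.0, noise_sd, n_mc)
    if covariate_design is not None:
        offs = np.asarray(covariate_design, dtype=float)
        offset = rng.choice(offs, size=n_mc, replace=True)
    else:
        offset = np.zeros(n_mc)

    m = {xa: a * xa + eps for xa in (0.0, 1.0)}

    def risk(x_out, x_med, alpha):
        return expit(alpha + direct * x_out + b * m[x_med] + offset)

    if intercept is None:
        if target_prevalence is None:
            raise ValueError("need intercept or target_prevalence")
        intercept = brentq(
            lambda al: np.mean(expit(al + direct * x + b * (a * x + eps)
                                     + offset)) - target_prevalence,
            -40.0, 40.0, xtol=1e-10)

    p = {(xo, xm): risk(xo, xm, intercept) for xo in (0.0, 1.0)
         for xm in (0.0, 1.0)}
    acme_i = 0.5 * ((p[1, 1] - p[1, 0]) + (p[0, 1] - p[0, 0]))
    ade_i = 0.5 * ((p[1, 1] - p[0, 1]) + (p[1, 0] - p[0, 0]))
    tot_i = p[1, 1] - p[0, 0]
    acme, ade, total = acme_i.mean(), ade_i.mean(), tot_i.mean()
    prop = acme / total
    # delta-method SE of the MC ratio estimate
    cov = np.cov(acme_i, tot_i) / n_mc
    grad = np.array([1.0 / total, -acme / total**2])
    se = float(np.sqrt(grad @ cov @ grad))
    return OracleResult(float(acme), float(ade), float(total), float(prop),
                        se, n_mc)
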