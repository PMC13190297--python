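"""Bidirectional causal mediation with nonparametric bootstrap CIs.

Each genotype-associated protein is tested in two directions anchored on
disease onset:

* upstream — genotype → protein → disease: the mediator model is linear
  (protein ~ exposure + covariates), the outcome model logistic
  (disease ~ exposure + protein + covariates).  The average causal
  mediation effect (ACME) and average direct effect (ADE) are computed on
  the risk-difference scale by plug-in g-computation over the empirical
  covariate distribution, integrating the mediator's residual normal error
  by Monte-Carlo, with the two exposure arms averaged with equal weight so
  ACME + ADE = total exactly on point estimates.
* downstream — genotype → disease → protein: the mediator model is
  logistic (disease ~ exposure + covariates), the outcome model linear
  (protein ~ exposure + disease + covariates); because the outcome model
  is linear in the mediator, ACME has the closed form
  (risk difference of disease w.r.t. exposure) × (disease coefficient),
  in protein-SD units.

With a continuous outcome both models are linear and the ACME reduces
exactly to the product of fitted coefficients.  Confidence intervals are
percentile bootstrap over subject resampling; no exposure–mediator
interaction is modelled.  The screen is gated by the causal-steps
requirement: only proteins with FDR-significant genotype association in
the marginal (type 1) model are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from ._utils import child_rng, child_seed
from .assoc import (_covariate_frame, _disease_indicator, bh_fdr,
                    get_contrast, make_contrast_groups)
from .containers import ProteinMatrix
from .preprocess import exclude_outlier_values

__all__ = ["MediationSpec", "MediationRecord", "mediate_pair",
           "MediationScreen", "run_mediation_screen"]


@dataclass
class MediationSpec:
    """Configuration of one analyte × direction mediation fit."""

    analyte_id: str
    direction: str = "upstream"          # 'upstream' | 'downstream'
    contrast: str = "e4"
    disease_variable: str = "dx"         # 'dx' | 'abeta' | 'abeta_ratio'
    covariates: list | None = None
    n_boot: int = 1000
    mc_draws: int = 200
    seed: int = 0
    outlier_sd: float = 5.0

    def __post_init__(self):
        if self.direction not in ("upstream", "downstream"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "downstream" and \
                self.disease_variable == "abeta_ratio":
            raise ValueError("downstream direction needs a binary mediator")


@dataclass
class MediationRecord:
    analyte_id: str
    direction: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple = (np.nan, np.nan)
    ade_ci: tuple = (np.nan, np.nan)
    total_ci: tuple = (np.nan, np.nan)
    prop_ci: tuple = (np.nan, np.nan)
    p_acme: float = np.nan
    n: int = 0
    n_boot: int = 0
    n_boot_ok: int = 0
    seed: int = 0
    flags: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "analyte_id": self.analyte_id, "direction": self.direction,
            "acme": self.acme, "ade": self.ade, "total": self.total,
            "prop_mediated": self.prop_mediated, "p_acme": self.p_acme,
            "n": self.n, "n_boot": self.n_boot, "n_boot_ok": self.n_boot_ok,
            "seed": self.seed,
        }
        for name, ci in (("acme", self.acme_ci), ("ade", self.ade_ci),
                         ("total", self.total_ci), ("prop", self.prop_ci)):
            row[f"{name}_lo"], row[f"{name}_hi"] = ci
        for flag in ("inconsistent_sign", "small_total_effect", "unstable"):
            row[flag] = bool(self.flags.get(flag, False))
        return row


class _ConvergenceError(RuntimeError):
    pass


def _logit_params(X: np.ndarray, y: np.ndarray, start=None) -> np.ndarray:
    """Newton–Raphson logistic fit for the bootstrap hot path.

    Orders of magnitude faster than building a model object per resample;
    step-halving guards against overshoot and diverging coefficients are
    treated as separation.  Agreement with the statsmodels MLE is checked
    in the test suite.
    """
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.array(start, dtype=float)
    eta = X @ beta
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    for _ in range(60):
        mu = expit(eta)
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise _ConvergenceError("singular hessian")
        # step-halving line search on the log-likelihood
        for _ in range(25):
            cand = beta + step
            eta_c = X @ cand
            ll_c = np.sum(y * eta_c - np.logaddexp(0.0, eta_c))
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        moved = np.max(np.abs(cand - beta))
        beta, eta, ll = cand, eta_c, ll_c
        if moved < 1e-9:
            if np.max(np.abs(beta)) > 100.0:
                raise _ConvergenceError("separation suspected")
            return beta
    raise _ConvergenceError("logit did not converge")


def _ols_params(X: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - rank, 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    return beta, sigma


def _upstream_points(Xm, y, Z, x, m, mc_z, warm=None):
    """Point estimates (acme, ade, total) for the upstream direction.

    Xm: [1, x, Z] mediator design;  outcome design is [1, x, m, Z].
    mc_z: shared standard-normal draws integrating the mediator error.

    Because the models carry no exposure–mediator interaction, the four
    counterfactual arms differ only by scalar shifts of one linear
    predictor grid: setting the exposure adds the direct coefficient, and
    setting the mediator arm adds (mediator coefficient × fitted
    exposure→mediator effect).  The grid is evaluated once (float32: the
    subsequent decomposition identity is exact in the returned float64
    means regardless of grid precision).
    """
    beta_m, sigma = _ols_params(Xm, m)
    a_hat = beta_m[1]
    Xy = np.column_stack([Xm[:, :2], m, Xm[:, 2:]])
    warm_y = _logit_params(Xy, y, start=warm)
    theta_x, b_m = warm_y[1], warm_y[2]
    # intercept + covariate part + mediator model prediction at exposure 0
    mu0 = Xm @ beta_m - a_hat * x
    base = Xy @ warm_y - theta_x * x - b_m * m + b_m * mu0
    grid = base.astype(np.float32)[:, None] \
        + (b_m * sigma) * mc_z.astype(np.float32)[None, :]

    def pbar(x_out, x_med):
        return float(expit(grid + np.float32(theta_x * x_out
                                             + b_m * a_hat * x_med)).mean(
            dtype=np.float64))

    p11, p10 = pbar(1.0, 1.0), pbar(1.0, 0.0)
    p01, p00 = pbar(0.0, 1.0), pbar(0.0, 0.0)
    acme = 0.5 * ((p11 - p10) + (p01 - p00))
    ade = 0.5 * ((p11 - p01) + (p10 - p00))
    total = p11 - p00
    return acme, ade, total, warm_y


def _upstream_linear_points(Xm, y, Z, x, m):
    """Both models linear (continuous outcome): ACME is exactly the
    product of the fitted exposure→mediator and mediator→outcome
    coefficients."""
    beta_m, _ = _ols_params(Xm, m)
    Xy = np.column_stack([Xm[:, :2], m, Xm[:, 2:]])
    beta_y, _ = _ols_params(Xy, y)
    acme = beta_m[1] * beta_y[2]
    ade = beta_y[1]
    return acme, ade, acme + ade, None


def _downstream_points(Xm, y_protein, Z, x, disease, warm=None):
    """Closed-form decomposition for the downstream direction."""
    warm_d = _logit_params(Xm, disease, start=warm)
    eta = Xm @ warm_d
    eta1 = eta + warm_d[1] * (1.0 - x)
    eta0 = eta - warm_d[1] * x
    rd = float(expit(eta1).mean() - expit(eta0).mean())
    Xy = np.column_stack([Xm[:, :2], disease, Xm[:, 2:]])
    beta_y, _ = _ols_params(Xy, y_protein)
    acme = rd * beta_y[2]
    ade = beta_y[1]
    return acme, ade, acme + ade, warm_d


def mediate_pair(matrix: ProteinMatrix, cohort: pd.DataFrame,
                 spec: MediationSpec) -> MediationRecord:
    """Fit one analyte in one mediation direction.

    Complete-case rows over exposure, mediator, outcome, and covariates;
    the protein is outlier-screened (>5 SD) and z-scored within the
    analysis sample.  See the module docstring for the estimator.
    """
    contrast = get_contrast(spec.contrast)
    x = make_contrast_groups(cohort, contrast)
    protein = matrix.values[spec.analyte_id].reindex(cohort.index)
    if spec.disease_variable == "abeta_ratio":
        disease = pd.to_numeric(cohort["abeta_ratio"]).rename("disease")
        binary_outcome = False
    else:
        disease = _disease_indicator(cohort, spec.disease_variable)
        binary_outcome = True
    Zf = _covariate_frame(cohort, matrix, spec.covariates)
    frame = pd.concat([x.rename("x"), protein.rename("m"),
                       disease, Zf], axis=1).dropna()
    _, excluded = exclude_outlier_values(frame["m"], spec.outlier_sd)
    frame = frame.drop(index=excluded)
    m = frame["m"]
    if m.std(ddof=1) == 0:
        raise ValueError(f"zero-variance mediator {spec.analyte_id!r}")
    frame["m"] = (m - m.mean()) / m.std(ddof=1)
    if not binary_outcome:
        d = frame["disease"]
        frame["disease"] = (d - d.mean()) / d.std(ddof=1)

    n = len(frame)
    xv = frame["x"].to_numpy()
    mv = frame["m"].to_numpy()
    dv = frame["disease"].to_numpy()
    Z = frame[list(Zf.columns)].to_numpy()
    Xm = np.column_stack([np.ones(n), xv, Z])

    rng = np.random.default_rng(spec.seed)
    mc_z = rng.standard_normal(spec.mc_draws)

    if spec.direction == "upstream":
        if binary_outcome:
            def points(Xm_, y_, Z_, x_, m_, warm):
                return _upstream_points(Xm_, y_, Z_, x_, m_, mc_z, warm)
            yv, med = dv, mv
        else:
            def points(Xm_, y_, Z_, x_, m_, warm):
                return _upstream_linear_points(Xm_, y_, Z_, x_, m_)
            yv, med = dv, mv
    else:
        def points(Xm_, y_, Z_, x_, m_, warm):
            return _downstream_points(Xm_, y_, Z_, x_, m_, warm)
        yv, med = mv, dv    # outcome is the protein, mediator the disease

    flags: dict = {}
    try:
        acme, ade, total, warm = points(Xm, yv, Z, xv, med, None)
    except _ConvergenceError:
        return MediationRecord(spec.analyte_id, spec.direction, np.nan,
                               np.nan, np.nan, np.nan, n=n,
                               seed=spec.seed, flags={"unstable": True})
    prop = acme / total if total != 0 else np.nan

    rec = MediationRecord(spec.analyte_id, spec.direction, acme, ade, total,
                          prop, n=n, n_boot=spec.n_boot, seed=spec.seed)
    if spec.n_boot <= 0:
        rec.flags = flags
        return rec

    boots = np.full((spec.n_boot, 3), np.nan)
    n_bad = 0
    for bidx in range(spec.n_boot):
        idx = rng.integers(0, n, n)
        try:
            a_b, d_b, t_b, _ = points(Xm[idx], yv[idx], Z[idx], xv[idx],
                                      med[idx], warm)
            boots[bidx] = (a_b, d_b, t_b)
        except _ConvergenceError:
            n_bad += 1
    ok = ~np.isnan(boots[:, 0])
    rec.n_boot_ok = int(ok.sum())
    if rec.n_boot_ok < max(20, spec.n_boot // 2):
        flags["unstable"] = True
        rec.flags = flags
        return rec

    ac, de, tot = boots[ok, 0], boots[ok, 1], boots[ok, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        pr = ac / tot
    rec.acme_ci = tuple(np.percentile(ac, [2.5, 97.5]))
    rec.ade_ci = tuple(np.percentile(de, [2.5, 97.5]))
    rec.total_ci = tuple(np.percentile(tot, [2.5, 97.5]))
    n_ok = len(ac)
    rec.p_acme = min(1.0, 2.0 * (min((ac <= 0).sum(), (ac >= 0).sum()) + 1)
                     / (n_ok + 1))
    flags["inconsistent_sign"] = bool(np.sign(tot).std() > 0 and
                                      (np.sign(tot) != np.sign(total)).any())
    se_total = tot.std(ddof=1)
    if abs(total) < 0.5 * se_total:
        flags["small_total_effect"] = True
        rec.prop_ci = (np.nan, np.nan)
    else:
        finite = pr[np.isfinite(pr)]
        if len(finite):
            rec.prop_ci = tuple(np.percentile(finite, [2.5, 97.5]))
    rec.flags = flags
    return rec


class MediationScreen(BaseEstimator):
    """Run the gated bidirectional mediation screen.

    ``fit(matrix, cohort, gate)`` takes a type-1 association table (the
    causal-steps gate): only analytes with ``q < alpha_gate`` for the APOE
    term are tested, in the requested directions, each with a sub-seed
    derived from ``seed`` and the analyte id so reruns are deterministic
    and analytes independent.  ``results_`` holds one row per analyte ×
    direction with BH-adjusted ``q_acme`` within each direction.
    """

    def __init__(self, contrast: str = "e4", disease_variable: str = "dx",
                 directions=("upstream", "downstream"), n_boot: int = 1000,
                 mc_draws: int = 200, seed: int = 0,
                 alpha_gate: float = 0.05, covariates=None):
        self.contrast = contrast
        self.disease_variable = disease_variable
        self.directions = directions
        self.n_boot = n_boot
        self.mc_draws = mc_draws
        self.seed = seed
        self.alpha_gate = alpha_gate
        self.covariates = covariates

    def fit(self, matrix: ProteinMatrix, cohort: pd.DataFrame,
            gate: pd.DataFrame):
        apoe_rows = gate[gate["term"] == "apoe"]
        tested = sorted(apoe_rows.loc[apoe_rows["q"] < self.alpha_gate,
                                      "analyte_id"].unique())
        rows = []
        for direction in self.directions:
            for analyte in tested:
                spec = MediationSpec(
                    analyte_id=analyte, direction=direction,
                    contrast=self.contrast,
                    disease_variable=self.disease_variable,
                    covariates=self.covariates, n_boot=self.n_boot,
                    mc_draws=self.mc_draws,
                    seed=child_seed(self.seed, direction, analyte))
                rows.append(mediate_pair(matrix, cohort, spec).to_row())
        res = pd.DataFrame(rows)
        if len(res):
            for direction in self.directions:
                sel = res["direction"] == direction
                res.loc[sel, "q_acme"] = bh_fdr(res.loc[sel, "p_acme"])
        else:
            res = pd.DataFrame(columns=[
                "analyte_id", "direction", "acme", "ade", "total",
                "prop_mediated", "p_acme", "q_acme", "n", "n_boot",
                "n_boot_ok", "seed", "acme_lo", "acme_hi", "ade_lo",
                "ade_hi", "total_lo", "total_hi", "prop_lo", "prop_hi",
                "inconsistent_sign", "small_total_effect", "unstable"])
        self.results_ = res
        self.tested_ = tested
        return self


def run_mediation_screen(gate: pd.DataFrame, matrix: ProteinMatrix,
                         cohort: pd.DataFrame, **params) -> pd.DataFrame:
    """Functional wrapper over :class:`MediationScreen`."""
    screen = MediationScreen(**params)
    screen.fit(matrix, cohort, gate)
    return screen.results_
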