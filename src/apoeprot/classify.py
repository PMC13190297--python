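"""Mechanistic classification of genotype-associated proteins, and a
linear-discriminant check of category separability.

Each analyte receives exactly one label from the marginal genotype
association (type 1), the disease association (type 2), and the two
mediation records:

1. exactly one mediation direction FDR-significant → that direction's
   category (upstream → ``mediator``, downstream → ``pathology_mediated``);
2. both significant → the direction with larger \\|proportion mediated\\|
   wins, ties go upstream (genotype is fixed at birth, hence temporally
   prior);
3. genotype-significant but disease-non-significant → ``genotype_specific``;
4. genotype- and disease-significant without mediation → ``nonspecific``;
5. disease-significant only → ``disease_specific``;
6. otherwise ``unassigned``.

Mediation categories also carry a completeness flag: ``complete`` when the
ACME is significant and the direct-effect CI covers zero in the dominant
direction, ``partial`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

__all__ = ["ProteinClass", "assign_class", "classify_proteins",
           "ProteinClassifier", "LDAResult", "lda_separability", "ClassLDA"]

LABELS = ("mediator", "pathology_mediated", "genotype_specific",
          "nonspecific", "disease_specific", "unassigned")


@dataclass
class ProteinClass:
    analyte_id: str
    label: str
    mediation_completeness: str   # 'complete' | 'partial' | 'na'
    dominance_margin: float       # |prop_up| - |prop_down|


def _get(rec, key):
    return rec.get(key) if isinstance(rec, dict) else rec[key]


def assign_class(assoc_m1: dict | pd.Series, assoc_m2: dict | pd.Series,
                 med_up: dict | pd.Series | None,
                 med_down: dict | pd.Series | None,
                 alpha_q: float = 0.05) -> ProteinClass:
    """Classify one analyte.

    ``assoc_m1`` / ``assoc_m2`` need ``analyte_id`` and ``q``;
    ``med_up`` / ``med_down`` (present only for gate-passing analytes)
    need ``q_acme``, ``prop_mediated``, ``ade_lo``, ``ade_hi``.
    """
    if assoc_m1 is None or assoc_m2 is None:
        raise ValueError("missing association record")
    analyte = assoc_m1["analyte_id"]
    q_geno = _get(assoc_m1, "q")
    q_dis = _get(assoc_m2, "q")

    def sig(q):
        return q is not None and np.isfinite(q) and q < alpha_q

    def med_sig(rec):
        return rec is not None and sig(_get(rec, "q_acme"))

    def prop(rec):
        v = _get(rec, "prop_mediated")
        return abs(v) if v is not None and np.isfinite(v) else 0.0

    up_sig, down_sig = med_sig(med_up), med_sig(med_down)
    margin = (prop(med_up) if med_up is not None else 0.0) - \
             (prop(med_down) if med_down is not None else 0.0)

    label, dominant = None, None
    if up_sig and not down_sig:
        label, dominant = "mediator", med_up
    elif down_sig and not up_sig:
        label, dominant = "pathology_mediated", med_down
    elif up_sig and down_sig:
        # dominant direction by |proportion mediated|; tie favors upstream
        if prop(med_up) >= prop(med_down):
            label, dominant = "mediator", med_up
        else:
            label, dominant = "pathology_mediated", med_down
    elif sig(q_geno) and not sig(q_dis):
        label = "genotype_specific"
    elif sig(q_geno) and sig(q_dis):
        label = "nonspecific"
    elif sig(q_dis):
        label = "disease_specific"
    else:
        label = "unassigned"

    completeness = "na"
    if dominant is not None:
        lo = _get(dominant, "ade_lo")
        hi = _get(dominant, "ade_hi")
        covers0 = (lo is not None and hi is not None
                   and np.isfinite(lo) and np.isfinite(hi)
                   and lo <= 0.0 <= hi)
        completeness = "complete" if covers0 else "partial"
    return ProteinClass(analyte, label, completeness, margin)


def classify_proteins(assoc_m1: pd.DataFrame, assoc_m2: pd.DataFrame,
                      mediation: pd.DataFrame,
                      alpha_q: float = 0.05) -> pd.DataFrame:
    """Classify every analyte appearing in the type-1 table.

    ``mediation`` is the long screen table (one row per analyte ×
    direction).  Classification is a pure function of its inputs: analyte
    order never changes any label.
    """
    m1 = assoc_m1[assoc_m1["term"] == "apoe"].set_index("analyte_id")
    m2 = assoc_m2[assoc_m2["term"] == "disease"].set_index("analyte_id")
    med = {}
    if len(mediation):
        for (analyte, direction), grp in mediation.groupby(
                ["analyte_id", "direction"]):
            med[(analyte, direction)] = grp.iloc[0]
    rows = []
    for analyte in m1.index:
        if analyte not in m2.index:
            raise ValueError(f"no disease association record for {analyte!r}")
        r1 = m1.loc[analyte].to_dict() | {"analyte_id": analyte}
        r2 = m2.loc[analyte].to_dict() | {"analyte_id": analyte}
        up = med.get((analyte, "upstream"))
        down = med.get((analyte, "downstream"))
        pc = assign_class(r1, r2, up, down, alpha_q)
        rows.append({"analyte_id": pc.analyte_id, "label": pc.label,
                     "mediation_completeness": pc.mediation_completeness,
                     "dominance_margin": pc.dominance_margin})
    return pd.DataFrame(rows).set_index("analyte_id")


class ProteinClassifier(BaseEstimator):
    """Estimator wrapper over :func:`classify_proteins`.

    ``fit(assoc_m1, assoc_m2, mediation)`` stores ``labels_`` (a
    DataFrame indexed by analyte id)."""

    def __init__(self, alpha_q: float = 0.05):
        self.alpha_q = alpha_q

    def fit(self, assoc_m1, assoc_m2, mediation):
        self.labels_ = classify_proteins(assoc_m1, assoc_m2, mediation,
                                         self.alpha_q)
        return self


# --------------------------------------------------------------------------
# linear discriminant separability

@dataclass
class LDAResult:
    projections: pd.DataFrame      # all analytes × discriminant axes
    loadings: np.ndarray           # original feature dims × axes
    trace_ratio: float             # between/within scatter in the projection
    eigenvalues: np.ndarray
    ridge_used: bool
    n_components_pca: int


def lda_separability(features: pd.DataFrame, labels: pd.Series,
                     n_axes: int = 2, var_explained: float = 0.95,
                     ridge: float = 1e-6) -> LDAResult:
    """Fisher discriminant axes over analyte feature vectors.

    ``features``: analytes × feature dimensions (e.g. per-subject protein
    residuals, so the feature dimension is the number of subjects);
    ``labels``: class labels for the labelled subset.  With far more
    features than labelled analytes the within-class scatter is singular,
    so the feature space is first compressed to the leading principal axes
    explaining ``var_explained`` of the labelled variance (capped at
    n_labelled − n_classes), and the generalized eigenproblem
    Sb·w = λ·Sw·w is solved there.  A singular within scatter after
    compression falls back to a ridge (``ridge`` × mean diagonal), flagged
    in the result.  Every analyte, labelled or not, is projected; the
    separation statistic is trace(WᵀSbW)/trace(WᵀSwW).
    """
    labels = labels.dropna()
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members")
    Xl = features.loc[labels.index].to_numpy(dtype=float)
    n_lab = len(labels)
    max_comp = max(1, min(n_lab - len(classes), features.shape[1],
                          n_lab - 1))
    pca = PCA(n_components=max_comp, svd_solver="full")
    scores = pca.fit_transform(Xl)
    if var_explained >= 1.0:
        n_comp = max_comp
    else:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_comp = min(int(np.searchsorted(cum, var_explained) + 1), max_comp)
    scores = scores[:, :n_comp]

    overall = scores.mean(axis=0)
    Sw = np.zeros((n_comp, n_comp))
    Sb = np.zeros((n_comp, n_comp))
    for cls in classes:
        sub = scores[(labels == cls).to_numpy()]
        mu = sub.mean(axis=0)
        dev = sub - mu
        Sw += dev.T @ dev
        Sb += len(sub) * np.outer(mu - overall, mu - overall)

    ridge_used = False
    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError:
        ridge_used = True
        Sw = Sw + ridge * np.trace(Sw) / n_comp * np.eye(n_comp)
        evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    n_axes = min(n_axes, len(classes) - 1, n_comp)
    W = evecs[:, order[:n_axes]]
    evals = evals[order[:n_axes]]

    all_scores = pca.transform(features.to_numpy(dtype=float))[:, :n_comp]
    proj = all_scores @ W
    tr_b = float(np.trace(W.T @ Sb @ W))
    tr_w = float(np.trace(W.T @ Sw @ W))
    loadings = pca.components_[:n_comp].T @ W
    cols = [f"LD{i + 1}" for i in range(n_axes)]
    return LDAResult(pd.DataFrame(proj, index=features.index, columns=cols),
                     loadings, tr_b / tr_w, evals, ridge_used, n_comp)


class ClassLDA(BaseEstimator):
    """Estimator wrapper over :func:`lda_separability` with a sklearn-like
    fit/transform surface."""

    def __init__(self, n_axes: int = 2, var_explained: float = 0.95,
                 ridge: float = 1e-6):
        self.n_axes = n_axes
        self.var_explained = var_explained
        self.ridge = ridge

    def fit(self, features: pd.DataFrame, labels: pd.Series):
        self.result_ = lda_separability(features, labels, self.n_axes,
                                        self.var_explained, self.ridge)
        self.trace_ratio_ = self.result_.trace_ratio
        return self

    def transform(self, features: pd.DataFrame = None) -> pd.DataFrame:
        return self.result_.projections
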