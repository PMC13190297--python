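"""Size-matched permutation cell-type enrichment.

For a gene set and a gene × cell-type mean-expression reference, the
observed statistic per cell type is the mean expression of the set's
genes.  The null distribution is the same statistic over random gene sets
of identical size drawn without replacement from the assayed background;
the one-sided upper-tail p is (#null ≥ observed + 1)/(n_perm + 1), with
Benjamini–Hochberg adjustment across cell types per set.  Small
backgrounds can be enumerated exactly instead of sampled.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .assoc import bh_fdr

__all__ = ["ExpressionReference", "celltype_permutation_enrichment",
           "CellTypeEnrichment", "collapse_to_genes"]


@dataclass
class ExpressionReference:
    """Gene × cell-type mean expression with an assayed-gene background."""

    expression: pd.DataFrame           # genes × cell types, non-negative
    background: list[str] | None = None

    def __post_init__(self):
        if (self.expression < 0).any().any():
            raise ValueError("expression must be non-negative")
        if self.background is None:
            self.background = list(self.expression.index)
        missing = set(self.background) - set(self.expression.index)
        if missing:
            raise ValueError(
                f"{len(missing)} background genes missing from the "
                f"reference (e.g. {sorted(missing)[:3]})")


def collapse_to_genes(analytes: pd.DataFrame, analyte_ids) -> list[str]:
    """Map analyte ids to unique gene symbols, keeping the first analyte
    per gene (multi-aptamer targets collapse to one gene)."""
    genes = analytes.loc[list(analyte_ids), "gene"]
    dropped = genes.duplicated()
    if dropped.any():
        warnings.warn(f"collapsed {int(dropped.sum())} duplicate-gene "
                      "analytes (first occurrence kept)")
    return list(genes[~dropped])


def celltype_permutation_enrichment(
    gene_set,
    reference: ExpressionReference,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "sampled",
    exact_limit: int = 200_000,
    gene_set_id: str = "set",
) -> pd.DataFrame:
    """Permutation enrichment of one gene set across all cell types.

    Returns a DataFrame with one row per cell type: observed mean, null
    mean/SD, one-sided upper-tail ``p_perm``, BH ``q`` across cell types,
    and the mode used.  Genes absent from the reference are dropped with a
    warning; an empty set or a set larger than the background is an error.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    expr = reference.expression
    bg = [g for g in reference.background]
    present = [g for g in gene_set if g in expr.index]
    absent = set(gene_set) - set(present)
    if absent:
        warnings.warn(f"{len(absent)} gene(s) absent from the reference "
                      f"dropped: {sorted(absent)[:5]}")
    outside = set(present) - set(bg)
    if outside:
        raise ValueError(f"genes outside the background: {sorted(outside)[:5]}")
    k = len(present)
    nbg = len(bg)
    if k == 0:
        raise ValueError("no gene of the set is in the reference")
    if k > nbg:
        raise ValueError(f"set size {k} exceeds background size {nbg}")

    bg_vals = expr.loc[bg].to_numpy(dtype=float)        # nbg × n_celltypes
    obs = expr.loc[present].mean(axis=0).to_numpy()
    cell_types = list(expr.columns)

    if mode == "exact":
        total = math.comb(nbg, k)
        if total > exact_limit:
            raise ValueError(f"{total} subsets exceed exact_limit="
                             f"{exact_limit}; use sampled mode")
        null = np.empty((total, len(cell_types)))
        for i, combo in enumerate(itertools.combinations(range(nbg), k)):
            null[i] = bg_vals[list(combo)].mean(axis=0)
        p = (null >= obs - 1e-12).sum(axis=0) / total
        n_used = total
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        null = np.empty((n_perm, len(cell_types)))
        chunk = max(1, min(n_perm, 64_000_000 // (k * len(cell_types) * 8)))
        row = 0
        while row < n_perm:
            size = min(chunk, n_perm - row)
            idx = np.array([rng.choice(nbg, k, replace=False)
                            for _ in range(size)])
            null[row:row + size] = bg_vals[idx].mean(axis=1)
            row += size
        p = ((null >= obs - 1e-12).sum(axis=0) + 1) / (n_perm + 1)
        n_used = n_perm
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = pd.DataFrame({
        "gene_set_id": gene_set_id,
        "cell_type": cell_types,
        "observed_mean": obs,
        "null_mean": null.mean(axis=0),
        "null_sd": null.std(axis=0, ddof=1),
        "p_perm": p,
        "n_perm": n_used,
        "seed": seed,
        "mode": mode,
    })
    out["q"] = bh_fdr(out["p_perm"])
    return out


class CellTypeEnrichment(BaseEstimator):
    """Estimator over :func:`celltype_permutation_enrichment` for a
    collection of gene sets; ``fit(gene_sets, reference)`` with
    ``gene_sets`` a mapping set-id → gene list stores the concatenated
    ``results_`` table (one sub-seed per set)."""

    def __init__(self, n_perm: int = 10_000, mode: str = "sampled",
                 seed: int = 0, exact_limit: int = 200_000):
        self.n_perm = n_perm
        self.mode = mode
        self.seed = seed
        self.exact_limit = exact_limit

    def fit(self, gene_sets: dict, reference: ExpressionReference):
        from ._utils import child_seed
        tables = []
        for set_id, genes in gene_sets.items():
            tables.append(celltype_permutation_enrichment(
                genes, reference, n_perm=self.n_perm,
                seed=child_seed(self.seed, "enrich", set_id),
                mode=self.mode, exact_limit=self.exact_limit,
                gene_set_id=set_id))
        self.results_ = pd.concat(tables, ignore_index=True) if tables \
            else pd.DataFrame()
        return self
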