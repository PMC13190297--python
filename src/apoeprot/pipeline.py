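"""End-to-end deterministic pipeline over a synthetic cohort.

``run_pipeline`` chains simulate → QC → association (model types 1–3) →
bidirectional mediation screen → classification → cell-type enrichment,
writing every stage as tab-separated text.  All randomness derives from
the master seed, so two runs with the same configuration produce
byte-identical output trees.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ._utils import child_rng, child_seed
from .assoc import run_assoc
from .classify import classify_proteins
from .containers import ProteinMatrix, write_cohort
from .enrich import CellTypeEnrichment, ExpressionReference, collapse_to_genes
from .mediate import run_mediation_screen
from .preprocess import ProteinQC, compute_mean_abundance
from .simulate import SimConfig, simulate_cohort

__all__ = ["run_pipeline", "synthetic_reference"]

_FLOAT_FMT = "%.10g"


def synthetic_reference(matrix: ProteinMatrix, seed: int,
                        n_cell_types: int = 5,
                        enriched_genes=None) -> ExpressionReference:
    """A small synthetic gene × cell-type mean-expression reference over
    the matrix's genes (labelled synthetic; it stands in for a single-cell
    atlas average-expression table).  ``enriched_genes`` get elevated
    expression in the first cell type."""
    rng = child_rng(seed, "reference")
    genes = list(dict.fromkeys(matrix.analytes["gene"]))
    expr = rng.gamma(2.0, 1.0, (len(genes), n_cell_types))
    ref = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                       columns=[f"celltype{i}" for i in range(n_cell_types)])
    if enriched_genes:
        ref.loc[[g for g in enriched_genes if g in ref.index],
                "celltype0"] += 3.0
    return ExpressionReference(ref)


def run_pipeline(config: SimConfig, out_dir: str | Path,
                 contrast: str = "e4", disease_variable: str = "dx",
                 n_boot: int = 200, n_perm: int = 2000) -> dict:
    """Run the full analysis on one simulated cohort and write TSVs.

    Returns a dict of the in-memory stage outputs.  The bootstrap and
    permutation sizes default below the production values (1,000 and
    10,000) so a desk run finishes quickly; both are parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed

    sim = simulate_cohort(config)
    cohort, matrix, truth = sim.cohort, sim.matrix, sim.truth
    write_cohort(cohort, out / "cohort.tsv")
    matrix.write(out)
    truth.to_csv(out / "truth.tsv", sep="\t", float_format=_FLOAT_FMT)
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")

    qc = ProteinQC()
    filtered = qc.fit_transform(matrix)
    cohort_f = cohort.loc[filtered.values.index]
    (out / "qc_report.json").write_text(
        json.dumps(qc.report_.to_dict(), indent=2, sort_keys=True) + "\n")
    compute_mean_abundance(filtered).to_csv(
        out / "mean_abundance.tsv", sep="\t", float_format=_FLOAT_FMT)

    assoc = {}
    for model_type in (1, 2, 3):
        tbl = run_assoc(filtered, cohort_f, contrast=contrast,
                        model_type=model_type,
                        disease_variable=disease_variable, strata=("all",))
        tbl.to_csv(out / f"assoc_model{model_type}.tsv", sep="\t",
                   index=False, float_format=_FLOAT_FMT)
        assoc[model_type] = tbl

    mediation = run_mediation_screen(
        assoc[1], filtered, cohort_f, contrast=contrast,
        disease_variable=disease_variable, n_boot=n_boot,
        seed=child_seed(seed, "mediation"))
    mediation.to_csv(out / "mediation.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)

    classes = classify_proteins(assoc[1], assoc[2], mediation)
    classes.to_csv(out / "classes.tsv", sep="\t", float_format=_FLOAT_FMT)

    mediator_genes = collapse_to_genes(
        filtered.analytes, classes.index[classes["label"] == "mediator"]) \
        if (classes["label"] == "mediator").any() else []
    reference = synthetic_reference(filtered, seed,
                                    enriched_genes=mediator_genes)
    gene_sets = {}
    for label in ("mediator", "pathology_mediated"):
        ids = classes.index[classes["label"] == label]
        if len(ids) >= 2:
            gene_sets[label] = collapse_to_genes(filtered.analytes, ids)
    enrichment = pd.DataFrame()
    if gene_sets:
        enr = CellTypeEnrichment(n_perm=n_perm,
                                 seed=child_seed(seed, "enrichment"))
        enr.fit(gene_sets, reference)
        enrichment = enr.results_
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)

    return {"cohort": cohort, "matrix": matrix, "truth": truth,
            "filtered": filtered, "assoc": assoc, "mediation": mediation,
            "classes": classes, "enrichment": enrichment}
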