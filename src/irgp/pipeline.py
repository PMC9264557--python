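"""End-to-end pipeline: load inputs, fit the model, write every stage.

Outputs are tab-separated text files in the configured output directory,
plus a machine-readable ``run_log.json`` recording the seed, thresholds
and the count at each stage.  Given the same config and seed the stage
files are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import io as irgpio
from .datatypes import PipelineConfig, ValidationError
from .maf import read_maf, restrict_to_genes, signature_genes, summarize
from .model import IRGPRiskModel, IRGPRiskResults

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
              index_label=index_label)


def run_pipeline(config: PipelineConfig) -> IRGPRiskResults:
    """Run every stage and write the intermediates as TSV files.

    Any stage failure aborts with the stage name and cause.  Returns the
    fitted results object.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        em = irgpio.load_expression(config.expression_path, config.groups_path)
        clinical = irgpio.load_clinical(config.clinical_path)
        immune = irgpio.load_gene_list(config.immune_genes_path,
                                       provenance="immune")
        model = IRGPRiskModel(
            em, clinical, immune, lfc_min=config.lfc_min, p_max=config.p_max,
            prevalence=(config.prevalence_lo, config.prevalence_hi),
            univariate_alpha=config.univariate_alpha,
            cv_folds=config.cv_folds, n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
            horizon=config.roc_horizon, split_ratio=config.split_ratio,
            normalize=config.normalize, pseudocount=config.pseudocount)
        stage = "model fit"
        res = model.fit(seed=config.seed)

        stage = "write outputs"
        _write(res.de_table, outdir / "de_table.tsv", "gene")
        irgpio.write_gene_list(res.degs, outdir / "degs.txt")
        irgpio.write_gene_list(res.immune_degs, outdir / "immune_degs.txt")
        _write(res.pair_matrix.to_frame(), outdir / "pair_indicators.tsv",
               "pair")
        _write(res.screen_table, outdir / "univariate_screen.tsv", "pair")
        _write(res.cv.cv_table, outdir / "lasso_cv.tsv", "index")
        irgpio.write_signature(res.signature, outdir / "signature.tsv")
        risk_rows = []
        for cohort, scores, cmp_ in (("train", res.scores_train,
                                      res.train_comparison),
                                     ("test", res.scores_test,
                                      res.test_comparison)):
            g = cmp_.assignment.table
            for s in scores.index:
                risk_rows.append((s, cohort, scores[s], g.loc[s, "group"]))
        pd.DataFrame(risk_rows, columns=["sample_id", "cohort", "score",
                                         "group"]).to_csv(
            outdir / "risk_assignments.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        roc_df = pd.DataFrame({"threshold": res.roc.thresholds,
                               "sensitivity": res.roc.sensitivity,
                               "specificity": res.roc.specificity})
        roc_df.to_csv(outdir / "roc.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
        _write(res.independence.univariate, outdir / "cox_univariate.tsv",
               "variable")
        _write(res.independence.multivariate, outdir / "cox_multivariate.tsv",
               "variable")

        maf_summary = None
        if config.maf_path:
            stage = "mutation summary"
            records = read_maf(config.maf_path)
            high = res.train_comparison.assignment.high \
                + res.test_comparison.assignment.high
            records = [r for r in records if r.sample in set(high)]
            records = restrict_to_genes(records,
                                        signature_genes(res.signature))
            maf_summary = summarize(records)
            write_maf_summary(maf_summary, outdir)

        stage = "run log"
        log = {
            "seed": config.seed,
            "config": {k: v for k, v in dataclasses.asdict(config).items()},
            "stage_counts": res.stage_counts,
            "selected_lambda": res.cv.lambda_,
            "cutoff": res.cutoff,
            "train_auc_1yr": res.roc.auc,
            "logrank_p": {"train": res.train_comparison.p_value,
                          "test": res.test_comparison.p_value},
            "death_fraction": {"train": res.train_comparison.death_fraction,
                               "test": res.test_comparison.death_fraction},
            "notes": ["differential expression uses a Welch t-test on "
                      "log2-CPM values (no negative-binomial dispersion "
                      "modeling)",
                      "raw p-values at the DEG stage (no FDR adjustment)"],
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
        (outdir / "summary.txt").write_text(res.summary() + "\n")
    except ValidationError as exc:
        raise ValidationError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return res


def write_maf_summary(summary, outdir: str | Path) -> None:
    """Write the mutation summary as a set of small TSV tables."""
    outdir = Path(outdir)
    pd.Series(summary.classification_counts, name="count").sort_index().to_csv(
        outdir / "maf_classification.tsv", sep="\t",
        index_label="classification")
    pd.Series(summary.type_counts, name="count").sort_index().to_csv(
        outdir / "maf_variant_type.tsv", sep="\t", index_label="variant_type")
    pd.Series(summary.snv_class_counts, name="count").to_csv(
        outdir / "maf_snv_class.tsv", sep="\t", index_label="snv_class")
    pd.Series(summary.per_sample_counts, name="n_mutations").sort_index().to_csv(
        outdir / "maf_per_sample.tsv", sep="\t", index_label="sample_id")
    summary.top.to_csv(outdir / "maf_genes.tsv", sep="\t")
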