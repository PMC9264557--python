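"""End-to-end model fit, pipeline determinism, CLI smoke tests."""

import json
import warnings
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from irgp import IRGPRiskModel, SimulationConfig, run_pipeline
from irgp.cli import main as cli_main
from irgp.datatypes import PipelineConfig, ValidationError
from irgp.io import write_clinical, write_expression, write_gene_list
from irgp.maf import write_maf
from irgp.simulate import immune_gene_set, simulate_cohort


@pytest.fixture(scope="module")
def fitted(tmp_path_factory):
    from irgp.simulate import default_planted_pairs
    base = SimulationConfig(n_tumor=300, n_normal=24, n_genes=120,
                            immune_fraction=0.5, n_de_genes=12, seed=11)
    cfg = SimulationConfig(n_tumor=300, n_normal=24, n_genes=120,
                           immune_fraction=0.5, n_de_genes=12, seed=11,
                           planted_pairs=default_planted_pairs(base, 3,
                                                               beta=1.2))
    em, clinical, truth, maf = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = IRGPRiskModel(em, clinical, immune_gene_set(cfg),
                            cv_folds=5, n_lambda=50).fit(seed=11)
    return cfg, truth, res


class TestModelFit:
    def test_signature_contains_planted_pairs_with_correct_signs(self, fitted):
        cfg, truth, res = fitted
        coef = dict(zip(res.signature.pairs, res.signature.coefficients))
        hits = sum(1 for gi, gj, b in truth.planted_pairs
                   if (gi, gj) in coef
                   and np.sign(coef[(gi, gj)]) == np.sign(b))
        assert hits >= 2  # at least 2 of 3 planted pairs, right signs

    def test_high_risk_group_has_worse_survival(self, fitted):
        _, _, res = fitted
        tr = res.train_comparison
        assert tr.death_fraction["high"] > tr.death_fraction["low"]
        assert tr.p_value < 0.05

    def test_stage_counts_are_consistent(self, fitted):
        _, _, res = fitted
        c = res.stage_counts
        assert c["immune_degs"] <= c["degs"] <= c["genes_tested"]
        assert c["pairs_after_prevalence"] <= c["candidate_pairs"]
        assert c["signature_pairs"] <= c["pairs_after_screen"]
        assert c["train_samples"] + c["test_samples"] == 300

    def test_summary_mentions_key_quantities(self, fitted):
        _, _, res = fitted
        text = res.summary()
        assert "Signature" in text and "log-rank" in text
        assert f"signature size: {len(res.signature)}" in text


def _write_cohort(outdir: Path, seed=11):
    from irgp.simulate import default_planted_pairs
    base = SimulationConfig(n_tumor=140, n_normal=16, n_genes=90,
                            immune_fraction=0.5, n_de_genes=10, seed=seed)
    cfg = SimulationConfig(n_tumor=140, n_normal=16, n_genes=90,
                           immune_fraction=0.5, n_de_genes=10, seed=seed,
                           planted_pairs=default_planted_pairs(base, 3,
                                                               beta=1.3))
    em, clinical, truth, maf = simulate_cohort(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(em, outdir / "expr.tsv", outdir / "groups.tsv")
    write_clinical(clinical, outdir / "clinical.tsv")
    write_gene_list(immune_gene_set(cfg), outdir / "immune.txt")
    write_maf(maf, outdir / "muts.maf")
    return cfg


def _config(indir: Path, outdir: Path, seed=11):
    return PipelineConfig(
        expression_path=str(indir / "expr.tsv"),
        groups_path=str(indir / "groups.tsv"),
        clinical_path=str(indir / "clinical.tsv"),
        immune_genes_path=str(indir / "immune.txt"),
        maf_path=str(indir / "muts.maf"),
        outdir=str(outdir), seed=seed, cv_folds=5, n_lambda=40)


class TestPipeline:
    def test_all_stage_files_emitted(self, tmp_path):
        _write_cohort(tmp_path / "in")
        cfg = _config(tmp_path / "in", tmp_path / "out")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(cfg)
        for name in ["de_table.tsv", "degs.txt", "immune_degs.txt",
                     "pair_indicators.tsv", "univariate_screen.tsv",
                     "lasso_cv.tsv", "signature.tsv",
                     "risk_assignments.tsv", "roc.tsv",
                     "cox_univariate.tsv", "cox_multivariate.tsv",
                     "maf_classification.tsv", "run_log.json",
                     "summary.txt"]:
            assert (tmp_path / "out" / name).exists(), name
        log = json.loads((tmp_path / "out" / "run_log.json").read_text())
        assert log["seed"] == 11
        assert log["stage_counts"]["signature_pairs"] >= 1

    def test_reruns_are_byte_identical(self, tmp_path):
        _write_cohort(tmp_path / "in")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(_config(tmp_path / "in", tmp_path / "a"))
            run_pipeline(_config(tmp_path / "in", tmp_path / "b"))
        for f in sorted((tmp_path / "a").iterdir()):
            if f.name == "run_log.json":
                # embeds the (differing) output paths; compare modulo config
                a = json.loads(f.read_text())
                b = json.loads((tmp_path / "b" / f.name).read_text())
                a.pop("config"), b.pop("config")
                assert a == b
                continue
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), \
                f.name

    def test_invalid_folds_rejected_before_compute(self, tmp_path):
        with pytest.raises(ValidationError):
            PipelineConfig("e", "c", "i", str(tmp_path), cv_folds=1)


class TestCLI:
    def test_simulate_then_mafsum(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate", "--outdir",
                                     str(tmp_path / "sim"), "--seed", "3",
                                     "--n-tumor", "60", "--n-normal", "10",
                                     "--n-genes", "60"])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "sim" / "expression.tsv").exists()
        r = runner.invoke(cli_main, ["mafsum", "--maf",
                                     str(tmp_path / "sim" / "mutations.maf"),
                                     "--outdir", str(tmp_path / "ms")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "ms" / "maf_snv_class.tsv").exists()

    def test_run_all_from_json_config(self, tmp_path):
        _write_cohort(tmp_path / "in")
        cfg = _config(tmp_path / "in", tmp_path / "out")
        import dataclasses
        (tmp_path / "cfg.json").write_text(
            json.dumps(dataclasses.asdict(cfg)))
        runner = CliRunner()
        r = runner.invoke(cli_main, ["run-all", "--config",
                                     str(tmp_path / "cfg.json")])
        assert r.exit_code == 0, r.output
        assert "Signature" in r.output
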