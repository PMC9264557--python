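"""The fitted-signature workflow as a model/results pair.

``IRGPRiskModel`` holds the data and settings; ``fit`` runs the entire
analysis — differential expression, immune intersection, pair
construction and prevalence filtering, train/test split, univariate Cox
screening, cross-validated L1-penalized Cox selection, ROC cutoff on the
training cohort, stratified survival comparison on both cohorts, and the
multivariate independence check — and returns an ``IRGPRiskResults``
carrying every intermediate plus a ``summary()`` table.

Example
-------
>>> from irgp import IRGPRiskModel, SimulationConfig, simulate
>>> cfg = SimulationConfig(seed=7, planted_pairs=simulate.default_planted_pairs(
...     SimulationConfig(), 5, beta=1.0))
>>> em, clinical, truth, _ = simulate.simulate_cohort(cfg, with_maf=False)
>>> res = IRGPRiskModel(em, clinical, simulate.immune_gene_set(cfg)).fit(seed=7)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffexpr, pairs as pairmod, risk as riskmod
from .coxnet import CVSelection, cv_select
from .datatypes import (ClinicalTable, ExpressionMatrix, GeneSet,
                        PairIndicatorMatrix, SignatureModel, ValidationError)
from .risk import (IndependenceResult, StratifiedComparison,
                   multivariate_independence, one_year_roc, risk_score,
                   select_cutoff, split_cohort, stratify_and_compare)
from .survival import univariate_screen


class IRGPRiskModel:
    """Immune gene-pair risk model builder.

    Parameters
    ----------
    expression : ExpressionMatrix
        Raw (or already normalized, with ``normalize=False``) expression
        with tumor/normal labels.
    clinical : ClinicalTable
        Survival follow-up for (a subset of) the tumor samples.
    immune_genes : GeneSet
        Immune-annotated symbols to intersect with differential genes.

    The remaining keyword arguments are the analysis thresholds: the
    differential-expression cuts (|log2FC| > ``lfc_min``, p < ``p_max``),
    the pair prevalence interval, the univariate screening alpha, the
    cross-validation fold count and lambda grid, the ROC horizon in days
    and the train/test split ratio.
    """

    def __init__(self, expression: ExpressionMatrix, clinical: ClinicalTable,
                 immune_genes: GeneSet, *, lfc_min: float = 1.0,
                 p_max: float = 0.05, prevalence: tuple[float, float] = (0.2, 0.8),
                 univariate_alpha: float = 0.01, cv_folds: int = 10,
                 n_lambda: int = 100, lambda_min_ratio: float = 0.01,
                 horizon: float = 365.0, split_ratio: float = 0.5,
                 normalize: bool = True, pseudocount: float = 1.0,
                 score_form: str = "continuous"):
        self.expression = expression
        self.clinical = clinical
        self.immune_genes = immune_genes
        self.lfc_min = lfc_min
        self.p_max = p_max
        self.prevalence = prevalence
        self.univariate_alpha = univariate_alpha
        self.cv_folds = cv_folds
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.horizon = horizon
        self.split_ratio = split_ratio
        self.normalize = normalize
        self.pseudocount = pseudocount
        self.score_form = score_form

    @classmethod
    def from_frames(cls, expression: pd.DataFrame, group: pd.Series,
                    clinical: pd.DataFrame, immune_genes, **kwargs
                    ) -> "IRGPRiskModel":
        """Build from plain pandas objects (genes x samples, labels, table)."""
        em = ExpressionMatrix(expression, group)
        ct = ClinicalTable(clinical)
        if not isinstance(immune_genes, GeneSet):
            immune_genes = GeneSet(list(immune_genes), provenance="immune")
        return cls(em, ct, immune_genes, **kwargs)

    def fit(self, seed: int = 0) -> "IRGPRiskResults":
        """Run the full analysis; ``seed`` drives the split and CV folds."""
        em = (diffexpr.normalize_log2cpm(self.expression, self.pseudocount)
              if self.normalize else self.expression)

        de_table = diffexpr.differential_expression(em)
        degs = diffexpr.filter_degs(de_table, self.lfc_min, self.p_max)
        immune_degs = diffexpr.intersect_immune(degs, self.immune_genes)
        if len(immune_degs) < 2:
            raise ValidationError(
                f"only {len(immune_degs)} immune differential gene(s); "
                "cannot form pairs")

        candidates = pairmod.enumerate_pairs(immune_degs)
        tumor_with_surv = [s for s in em.samples_in_group("tumor")
                           if s in set(self.clinical.sample_ids)]
        pm_all = pairmod.build_indicator_matrix(em, candidates,
                                                tumor_with_surv)
        pm = pairmod.prevalence_filter(pm_all, *self.prevalence)
        if pm.n_pairs == 0:
            raise ValidationError("no pairs survive the prevalence filter")

        clin = self.clinical.subset(tumor_with_surv)
        train_ids, test_ids = split_cohort(clin, self.split_ratio, seed)
        pm_train = pm.subset_samples(train_ids)
        clin_train = clin.subset(train_ids)
        clin_test = clin.subset(test_ids)

        screened, screen_table = univariate_screen(
            pm_train, clin_train.time.to_numpy(), clin_train.event.to_numpy(),
            self.univariate_alpha)
        if not screened:
            raise ValidationError(
                "no pair passes the univariate screen; "
                "lower univariate_alpha or increase the cohort size")
        keep = [i for i, p in enumerate(pm.pairs) if p in set(screened)]
        pm_screened_train = pm_train.subset_pairs(keep)

        X = pm_screened_train.to_frame().T.astype(float)
        cv = cv_select(X, clin_train.time.to_numpy(),
                       clin_train.event.to_numpy(), folds=self.cv_folds,
                       seed=seed, n_lambda=self.n_lambda,
                       lambda_min_ratio=self.lambda_min_ratio)
        nz = cv.coef[cv.coef != 0]
        if nz.empty:
            raise ValidationError("the selected penalty keeps no pairs")
        sig_pairs = [tuple(tok.split("|")) for tok in nz.index]
        signature = SignatureModel(sig_pairs, nz.to_numpy())

        scores_train = risk_score(signature, pm.subset_samples(train_ids),
                                  expression=em)
        scores_test = risk_score(signature, pm.subset_samples(test_ids),
                                 expression=em)
        roc = one_year_roc(scores_train, clin_train, self.horizon)
        cutoff = select_cutoff(roc)
        signature.cutoff = cutoff
        train_cmp = stratify_and_compare(scores_train, cutoff, clin_train)
        test_cmp = stratify_and_compare(scores_test, cutoff, clin_test)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            independence = multivariate_independence(
                scores_train, clin_train, score_form=self.score_form,
                cutoff=cutoff)

        counts = {
            "genes_tested": int(len(de_table)),
            "degs": len(degs),
            "immune_degs": len(immune_degs),
            "candidate_pairs": len(candidates),
            "pairs_after_prevalence": pm.n_pairs,
            "train_samples": len(train_ids),
            "test_samples": len(test_ids),
            "pairs_after_screen": len(screened),
            "signature_pairs": len(signature),
        }
        return IRGPRiskResults(
            model=self, seed=seed, de_table=de_table, degs=degs,
            immune_degs=immune_degs, pair_matrix=pm, train_ids=train_ids,
            test_ids=test_ids, screen_table=screen_table,
            screened_pairs=screened, cv=cv, signature=signature,
            scores_train=scores_train, scores_test=scores_test, roc=roc,
            cutoff=cutoff, train_comparison=train_cmp,
            test_comparison=test_cmp, independence=independence,
            stage_counts=counts)


@dataclass
class IRGPRiskResults:
    """Everything the fitted pipeline produced."""

    model: IRGPRiskModel
    seed: int
    de_table: pd.DataFrame
    degs: GeneSet
    immune_degs: GeneSet
    pair_matrix: PairIndicatorMatrix
    train_ids: list[str]
    test_ids: list[str]
    screen_table: pd.DataFrame
    screened_pairs: list[tuple[str, str]]
    cv: CVSelection
    signature: SignatureModel
    scores_train: pd.Series
    scores_test: pd.Series
    roc: "riskmod.ROCCurve"
    cutoff: float
    train_comparison: StratifiedComparison
    test_comparison: StratifiedComparison
    independence: IndependenceResult
    stage_counts: dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        """A plain-text report of the fitted signature and its performance."""
        c = self.stage_counts
        lines = [
            "Immune gene-pair risk model",
            "=" * 60,
            f"genes tested: {c['genes_tested']}   DEGs: {c['degs']}   "
            f"immune DEGs: {c['immune_degs']}",
            f"candidate pairs: {c['candidate_pairs']}   "
            f"after prevalence filter: {c['pairs_after_prevalence']}",
            f"train/test samples: {c['train_samples']}/{c['test_samples']}",
            f"pairs past univariate screen (p < "
            f"{self.model.univariate_alpha}): {c['pairs_after_screen']}",
            f"selected lambda: {self.cv.lambda_:.6g}   "
            f"signature size: {len(self.signature)}",
            "",
            "Signature (pair, coefficient):",
        ]
        for pair, coef in zip(self.signature.pairs,
                              self.signature.coefficients):
            lines.append(f"  {pair[0]}|{pair[1]:<12} {coef:+.6f}")
        tr, te = self.train_comparison, self.test_comparison
        lines += [
            "",
            f"1-year ROC AUC (train): {self.roc.auc:.3f}   "
            f"risk-score cutoff: {self.cutoff:.4g}",
            f"train: log-rank chi2={tr.chi_square:.2f} p={tr.p_value:.3g}; "
            f"deaths high/low = {tr.death_fraction['high']:.0%}/"
            f"{tr.death_fraction['low']:.0%} "
            f"(n={tr.n['high']}/{tr.n['low']})",
            f"test:  log-rank chi2={te.chi_square:.2f} p={te.p_value:.3g}; "
            f"deaths high/low = {te.death_fraction['high']:.0%}/"
            f"{te.death_fraction['low']:.0%} "
            f"(n={te.n['high']}/{te.n['low']})",
            "",
            "Multivariate Cox (risk score + clinical covariates):",
            self.independence.multivariate.to_string(
                float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
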