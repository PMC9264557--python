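"""Synthetic tumor/normal cohorts with planted survival structure.

The generator produces data with exactly the statistical structure the
pipeline assumes, plus a truth set for recovery tests:

* **Expression** is log-normal: ``log2 x ~ Normal(mu_g + shift, sd)``,
  with planted differential genes shifted by ``de_log2fc`` in tumor
  samples only.  The downstream analysis is rank- and order-based, so
  only within-sample orderings matter and a log-normal law keeps the
  generator analytic; negative-binomial count noise is deliberately not
  modeled.
* **Survival** follows proportional hazards with the planted pairs'
  ordering indicators as covariates: ``T ~ Exp(h0 * exp(sum beta_k I_k))``
  with independent ``Exp(censor_rate)`` censoring truncated at an
  administrative cutoff.  Clinical covariates are drawn independently of
  the hazard unless an age effect is requested (a positive control for
  the independence analysis).
* **Mutations** are Poisson per-sample counts assigned to genes with
  configurable propensities, written as standard MAF records with a
  C>T-dominant substitution law.

Genes are named ``G0001 ...``; the immune-labeled set is the first
``round(immune_fraction * n_genes)`` genes, and planted differential
genes are drawn from the immune set (so some survive the immune-DEG
intersection downstream).  Each gene of a planted pair shares the pair's
baseline mean, making the pair indicator a fair coin per sample, which
gives planted pairs prevalence near one half.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (ClinicalTable, ExpressionMatrix, GeneSet,
                        PairIndicatorMatrix, SimulationConfig, TruthSet,
                        ValidationError)
from .maf import MafRecord, SNV_CLASSES

_VARIANT_CLASSES = (("Missense_Mutation", 0.55), ("Nonsense_Mutation", 0.12),
                    ("Splice_Site", 0.10), ("Frame_Shift_Del", 0.06),
                    ("Frame_Shift_Ins", 0.05), ("In_Frame_Del", 0.04),
                    ("Silent", 0.08))

#: Pyrimidine-frame substitution law; C>T transitions dominate, as is
#: typical of somatic SNVs in head-and-neck tumors.
_SNV_PROBS = {"C>T": 0.40, "T>C": 0.20, "C>A": 0.14, "C>G": 0.08,
              "T>A": 0.09, "T>G": 0.09}


def gene_names(cfg: SimulationConfig) -> list[str]:
    width = max(4, len(str(cfg.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]


def immune_gene_set(cfg: SimulationConfig) -> GeneSet:
    """The first ``n_immune`` genes are the immune-annotated ones."""
    return GeneSet(gene_names(cfg)[:cfg.n_immune], provenance="immune")


def simulate_expression(cfg: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[ExpressionMatrix, TruthSet]:
    """Draw the expression matrix and record the partial truth set.

    Planted pair indicators are realized as ``I(x_i > x_j)`` on the tumor
    samples and stored in the truth set together with the true linear
    predictor ``sum beta_k I_k``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    genes = gene_names(cfg)
    gene_pos = {g: i for i, g in enumerate(genes)}
    immune = set(immune_gene_set(cfg).genes)
    for gi, gj, _ in cfg.planted_pairs:
        for g in (gi, gj):
            if g not in gene_pos:
                raise ValidationError(f"planted pair references unknown gene {g!r}")
            if g not in immune:
                raise ValidationError(
                    f"planted pair gene {g!r} is not in the immune-labeled set")
        if gi == gj:
            raise ValidationError(f"planted pair with identical genes: {gi}")

    tumor_ids = [f"T{i:04d}" for i in range(1, cfg.n_tumor + 1)]
    normal_ids = [f"N{i:04d}" for i in range(1, cfg.n_normal + 1)]
    samples = tumor_ids + normal_ids

    mu = rng.uniform(cfg.mu_low, cfg.mu_high, size=cfg.n_genes)
    # paired genes share a baseline mean so the ordering is a fair coin
    for gi, gj, _ in cfg.planted_pairs:
        mu[gene_pos[gj]] = mu[gene_pos[gi]]

    # both genes of a planted pair receive the same tumor shift: the pair
    # then passes the DEG filter downstream while its ordering indicator
    # stays a fair coin (the shift cancels within the pair)
    planted_de: dict[str, float] = {}
    pair_genes = {g for gi, gj, _ in cfg.planted_pairs for g in (gi, gj)}
    if cfg.de_log2fc != 0:
        for gi, gj, _ in cfg.planted_pairs:
            shift = float(rng.choice([-1.0, 1.0]) * cfg.de_log2fc)
            planted_de.setdefault(gi, shift)
            planted_de.setdefault(gj, planted_de[gi])
    de_candidates = [g for g in genes if g in immune and g not in pair_genes]
    de_candidates += [g for g in genes if g not in immune]
    n_de = min(cfg.n_de_genes, len(de_candidates))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    if cfg.de_log2fc != 0:
        for i in range(n_de):
            planted_de[de_candidates[i]] = float(signs[i] * cfg.de_log2fc)

    log2x = mu[:, None] + rng.normal(0.0, cfg.noise_sd,
                                     size=(cfg.n_genes, len(samples)))
    for g, lfc in planted_de.items():
        log2x[gene_pos[g], :cfg.n_tumor] += lfc
    values = pd.DataFrame(np.exp2(log2x), index=genes, columns=samples)
    group = pd.Series(["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
                      index=samples)
    em = ExpressionMatrix(values, group)

    truth = TruthSet(planted_de=planted_de,
                     planted_pairs=list(cfg.planted_pairs))
    if cfg.planted_pairs:
        pairs = [(gi, gj) for gi, gj, _ in cfg.planted_pairs]
        former = values.loc[[p[0] for p in pairs], tumor_ids].to_numpy()
        latter = values.loc[[p[1] for p in pairs], tumor_ids].to_numpy()
        ind = PairIndicatorMatrix(pairs, tumor_ids,
                                  (former > latter).astype(np.uint8))
        truth.indicators = ind
        truth.linear_predictor = pd.Series(
            truth.betas @ ind.values.astype(float), index=tumor_ids)
    else:
        truth.linear_predictor = pd.Series(0.0, index=tumor_ids)
    return em, truth


def simulate_survival(cfg: SimulationConfig, truth: TruthSet,
                      rng: np.random.Generator | None = None) -> ClinicalTable:
    """Draw survival and clinical covariates for the tumor samples."""
    rng = (np.random.default_rng(cfg.seed + 1_000_003)
           if rng is None else rng)
    lp = truth.linear_predictor
    if lp is None:
        raise ValidationError("truth set lacks a linear predictor; "
                              "run simulate_expression first")
    ids = list(lp.index)
    n = len(ids)

    age = np.round(rng.uniform(30.0, 85.0, size=n), 1)
    hazard_lp = lp.to_numpy(dtype=float)
    if cfg.age_effect != 0.0:
        hazard_lp = hazard_lp + cfg.age_effect * (age - age.mean())
    rate = cfg.baseline_hazard * np.exp(hazard_lp)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, cfg.admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)  # guard the time > 0 invariant

    gender = rng.choice(["male", "female"], size=n, p=[0.7, 0.3])
    grade = rng.choice([1, 2, 3, 4], size=n, p=[0.15, 0.45, 0.3, 0.1])
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.15, 0.2, 0.25, 0.4])
    t_stage = rng.choice([1, 2, 3, 4], size=n, p=[0.2, 0.3, 0.25, 0.25])
    n_stage = rng.choice([0, 1, 2, 3], size=n, p=[0.4, 0.2, 0.3, 0.1])
    data = pd.DataFrame(
        {"time": time, "event": event, "age": age, "gender": gender,
         "grade": grade, "stage": stage, "t_stage": t_stage,
         "n_stage": n_stage}, index=pd.Index(ids, name="sample_id"))
    return ClinicalTable(data)


def simulate_maf(cfg: SimulationConfig,
                 gene_weights: dict[str, float] | None = None,
                 sample_ids: list[str] | None = None,
                 rng: np.random.Generator | None = None) -> list[MafRecord]:
    """Draw per-sample Poisson mutation counts and emit MAF records.

    ``gene_weights`` gives each gene's relative mutation propensity
    (uniform over the immune genes by default); weights must be
    non-negative and not all zero.
    """
    rng = (np.random.default_rng(cfg.seed + 2_000_003)
           if rng is None else rng)
    if gene_weights is None:
        gene_weights = {g: 1.0 for g in immune_gene_set(cfg).genes}
    genes = list(gene_weights)
    w = np.array([gene_weights[g] for g in genes], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValidationError("gene weights must be non-negative, not all zero")
    w = w / w.sum()
    if sample_ids is None:
        sample_ids = [f"T{i:04d}" for i in range(1, cfg.n_tumor + 1)]

    class_names = [c for c, _ in _VARIANT_CLASSES]
    class_p = np.array([p for _, p in _VARIANT_CLASSES])
    snv_names = list(SNV_CLASSES)
    snv_p = np.array([_SNV_PROBS[c] for c in snv_names])
    records: list[MafRecord] = []
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for s in sample_ids:
        k = rng.poisson(cfg.mutation_rate)
        for _ in range(k):
            gene = genes[rng.choice(len(genes), p=w)]
            cls = class_names[rng.choice(len(class_names), p=class_p)]
            if "Frame_Shift_Ins" in cls:
                vtype, ref, alt = "INS", "-", "A"
            elif "Del" in cls:
                vtype, ref, alt = "DEL", "A", "-"
            else:
                vtype = "SNP"
                ref, alt = snv_names[rng.choice(len(snv_names), p=snv_p)].split(">")
                if rng.random() < 0.5:  # emit on the purine strand
                    ref, alt = complement[ref], complement[alt]
            records.append(MafRecord(gene=gene, sample=s, classification=cls,
                                     variant_type=vtype, ref=ref, alt=alt))
    return records


def simulate_cohort(cfg: SimulationConfig,
                    with_maf: bool = True,
                    ) -> tuple[ExpressionMatrix, ClinicalTable, TruthSet,
                               list[MafRecord]]:
    """Full cohort draw: expression, survival, truth set and (optional) MAF."""
    em, truth = simulate_expression(cfg)
    clinical = simulate_survival(cfg, truth)
    maf = simulate_maf(cfg) if with_maf else []
    return em, clinical, truth, maf


def default_planted_pairs(cfg: SimulationConfig, n_pairs: int,
                          beta: float = 1.0, alternate_signs: bool = True,
                          ) -> list[tuple[str, str, float]]:
    """Convenience: plant ``n_pairs`` disjoint immune-gene pairs.

    Pairs use consecutive immune genes (disjoint, so their indicators are
    independent); signs alternate when requested so both protective and
    hazardous pairs are represented.
    """
    immune = immune_gene_set(cfg).genes
    if 2 * n_pairs > len(immune):
        raise ValidationError("not enough immune genes for that many pairs")
    out = []
    for k in range(n_pairs):
        sign = -1.0 if (alternate_signs and k % 2) else 1.0
        out.append((immune[2 * k], immune[2 * k + 1], sign * beta))
    return out
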