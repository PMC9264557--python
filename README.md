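# irgp — rank-based immune gene-pair prognostic signatures

`irgp` builds and evaluates survival signatures for tumor cohorts whose
features are *within-sample gene orderings* rather than expression levels.
For an ordered pair of immune-annotated genes (an "immune-related gene
pair", IRGP), the feature of sample *s* is

```
I_k(s) = 1  if  x[former_k, s] > x[latter_k, s],   else 0
```

and a patient's risk score is the linear combination

```
RiskScore(s) = Σ_k α_k · I_k(s)
```

with coefficients α fitted by L1-penalized Cox regression.  Because each
feature depends only on the ordering of two genes inside one sample, the
signature transfers across expression platforms without normalization —
any strictly monotone per-sample transform leaves every indicator, score
ordering and downstream survival comparison unchanged.

The implementation targets oral/head-and-neck-style bulk RNA cohorts with
tumor/normal contrasts and overall-survival follow-up, and ships the
published 17-pair oral-cancer signature (with its coefficients) as
reference data.  It is aimed at biostatisticians and computational
biologists who want a tested, reproducible version of this class of
workflow, plus a synthetic-cohort generator for validating each step.

## The workflow

1. **Differential expression** — per-gene Welch *t* on log2-CPM values,
   tumor vs normal; DEGs are genes with |log2FC| > 1 and p < 0.05
   (strict, raw p-values; Benjamini–Hochberg opt-in).
2. **Immune intersection** — DEGs ∩ a user-supplied immune gene list.
3. **Pair features** — all unordered pairs of immune DEGs, binarized per
   sample; pairs whose indicator is constant in more than 80% of samples
   are removed (retained prevalence in [0.2, 0.8]).
4. **Screening and fitting** — 1:1 train/test split; univariate Cox per
   pair on the training cohort (keep p < 0.01); L1-penalized Cox
   (cyclic coordinate descent over a geometric λ path with warm starts)
   with 10-fold cross-validated λ selection; the nonzero coefficients are
   the signature.
5. **Stratification** — risk scores, a one-year ROC cutoff maximizing
   Youden's J on the training cohort, Kaplan–Meier curves and a log-rank
   test between high- and low-risk groups, per-group mortality, and
   univariate + multivariate Cox models testing the score against age,
   gender, grade, stage and T/N status.
6. **Mutation summaries** — MAF parsing, variant classification / type
   counts, six-class SNV substitution spectrum (pyrimidine frame),
   per-sample burden and top mutated genes, restricted to the signature's
   genes.

The Kaplan–Meier estimator, log-rank test, Cox partial-likelihood
Newton–Raphson solver (Efron or Breslow ties) and the penalized Cox path
are implemented in the package and cross-checked in the test suite
against `lifelines`, `scikit-survival` and brute-force minimization.

## Worked example

```python
import warnings
from irgp import IRGPRiskModel, SimulationConfig
from irgp.simulate import simulate_cohort, default_planted_pairs, immune_gene_set

base = SimulationConfig(seed=7)                      # 390 tumor / 32 normal
cfg = SimulationConfig(seed=7, planted_pairs=default_planted_pairs(base, 5, beta=1.0))
em, clinical, truth, maf = simulate_cohort(cfg)
res = IRGPRiskModel(em, clinical, immune_gene_set(cfg)).fit(seed=7)
print(res.summary())
```

prints (abridged):

```
Immune gene-pair risk model
============================================================
genes tested: 600   DEGs: 70   immune DEGs: 70
candidate pairs: 2415   after prevalence filter: 491
train/test samples: 195/195
pairs past univariate screen (p < 0.01): 27
selected lambda: 0.0412118   signature size: 19

Signature (pair, coefficient):
  G0001|G0002        +1.106538
  G0003|G0004        -0.460283
  G0005|G0006        +0.901785
  ...

1-year ROC AUC (train): 0.923   risk-score cutoff: 0.7629
train: log-rank chi2=105.16 p=1.13e-24; deaths high/low = 80%/31% (n=94/101)
test:  log-rank chi2=53.63 p=2.42e-13; deaths high/low = 76%/45% (n=90/105)

Multivariate Cox (risk score + clinical covariates):
               coef       se     HR  CI95_lower  CI95_upper       z         p
age       -0.004916 0.006078 0.9951      0.9833       1.007 -0.8088    0.4186
...
riskScore     1.405   0.1328  4.074        3.14       5.285   10.58 3.874e-26
```

All five planted pairs (G0001|G0002 … G0009|G0010) are recovered with the
generating signs; the high-risk group dies far more often in both
cohorts; and in the joint Cox model only the risk score is prognostic —
exactly the structure the generator planted.  The signature also picks up
a few small-coefficient proxy pairs that share genes with planted pairs,
the expected behavior of the minimum-deviance λ rule.

A published 17-pair signature can be loaded and applied to any expression
matrix directly:

```python
from irgp import load_packaged_signature, load_expression
from irgp.risk import risk_score
sig = load_packaged_signature()        # 17 pairs, 6 negative / 11 positive α
scores = risk_score(sig, expression=load_expression("expr.tsv"))
```

The same workflow is available from the shell: `irgp simulate`, `irgp
deg`, `irgp pairs`, `irgp screen`, `irgp fit`, `irgp stratify`, `irgp
mafsum` and `irgp run-all --config config.json`.

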