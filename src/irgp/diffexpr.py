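"""Tumor-vs-normal differential expression and immune-gene intersection.

Normalization is library-size scaling to counts-per-million followed by a
log2 with pseudocount; the per-gene test is a Welch two-sample t on the
normalized values with log2 fold-change defined as mean(tumor) minus
mean(normal).  Differential genes are those with |log2FC| strictly above
the fold-change threshold and p strictly below the p threshold (raw
p-values by default; Benjamini–Hochberg adjustment is opt-in).  The
downstream signature uses only within-sample orderings, so the analysis
is deliberately light on distributional assumptions here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSet, ValidationError, NORMAL, TUMOR


def normalize_log2cpm(em: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Scale each sample to counts-per-million, then take log2(x + pseudocount).

    After the transform, ``sum(2**v - pseudocount)`` over any column is
    1e6 up to floating tolerance.  Raises on a pseudocount <= 0 or an
    all-zero sample column (which has no defined library size).
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    totals = em.values.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"all-zero expression column for sample {zero[0]!r}")
    cpm = em.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + pseudocount), em.group)


def differential_expression(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs normal on (normalized) values.

    Returns a DataFrame indexed by gene with columns ``mean_tumor``,
    ``mean_normal``, ``log2fc`` (tumor minus normal), ``t_stat`` and
    ``p_value`` (two-sided).  A gene with identical values in both groups
    gets t = 0, p = 1; a gene with zero within-group variance but
    different means gets p = 0.  Both groups need at least two samples.
    """
    tumor = em.samples_in_group(TUMOR)
    normal = em.samples_in_group(NORMAL)
    for name, ids in (("tumor", tumor), ("normal", normal)):
        if len(ids) < 2:
            raise ValidationError(
                f"differential expression needs >= 2 {name} samples, "
                f"got {len(ids)}")
    a = em.values[tumor].to_numpy()
    b = em.values[normal].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = m1 - m2
    se2 = v1 / n1 + v2 / n2

    t_stat = np.zeros_like(diff)
    p = np.ones_like(diff)
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ok = diff[ok] / np.sqrt(se2[ok])
        # Welch–Satterthwaite degrees of freedom
        df = se2[ok] ** 2 / ((v1[ok] / n1) ** 2 / (n1 - 1)
                             + (v2[ok] / n2) ** 2 / (n2 - 1))
    t_stat[ok] = t_ok
    p[ok] = 2.0 * stats.t.sf(np.abs(t_ok), df)
    # zero pooled variance: identical values -> t=0, p=1; else separated
    degen = ~ok & (diff != 0)
    t_stat[degen] = np.sign(diff[degen]) * np.inf
    p[degen] = 0.0
    return pd.DataFrame(
        {"mean_tumor": m1, "mean_normal": m2, "log2fc": diff,
         "t_stat": t_stat, "p_value": p},
        index=em.values.index)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def filter_degs(table: pd.DataFrame, lfc_min: float = 1.0, p_max: float = 0.05,
                fdr: bool = False) -> GeneSet:
    """Genes with |log2FC| > lfc_min and p < p_max (both strict).

    ``fdr=True`` applies the thresholds to Benjamini–Hochberg adjusted
    p-values instead of raw ones.
    """
    if lfc_min <= 0 or p_max <= 0:
        raise ValidationError("thresholds must be positive")
    p = bh_adjust(table["p_value"].to_numpy()) if fdr else table["p_value"].to_numpy()
    keep = (np.abs(table["log2fc"].to_numpy()) > lfc_min) & (p < p_max)
    return GeneSet(list(table.index[keep]), provenance="DEG")


def intersect_immune(degs: GeneSet, immune: GeneSet) -> GeneSet:
    """Differential genes that are also immune-annotated, in DEG order."""
    immune_set = set(immune.genes)
    return GeneSet([g for g in degs.genes if g in immune_set],
                   provenance="immune-DEG")
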