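"""Candidate gene-pair construction, binarization and prevalence filtering.

A pair feature compares two genes *within* a sample: the indicator is 1
exactly when the former gene's expression strictly exceeds the latter's
(ties give 0).  Each unordered pair is emitted once, oriented by input
order; the reversed orientation would be (1 - indicator) except at ties,
so keeping both would duplicate near-identical features.  Pairs whose
indicator is constant (0 or 1) in more than 80% of samples carry little
information and are removed; the retained prevalence interval is closed,
[lo, hi] = [0.2, 0.8] by default.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .datatypes import (ExpressionMatrix, GeneSet, PairIndicatorMatrix,
                        ValidationError)


def enumerate_pairs(genes: GeneSet | Sequence[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered pairs, oriented by the input gene order."""
    gene_list = list(genes)
    if len(gene_list) < 2:
        raise ValidationError(
            f"need at least 2 genes to form pairs, got {len(gene_list)}")
    return list(combinations(gene_list, 2))


def binarize_pair(em: ExpressionMatrix, pair: tuple[str, str]) -> np.ndarray:
    """Indicator over samples: 1 where expr[former] > expr[latter], else 0."""
    for g in pair:
        if g not in em.values.index:
            raise ValidationError(f"gene {g!r} not present in expression matrix")
    a = em.values.loc[pair[0]].to_numpy()
    b = em.values.loc[pair[1]].to_numpy()
    return (a > b).astype(np.uint8)


def build_indicator_matrix(em: ExpressionMatrix,
                           pairs: Iterable[tuple[str, str]],
                           sample_ids: Sequence[str] | None = None,
                           ) -> PairIndicatorMatrix:
    """Vectorized binarization of many pairs over (a subset of) samples."""
    pairs = [tuple(p) for p in pairs]
    values = em.values if sample_ids is None else em.values[list(sample_ids)]
    missing = {g for p in pairs for g in p} - set(em.values.index)
    if missing:
        raise ValidationError(
            f"gene {sorted(missing)[0]!r} not present in expression matrix")
    former = values.loc[[p[0] for p in pairs]].to_numpy()
    latter = values.loc[[p[1] for p in pairs]].to_numpy()
    return PairIndicatorMatrix(pairs, list(values.columns),
                               (former > latter).astype(np.uint8))


def prevalence_filter(pm: PairIndicatorMatrix, lo: float = 0.2,
                      hi: float = 0.8) -> PairIndicatorMatrix:
    """Retain pairs whose indicator mean over samples lies in [lo, hi].

    Equivalent to removing pairs that are 0 in more than (1-lo) or 1 in
    more than hi of the samples; a pair constant in *exactly* hi of the
    samples is retained (closed interval).  Idempotent.
    """
    if not (0.0 < lo < hi < 1.0):
        raise ValidationError("prevalence bounds must satisfy 0 < lo < hi < 1")
    prev = pm.prevalence()
    keep = np.flatnonzero((prev >= lo) & (prev <= hi))
    return pm.subset_pairs(keep)
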