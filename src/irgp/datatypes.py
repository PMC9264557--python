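"""Core containers for the gene-pair signature pipeline.

The pipeline moves through a small number of well-defined objects: an
expression matrix with tumor/normal labels, a clinical/survival table, a
binary pair-indicator matrix (one row per ordered gene pair, 1 where the
first gene's expression exceeds the second's within a sample), and a fitted
signature (ordered pairs with coefficients and an optional risk-score
cutoff).  Each container validates its invariants on construction so that
malformed inputs fail early with a message naming the offending entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
VALID_GROUPS = frozenset({TUMOR, NORMAL})


class ValidationError(ValueError):
    """An input container violated one of its structural invariants."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene symbols, columns by unique sample ids.
        All entries must be finite and non-negative (raw counts, normalized
        intensities or log-scale values after a pseudocount).
    group : pandas.Series
        Per-sample label, either ``"tumor"`` or ``"normal"``, indexed by the
        same sample ids as ``values`` columns.
    """

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if arr.size and (arr < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.group = pd.Series(self.group)
        if list(self.group.index) != list(self.values.columns):
            # allow unordered input but require the same id set
            try:
                self.group = self.group.loc[self.values.columns]
            except KeyError as exc:
                raise ValidationError(f"group labels missing for sample: {exc}")
        bad = set(self.group.unique()) - VALID_GROUPS
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.group.index[self.group == group])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)],
                                self.group.loc[list(sample_ids)])


#: Columns a clinical table may carry beyond the mandatory id/time/event.
CLINICAL_COVARIATES = ("age", "gender", "grade", "stage", "t_stage", "n_stage")


@dataclass
class ClinicalTable:
    """Survival follow-up plus clinical covariates, one row per sample.

    ``data`` is indexed by unique sample id and must contain ``time``
    (follow-up in days, > 0) and ``event`` (1 = death, 0 = censored).
    Covariates (age, gender, grade, stage, t_stage, n_stage) are optional
    and may contain missing values; they are excluded per-model downstream,
    never imputed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("clinical data must be a DataFrame")
        _check_unique(self.data.index, "sample id")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        t = self.data["time"].to_numpy(dtype=float)
        if len(t) and (~np.isfinite(t) | (t <= 0)).any():
            raise ValidationError("follow-up times must be finite and > 0")
        ev = self.data["event"].to_numpy()
        if len(ev) and not np.isin(ev, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])


def pair_token(pair: tuple[str, str]) -> str:
    """Render a gene pair as the conventional ``FORMER|LATTER`` token."""
    return f"{pair[0]}|{pair[1]}"


@dataclass
class SignatureModel:
    """An ordered gene-pair signature with per-pair coefficients.

    The risk score of a sample is ``sum_k coef_k * I(expr[former_k] >
    expr[latter_k])``.  ``cutoff`` (optional) is the risk-score threshold
    above which a sample is called high risk.
    """

    pairs: list[tuple[str, str]]
    coefficients: np.ndarray
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise ValidationError("pairs and coefficients differ in length")
        _check_unique((pair_token(p) for p in self.pairs), "pair")
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"pair with identical genes: {a}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        """Union of both members of every pair, in order of appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for a, b in self.pairs:
            for g in (a, b):
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pair": [pair_token(p) for p in self.pairs],
             "coefficient": self.coefficients})


@dataclass
class PairIndicatorMatrix:
    """Binary pairs x samples matrix of within-sample ordering indicators.

    Entry (k, s) is 1 when, in sample s, the former gene of pair k has
    strictly higher expression than the latter gene; ties and reversals
    give 0.  Because it depends only on the within-sample ordering, the
    matrix is invariant under any strictly monotone per-sample transform
    of the expression values.
    """

    pairs: list[tuple[str, str]]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValidationError(
                f"indicator shape {self.values.shape} does not match "
                f"{len(self.pairs)} pairs x {len(self.sample_ids)} samples")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValidationError("indicators must be 0 or 1")
        self.values = self.values.astype(np.uint8)
        seen: set[frozenset[str]] = set()
        for a, b in self.pairs:
            key = frozenset((a, b))
            if key in seen:
                raise ValidationError(
                    f"unordered pair appears twice: {a}|{b}")
            seen.add(key)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def prevalence(self) -> np.ndarray:
        """Per-pair mean indicator across samples."""
        return self.values.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=[pair_token(p) for p in self.pairs],
                            columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "PairIndicatorMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return PairIndicatorMatrix(self.pairs, list(sample_ids),
                                   self.values[:, idx])

    def subset_pairs(self, keep: Sequence[int]) -> "PairIndicatorMatrix":
        keep = list(keep)
        return PairIndicatorMatrix([self.pairs[i] for i in keep],
                                   self.sample_ids, self.values[keep, :])


@dataclass
class GeneSet:
    """An ordered, duplicate-free collection of gene symbols."""

    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.genes, "gene")
        self.genes = list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (paths, thresholds, seeds)."""

    expression_path: str
    clinical_path: str
    immune_genes_path: str
    outdir: str
    groups_path: str | None = None
    maf_path: str | None = None
    split_ratio: float = 0.5
    seed: int = 0
    lfc_min: float = 1.0
    p_max: float = 0.05
    prevalence_lo: float = 0.2
    prevalence_hi: float = 0.8
    univariate_alpha: float = 0.01
    cv_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    roc_horizon: float = 365.0
    normalize: bool = True
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_lo < self.prevalence_hi < 1.0):
            raise ValidationError("prevalence bounds must satisfy 0 < lo < hi < 1")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be at least 2")
        for name in ("lfc_min", "p_max", "univariate_alpha", "roc_horizon",
                     "pseudocount", "lambda_min_ratio"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 < self.split_ratio < 1.0):
            raise ValidationError("split_ratio must lie in (0, 1)")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic tumor/normal survival cohort.

    Expression is log-normal: ``log2 x ~ Normal(mu_g + shift, noise_sd)``
    where planted differentially expressed genes receive a tumor-only mean
    shift of ``de_log2fc``.  Event times follow a proportional-hazards
    exponential law whose covariates are the planted pairs' ordering
    indicators: ``T ~ Exp(baseline_hazard * exp(sum beta_k * I_k))``.
    Censoring is an independent ``Exp(censor_rate)`` truncated at
    ``admin_censor_time``.  Defaults emulate the study cohort: 390 tumor
    and 32 normal profiles, follow-up in days with roughly half to
    two-thirds of samples censored.
    """

    n_tumor: int = 390
    n_normal: int = 32
    n_genes: int = 600
    immune_fraction: float = 0.25
    n_de_genes: int = 60
    de_log2fc: float = 2.0
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    baseline_hazard: float = 1.0 / 1000.0
    censor_rate: float = 1.0 / 900.0
    admin_censor_time: float = 1825.0
    noise_sd: float = 1.0
    mu_low: float = 3.0
    mu_high: float = 10.0
    age_effect: float = 0.0
    mutation_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 < self.immune_fraction <= 1.0):
            raise ValidationError("immune_fraction must lie in (0, 1]")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValidationError("censor_rate must be non-negative")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValidationError("n_de_genes out of range")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.mutation_rate < 0:
            raise ValidationError("mutation_rate must be non-negative")

    @property
    def n_immune(self) -> int:
        return max(2, int(round(self.immune_fraction * self.n_genes)))


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort, for recovery tests.

    ``linear_predictor[s]`` equals ``sum_k beta_k * indicators[k, s]``
    exactly, by construction.
    """

    planted_de: dict[str, float]
    planted_pairs: list[tuple[str, str, float]]
    indicators: PairIndicatorMatrix | None = None
    linear_predictor: pd.Series | None = None

    @property
    def betas(self) -> np.ndarray:
        return np.array([b for _, _, b in self.planted_pairs], dtype=float)
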