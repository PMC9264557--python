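"""Mutation Annotation Format (MAF) parsing and summary statistics.

Summaries follow the conventions of standard somatic-mutation reports:
counts per variant classification (missense, nonsense, splice site, ...),
per variant type (SNP/INS/DEL/...), the six single-nucleotide substitution
classes after collapsing purine-reference changes onto the pyrimidine
frame (so G>A is counted as C>T), per-sample mutation burden with its
median and maximum, and genes ranked by the number of samples carrying a
mutation.  Multiple hits of one gene in one sample count once toward the
gene's sample frequency but fully toward burden.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datatypes import GeneSet, SignatureModel, ValidationError

REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode",
                    "Variant_Classification", "Variant_Type",
                    "Reference_Allele", "Tumor_Seq_Allele2")

VALID_VARIANT_TYPES = frozenset({"SNP", "INS", "DEL", "DNP", "TNP", "ONP"})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-frame substitution classes.
SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class MafRecord:
    """One somatic variant call."""

    gene: str
    sample: str
    classification: str
    variant_type: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.gene or not self.sample:
            raise ValidationError("MAF record needs a gene and a sample")
        if self.variant_type not in VALID_VARIANT_TYPES:
            raise ValidationError(
                f"invalid Variant_Type {self.variant_type!r} "
                f"(expected one of {sorted(VALID_VARIANT_TYPES)})")


def read_maf(path: str | Path) -> list[MafRecord]:
    """Parse a MAF file into records; '#' comment lines are skipped.

    Header columns are matched case-insensitively; a missing required
    column is an error naming it.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    colmap = {c.lower(): c for c in df.columns}
    resolved = {}
    for col in REQUIRED_COLUMNS:
        if col.lower() not in colmap:
            raise ValidationError(f"MAF file {path} missing required column "
                                  f"{col!r}")
        resolved[col] = colmap[col.lower()]
    records = []
    for _, row in df.iterrows():
        records.append(MafRecord(
            gene=str(row[resolved["Hugo_Symbol"]]).strip().upper(),
            sample=str(row[resolved["Tumor_Sample_Barcode"]]).strip(),
            classification=str(row[resolved["Variant_Classification"]]).strip(),
            variant_type=str(row[resolved["Variant_Type"]]).strip().upper(),
            ref=str(row[resolved["Reference_Allele"]]).strip().upper(),
            alt=str(row[resolved["Tumor_Seq_Allele2"]]).strip().upper()))
    return records


def write_maf(records: Iterable[MafRecord], path: str | Path) -> None:
    rows = [(r.gene, r.sample, r.classification, r.variant_type, r.ref, r.alt)
            for r in records]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def signature_genes(sig: SignatureModel) -> GeneSet:
    """Union of both members of every signature pair, in pair order."""
    return GeneSet(sig.genes, provenance="signature")


def restrict_to_genes(records: Sequence[MafRecord],
                      genes: GeneSet | Iterable[str]) -> list[MafRecord]:
    """Records whose gene belongs to the given set."""
    keep = set(genes.genes if isinstance(genes, GeneSet) else genes)
    return [r for r in records if r.gene in keep]


def _snv_class(ref: str, alt: str) -> str | None:
    """Six-class label on the pyrimidine frame, or None if not a valid SNV."""
    if len(ref) != 1 or len(alt) != 1:
        return None
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    if ref in ("G", "A"):  # collapse onto the pyrimidine reference strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class MutationSummary:
    """Aggregate mutation statistics of a set of MAF records."""

    classification_counts: dict[str, int]
    type_counts: dict[str, int]
    snv_class_counts: dict[str, int]
    n_invalid_snv: int
    per_sample_counts: dict[str, int]
    per_sample_median: float
    per_sample_max: int
    gene_mutation_counts: dict[str, int]
    gene_sample_counts: dict[str, int]
    gene_sample_frequency: dict[str, float]
    n_records: int
    n_samples: int
    top: pd.DataFrame = field(repr=False, default=None)


def summarize(records: Sequence[MafRecord]) -> MutationSummary:
    """Compute every summary field by direct counting.

    SNP-type records with non-single-base or non-ACGT alleles are counted
    as invalid (with a warning) and excluded from the substitution
    classes; the identity ``sum(SNV classes) + invalid == #SNP records``
    holds exactly.
    """
    classification = Counter(r.classification for r in records)
    types = Counter(r.variant_type for r in records)
    snv = {c: 0 for c in SNV_CLASSES}
    invalid = 0
    for r in records:
        if r.variant_type != "SNP":
            continue
        cls = _snv_class(r.ref, r.alt)
        if cls is None:
            invalid += 1
            warnings.warn(f"SNP record for {r.gene} in {r.sample} has "
                          f"non-single-base alleles {r.ref}>{r.alt}; "
                          "excluded from substitution classes")
        else:
            snv[cls] += 1
    per_sample = Counter(r.sample for r in records)
    gene_counts = Counter(r.gene for r in records)
    gene_samples: dict[str, set[str]] = defaultdict(set)
    for r in records:
        gene_samples[r.gene].add(r.sample)
    n_samples = len(per_sample)
    gene_sample_counts = {g: len(s) for g, s in gene_samples.items()}
    freq = {g: (c / n_samples if n_samples else 0.0)
            for g, c in gene_sample_counts.items()}
    counts = list(per_sample.values())
    summary = MutationSummary(
        classification_counts=dict(classification),
        type_counts=dict(types),
        snv_class_counts=snv,
        n_invalid_snv=invalid,
        per_sample_counts=dict(per_sample),
        per_sample_median=float(pd.Series(counts).median()) if counts else 0.0,
        per_sample_max=max(counts) if counts else 0,
        gene_mutation_counts=dict(gene_counts),
        gene_sample_counts=gene_sample_counts,
        gene_sample_frequency=freq,
        n_records=len(records),
        n_samples=n_samples)
    summary.top = _gene_table(summary)
    return summary


def _gene_table(summary: MutationSummary) -> pd.DataFrame:
    rows = sorted(summary.gene_sample_counts.items(),
                  key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {"gene": [g for g, _ in rows],
         "n_samples_mutated": [c for _, c in rows],
         "n_mutations": [summary.gene_mutation_counts[g] for g, _ in rows],
         "sample_frequency": [summary.gene_sample_frequency[g]
                              for g, _ in rows]}).set_index("gene")


def top_genes(summary: MutationSummary, n: int = 10) -> list[str]:
    """Genes ranked by mutated-sample count, ties alphabetical, top n."""
    if n < 1:
        raise ValidationError("n must be at least 1")
    return list(summary.top.index[:n])
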