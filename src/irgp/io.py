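"""Readers and writers for the pipeline's tabular formats.

Everything is plain tab-separated text with a header row, decimal point
and no thousands separators: expression matrices (genes as rows, samples
as columns, with a two-column sidecar assigning tumor/normal labels),
clinical tables, gene lists (one symbol per line) and gene-pair signatures
(two columns, ``FORMER|LATTER`` token and coefficient).  Gene symbols are
uppercased and stripped at load time.  The published 17-pair oral-cancer
signature and a small immune-gene list ship as packaged reference data.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import (ClinicalTable, ExpressionMatrix, GeneSet,
                        SignatureModel, ValidationError, pair_token)

#: Unicode minus, as it appears in published coefficient tables.
_UNICODE_MINUS = "−"

_FLOAT_FMT = "%.10g"


def _norm_gene(symbol: str) -> str:
    return symbol.strip().upper()


def load_expression(path: str | Path,
                    groups: str | Path | Mapping[str, str] | pd.Series | None = None,
                    ) -> ExpressionMatrix:
    """Read a genes x samples TSV matrix.

    The first row holds sample ids, the first column gene symbols.  Group
    labels come from ``groups``: a path to a two-column sidecar TSV
    (``sample_id``, ``group``), or a mapping/Series; when omitted every
    sample is labeled ``tumor``.

    Raises a hard error naming the offender on duplicate gene or sample
    ids and on non-numeric cells.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = [s.strip() for s in header[1:]]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ValidationError(f"duplicate sample id in {path.name}: {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.columns = sample_ids
    df.index = [_norm_gene(g) for g in df.index.astype(str)]
    dup = pd.Index(df.index)[pd.Index(df.index).duplicated()]
    if len(dup):
        raise ValidationError(
            f"duplicate gene id in {path.name}: {dup[0]!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric cell in {path.name}: gene {bad.index[0]!r}, "
                f"sample {col!r}, value {bad.iloc[0]!r}")
    df = df.astype(float)

    if groups is None:
        group = pd.Series("tumor", index=df.columns)
    elif isinstance(groups, (str, Path)):
        gtab = pd.read_csv(groups, sep="\t", dtype=str)
        if gtab.shape[1] < 2:
            raise ValidationError(f"group sidecar {groups} needs two columns")
        group = pd.Series(gtab.iloc[:, 1].str.strip().values,
                          index=gtab.iloc[:, 0].str.strip().values)
    else:
        group = pd.Series(dict(groups) if isinstance(groups, Mapping) else groups)
    return ExpressionMatrix(df, group)


def write_expression(em: ExpressionMatrix, path: str | Path,
                     groups_path: str | Path | None = None) -> None:
    em.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                     index_label="gene")
    if groups_path is not None:
        em.group.rename("group").to_frame().to_csv(
            groups_path, sep="\t", index_label="sample_id")


def load_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV (sample_id, time, event, covariates...)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError(f"clinical table {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(ct: ClinicalTable, path: str | Path) -> None:
    ct.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                   index_label="sample_id")


def load_gene_list(path: str | Path, provenance: str = "") -> GeneSet:
    """Read a one-symbol-per-line gene list, deduplicated in order."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = _norm_gene(line)
            if g and g not in seen:
                seen.add(g)
                genes.append(g)
    return GeneSet(genes, provenance=provenance)


def write_gene_list(gs: GeneSet | Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in gs:
            fh.write(f"{g}\n")


def _parse_coefficient(text: str, lineno: int, path: Path) -> float:
    cleaned = text.strip().replace(_UNICODE_MINUS, "-").replace(" ", "")
    try:
        return float(cleaned)
    except ValueError:
        raise ValidationError(
            f"non-numeric coefficient on line {lineno} of {path.name}: {text!r}")


def load_signature(path: str | Path) -> SignatureModel:
    """Read a two-column signature file: pair token ``A|B`` and coefficient.

    Pairs keep file order.  Coefficients may use either the ASCII
    hyphen-minus or the Unicode minus sign found in published tables.  A
    first line whose second field is non-numeric is treated as a header.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    coefs: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ValidationError(
                    f"expected two columns on line {lineno} of {path.name}")
            token, coef_text = fields
            if lineno == 1:
                try:
                    _parse_coefficient(coef_text, lineno, path)
                except ValidationError:
                    continue  # header row
            if token.count("|") != 1:
                raise ValidationError(
                    f"malformed pair token on line {lineno} of {path.name}: "
                    f"{token!r} (expected exactly one '|')")
            a, b = (_norm_gene(g) for g in token.split("|"))
            pairs.append((a, b))
            coefs.append(_parse_coefficient(coef_text, lineno, path))
    if not pairs:
        raise ValidationError(f"no pairs found in {path.name}")
    return SignatureModel(pairs, np.asarray(coefs))


def write_signature(sig: SignatureModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Gene\tCoefficient\n")
        for pair, coef in zip(sig.pairs, sig.coefficients):
            fh.write(f"{pair_token(pair)}\t{_FLOAT_FMT % coef}\n")


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("irgp").joinpath("data", name)))


def load_packaged_signature() -> SignatureModel:
    """The published 17-pair oral-cancer prognostic signature."""
    return load_signature(_data_path("irgp17_signature.tsv"))


def load_packaged_immune_genes() -> GeneSet:
    """A small immune-gene list (signature genes plus common immune genes).

    Stands in for the full ~2,500-gene immune-annotation catalogue, which
    is too large to ship; real analyses should supply their own list.
    """
    return load_gene_list(_data_path("immune_genes.txt"), provenance="immune")
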