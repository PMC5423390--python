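"""Tab-delimited text readers and writers for study components.

All matrices are TSV with a header row and the feature/sample id in the
first column, mirroring GEO series-matrix conventions.  Gene lists are
plain text, one symbol per line, with ``#``-prefixed provenance comments.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AlignmentError,
    DetectionCallMatrix,
    ExpressionMatrix,
    GeneList,
    ProbeAnnotation,
    QcTable,
    Scale,
    StudyBundle,
    StudyDesign,
)

__all__ = [
    "read_study", "write_study",
    "read_expression", "write_expression",
    "read_calls", "write_calls",
    "read_design", "write_design",
    "read_annotation", "write_annotation",
    "read_qc", "write_qc",
    "read_gene_list", "write_gene_list",
]

_FLOAT_FMT = "%.17g"  # full round-trip precision for float64


def _read_table(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", index_col=0, comment="#", **kw)
    except ValueError as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc


def read_expression(path, scale: Scale | str = Scale.LINEAR) -> ExpressionMatrix:
    df = _read_table(path)
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        for col in bad:
            coerced = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[coerced.isna() & df[col].notna()]
            if len(rows):
                raise ValueError(
                    f"non-numeric expression value at row {rows[0]!r}, "
                    f"column {col!r} in {path}")
        df = df.apply(pd.to_numeric)
    return ExpressionMatrix(df.astype(float), Scale(scale))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id",
                         float_format=_FLOAT_FMT)


def read_calls(path) -> DetectionCallMatrix:
    df = _read_table(path, dtype=str)
    return DetectionCallMatrix(df)


def write_calls(calls: DetectionCallMatrix, path) -> None:
    calls.calls.to_csv(path, sep="\t", index_label="feature_id")


def read_design(path) -> StudyDesign:
    df = _read_table(path)
    return StudyDesign(df)


def write_design(design: StudyDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path) -> ProbeAnnotation:
    df = _read_table(path, dtype=str)
    return ProbeAnnotation(df)


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="probe_id")


def read_qc(path) -> QcTable:
    df = _read_table(path)
    return QcTable(df)


def write_qc(qc: QcTable, path) -> None:
    qc.table.to_csv(path, sep="\t", index_label="sample_id",
                    float_format=_FLOAT_FMT)


def read_study(expr_path, calls_path, design_path, annot_path,
               qc_path=None, scale: Scale | str = Scale.LINEAR) -> StudyBundle:
    """Read and cross-validate all study components.

    Raises :class:`AlignmentError` naming the offending ids when the
    components disagree on sample or feature identifiers; QC is optional
    (QC diagnostics are simply unavailable without it).
    """
    return StudyBundle(
        expression=read_expression(expr_path, scale=scale),
        calls=read_calls(calls_path),
        design=read_design(design_path),
        annotation=read_annotation(annot_path),
        qc=read_qc(qc_path) if qc_path is not None else None,
    )


def write_study(bundle: StudyBundle, directory) -> dict[str, Path]:
    """Write all components into *directory*; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "calls": directory / "calls.tsv",
        "design": directory / "design.tsv",
        "annotation": directory / "annotation.tsv",
    }
    write_expression(bundle.expression, paths["expression"])
    write_calls(bundle.calls, paths["calls"])
    write_design(bundle.design, paths["design"])
    write_annotation(bundle.annotation, paths["annotation"])
    if bundle.qc is not None:
        paths["qc"] = directory / "qc.tsv"
        write_qc(bundle.qc, paths["qc"])
    return paths


def write_gene_list(gene_list: GeneList, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if gene_list.provenance:
            for line in gene_list.provenance.splitlines():
                fh.write(f"# {line}\n")
        for symbol in gene_list:
            fh.write(symbol + "\n")


def read_gene_list(path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; ``#`` lines become provenance.

    An empty file yields an empty list with a warning; duplicate lines
    collapse under set semantics, also with a warning.
    """
    path = Path(path)
    provenance: list[str] = []
    symbols: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            provenance.append(line.lstrip("#").strip())
        else:
            symbols.append(line)
    if not symbols:
        warnings.warn(f"gene list file {path} contains no symbols")
    if len(set(symbols)) != len(symbols):
        warnings.warn(f"gene list file {path} contains duplicate symbols; "
                      "collapsing to a set")
    return GeneList(name or path.stem, symbols, "\n".join(provenance))
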