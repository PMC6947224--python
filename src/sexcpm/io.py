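"""Readers and writers for on-disk formats.

Supported inputs: two-column per-sample count files in the HTSeq-count
dialect, a genes × samples count-matrix TSV, a pre-computed CPM matrix TSV,
and a gene → chromosome map as either a GTF/GFF2 annotation or a two-column
TSV.  Output: the per-sample sex report and MDS coordinates.
"""
from __future__ import annotations

import decimal
import os
import re
from collections import Counter

import numpy as np
import pandas as pd

from .types import (
    ChromosomeMap,
    ConsistencyError,
    CountsMatrix,
    CpmMatrix,
    ParseError,
    SexCallTable,
)

HTSEQ_SUMMARY_ROWS = (
    "__no_feature",
    "__ambiguous",
    "__too_low_aQual",
    "__not_aligned",
    "__alignment_not_unique",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (decimal half-up), not banker's rounding."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _sample_id_from_path(path: str) -> str:
    return os.path.splitext(os.path.basename(path))[0]


def _parse_htseq_file(path: str) -> tuple[list[str], list[int], dict[str, int]]:
    genes: list[str] = []
    counts: list[int] = []
    summary: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            gene_id, raw = parts
            try:
                value = int(raw)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer count {raw!r} for {gene_id!r}"
                ) from None
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative count for {gene_id!r}")
            if gene_id.startswith("__"):
                summary[gene_id] = summary.get(gene_id, 0) + value
            else:
                genes.append(gene_id)
                counts.append(value)
    dup = [g for g, k in Counter(genes).items() if k > 1]
    if dup:
        raise ConsistencyError(f"{path}: duplicate gene_id(s): {dup}")
    return genes, counts, summary


def read_htseq_counts(paths: list[str], sample_ids: list[str] | None = None) -> CountsMatrix:
    """Read one HTSeq-count two-column file per sample into a CountsMatrix.

    All files must share the same gene set (HTSeq output over one annotation
    always does); ``__``-prefixed bookkeeping rows are stripped from the gene
    list but retained as per-sample metadata in ``CountsMatrix.summary``.
    Sample ids default to the file basenames without extension.
    """
    if not paths:
        raise ParseError("no input files")
    if sample_ids is None:
        sample_ids = [_sample_id_from_path(p) for p in paths]
    if len(sample_ids) != len(paths):
        raise ConsistencyError(
            f"{len(paths)} files but {len(sample_ids)} sample ids"
        )

    ref_genes: list[str] | None = None
    ref_path = paths[0]
    columns: list[list[int]] = []
    summaries: list[dict[str, int]] = []
    for path in paths:
        genes, counts, summary = _parse_htseq_file(path)
        if ref_genes is None:
            ref_genes = genes
        elif genes != ref_genes:
            diff = sorted(set(genes) ^ set(ref_genes))
            if diff:
                raise ConsistencyError(
                    f"gene sets differ between {ref_path} and {path}; "
                    f"symmetric difference: {diff}"
                )
            raise ConsistencyError(
                f"gene order differs between {ref_path} and {path}"
            )
        columns.append(counts)
        summaries.append(summary)

    counts_df = pd.DataFrame(
        np.column_stack(columns) if columns else [],
        index=pd.Index(ref_genes, name="gene_id"),
        columns=sample_ids,
        dtype=np.int64,
    )
    summary_keys = sorted({k for s in summaries for k in s})
    summary_df = None
    if summary_keys:
        summary_df = pd.DataFrame(
            {sid: [s.get(k, 0) for k in summary_keys] for sid, s in zip(sample_ids, summaries)},
            index=pd.Index(summary_keys, name="summary_row"),
            dtype=np.int64,
        )
    return CountsMatrix(counts_df, summary_df)


def _read_matrix_tsv(path: str) -> pd.DataFrame:
    # pandas silently renames duplicated column headers; check the raw header.
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup = [s for s, k in Counter(header[1:]).items() if k > 1]
    if dup:
        raise ConsistencyError(f"{path}: duplicate sample_id(s): {dup}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error surface varies
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ConsistencyError(f"{path}: duplicate gene_id(s): {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ConsistencyError(f"{path}: duplicate sample_id(s): {dup}")
    return df


def read_counts_matrix(path: str) -> CountsMatrix:
    """Read a genes × samples TSV of integer counts (header row, gene_id first).

    ``__``-prefixed rows are moved to the summary metadata, matching
    :func:`read_htseq_counts`.
    """
    df = _read_matrix_tsv(path)
    values = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for (i, j), cell in np.ndenumerate(raw):
        try:
            v = int(cell)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-integer count {cell!r} at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            ) from None
        if v < 0:
            raise ParseError(
                f"{path}: negative count at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        values[i, j] = v
    full = pd.DataFrame(values, index=df.index, columns=df.columns)
    is_summary = full.index.str.startswith("__")
    summary = None
    if is_summary.any():
        summary = full.loc[is_summary]
        summary.index.name = "summary_row"
    counts = full.loc[~is_summary]
    counts.index.name = "gene_id"
    return CountsMatrix(counts, summary)


def write_counts_matrix(matrix: CountsMatrix, path: str) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    if matrix.summary is not None:
        out = pd.concat([out, matrix.summary])
    out.to_csv(path, sep="\t")


def read_cpm_matrix(path: str) -> CpmMatrix:
    """Read a genes × samples TSV of pre-computed CPM values (no library sizes)."""
    df = _read_matrix_tsv(path)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric CPM cell: {exc}") from None
    return CpmMatrix(values)


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_chrom_map_gtf(path: str) -> ChromosomeMap:
    """Extract gene_id → chromosome from the ``gene`` feature rows of a GTF."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(parts)}")
            if parts[2] != "gene":
                continue
            m = _GTF_GENE_ID.search(parts[8])
            if not m:
                raise ParseError(f"{path}:{lineno}: gene row without gene_id attribute")
            pairs.append((m.group(1), parts[0]))
    if not pairs:
        raise ParseError(f"{path}: no 'gene' feature rows found")
    return ChromosomeMap.from_pairs(pairs)


def read_chrom_map_tsv(path: str) -> ChromosomeMap:
    """Read a two-column (gene_id, chromosome) TSV; a header line is auto-skipped."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            if lineno == 1 and parts[0].lower() in {"gene", "gene_id", "geneid"}:
                continue
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise ParseError(f"{path}: empty chromosome map")
    return ChromosomeMap.from_pairs(pairs)


def read_chrom_map(path: str) -> ChromosomeMap:
    """Dispatch on extension: .gtf/.gff → GTF parser, anything else → TSV."""
    if path.lower().endswith((".gtf", ".gff", ".gff2", ".gff3")):
        return read_chrom_map_gtf(path)
    return read_chrom_map_tsv(path)


def write_chrom_map(chrom_map: ChromosomeMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\n")
        for gene_id, chrom in chrom_map.entries.items():
            fh.write(f"{gene_id}\t{chrom}\n")


def write_sex_report(calls: SexCallTable, path: str) -> None:
    """Write the per-sample report TSV; sigma values carry exactly 2 decimals."""
    with open(path, "w") as fh:
        fh.write("sample_id\tsigma_cpm\tlabel\tn_genes_used\n")
        for row in calls.table.itertuples(index=False):
            fh.write(
                f"{row.sample_id}\t{round_half_up(row.sigma_cpm):.2f}\t"
                f"{row.label}\t{int(row.n_genes_used)}\n"
            )


def read_sex_report(path: str) -> SexCallTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "label": str})
    return SexCallTable(df)
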