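"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as TSV (first column ``gene_id``, one column per
sample), group assignments as a two-column sidecar TSV, gene sets as GMT
and result tables as TSV with a fixed header.  Floats are written at six
significant digits, which defines the round-trip precision contract.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .datatypes import CountMatrix, DataError, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

#: Column order for GSEA result tables on disk.
GSEA_TABLE_COLUMNS = [
    "ID",
    "description",
    "set_size",
    "es",
    "nes",
    "pvalue",
    "p_adjust",
    "qvalue",
    "gene_ratio",
    "leading_edge",
]


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a ``sample_id<TAB>group`` sidecar file into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            sample, group = fields
            if sample == "sample_id":  # optional header
                continue
            if sample in out:
                raise DataError(f"{path}:{lineno}: duplicate sample id {sample!r}")
            out[sample] = group
    return out


def read_count_matrix(
    path: str | Path, group_map: Mapping[str, str] | str | Path
) -> CountMatrix:
    """Read a genes × samples TSV into a :class:`CountMatrix`.

    ``group_map`` is either a mapping or the path of a sidecar TSV.
    Row and column order are preserved from the file.  Duplicate gene
    ids, non-numeric cells and samples absent from the group map are
    hard errors.
    """
    if not isinstance(group_map, Mapping):
        group_map = read_groups(group_map)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise DataError(f"{path}: duplicate gene id {dup[0]!r}")
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        # locate the offending cell for the error message
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise DataError(
                        f"{path}: non-numeric value {v!r} at gene "
                        f"{df.index[i]!r}, sample {col!r}"
                    ) from None
        raise
    missing = [s for s in values.columns if s not in group_map]
    if missing:
        raise DataError(f"{path}: samples not in group map: {missing}")
    return CountMatrix(values, dict(group_map))


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV (floats at 6 significant digits)."""
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_groups(group_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in group_of.items():
            fh.write(f"{sample}\t{group}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (``term<TAB>description<TAB>gene...`` per line).

    Duplicate genes within a set are dropped with a logged warning;
    lines with fewer than three fields and repeated term ids are hard
    errors.
    """
    entries: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: expected >=3 fields, got {len(fields)}")
            term, desc, *genes = fields
            if term in seen:
                raise DataError(f"{path}:{lineno}: duplicate term id {term!r}")
            seen.add(term)
            unique = tuple(dict.fromkeys(g for g in genes if g))
            if len(unique) != len([g for g in genes if g]):
                logger.warning(
                    "%s:%d: dropped %d duplicate gene(s) within set %s",
                    path, lineno, len([g for g in genes if g]) - len(unique), term,
                )
            entries.append(GeneSet(term, desc, unique))
    return GeneSetCollection(tuple(entries))


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in sets:
            fh.write("\t".join([e.term_id, e.description, *e.members]) + "\n")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with deterministic row order.

    Rows are sorted by ascending ``pvalue`` with ties broken by ``ID``
    (when those columns are present); floats are formatted at six
    significant digits.
    """
    if records is None:
        raise DataError("records must not be None")
    df = records.copy()
    if "pvalue" in df.columns and "ID" in df.columns:
        df = df.sort_values(["pvalue", "ID"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
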