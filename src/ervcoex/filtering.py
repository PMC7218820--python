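"""Gene prefilters applied before the co-expression screen.

Two filters run on the normalized matrix, in order: a mean-expression
threshold (a gene's mean over ALL samples, both groups pooled, must be
>= the threshold — boundary inclusive) and an annotation filter (the
gene must appear in at least one gene set).  The analysis target is
exempted from both via a keep-list, since a lowly expressed target
would otherwise be deleted by its own screen.  A report records the
gene counts and the five-number quantile summary of per-gene means
before and after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datatypes import CountMatrix, DataError, GeneSetCollection

logger = logging.getLogger(__name__)

QUANTILE_PROBS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class FilterReport:
    n_before: int
    n_after_expression: int
    n_after_annotation: int
    quantiles_before: tuple[float, ...]
    quantiles_after: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (self.n_before >= self.n_after_expression >= self.n_after_annotation >= 0):
            raise DataError("filter counts must be non-increasing")
        for q in (self.quantiles_before, self.quantiles_after):
            if any(b < a for a, b in zip(q, q[1:])):
                raise DataError("quantile vector must be non-decreasing")


def filter_by_mean_expression(
    matrix: CountMatrix,
    threshold: float = 50.0,
    keep: Iterable[str] = (),
) -> CountMatrix:
    """Retain genes whose mean over all samples is >= *threshold*.

    Genes named in *keep* survive regardless.  The boundary is kept:
    a gene with mean exactly at the threshold passes.
    """
    if threshold < 0:
        raise DataError("threshold must be >= 0")
    keep_set = set(keep)
    means = matrix.values.mean(axis=1)
    mask = (means >= threshold) | matrix.values.index.isin(keep_set)
    if not mask.any():
        logger.warning("mean-expression filter removed every gene")
    return matrix.with_values(matrix.values.loc[mask])


def filter_by_annotation(
    matrix: CountMatrix,
    sets: GeneSetCollection,
    keep: Iterable[str] = (),
) -> CountMatrix:
    """Retain genes that belong to at least one gene set (or the keep-list)."""
    annotated = sets.all_members() | set(keep)
    mask = matrix.values.index.isin(annotated)
    if not mask.any():
        logger.warning("annotation filter removed every gene")
    return matrix.with_values(matrix.values.loc[mask])


def summarize_quantiles(matrix: CountMatrix) -> tuple[float, ...]:
    """Quantiles of per-gene means at (0, .25, .5, .75, 1).

    Uses the linear-interpolation quantile definition (numpy default).
    """
    if matrix.n_genes == 0:
        raise DataError("cannot summarize an empty matrix")
    means = matrix.values.mean(axis=1).to_numpy()
    return tuple(np.quantile(means, QUANTILE_PROBS).tolist())


def apply_filters(
    matrix: CountMatrix,
    sets: GeneSetCollection,
    threshold: float = 50.0,
    keep: Sequence[str] = (),
) -> tuple[CountMatrix, FilterReport]:
    """Run both prefilters and return the filtered matrix with a report."""
    q_before = summarize_quantiles(matrix)
    after_expr = filter_by_mean_expression(matrix, threshold, keep)
    after_annot = filter_by_annotation(after_expr, sets, keep)
    q_after = (
        summarize_quantiles(after_annot)
        if after_annot.n_genes
        else tuple(float("nan") for _ in QUANTILE_PROBS)
    )
    report = FilterReport(
        n_before=matrix.n_genes,
        n_after_expression=after_expr.n_genes,
        n_after_annotation=after_annot.n_genes,
        quantiles_before=q_before,
        quantiles_after=q_after,
    )
    return after_annot, report
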