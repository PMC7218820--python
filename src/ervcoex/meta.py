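"""Over-representation of a term category among top-ranked GSEA terms.

Given the GSEA table sorted by significance, count how many of the
top-k terms belong to a designated category (e.g. the handful of GO
terms describing neutrophil function) and refer the count to the exact
hypergeometric distribution over the full term vocabulary.  Both tail
conventions are reported: the inclusive P(X >= x) is the default
statistical report; the strictly-greater P(X > x) is the upper-tail
default of much survival-function software and is labelled as such.
The universe size is always caller-supplied because it changes the
p-value by orders of magnitude and must be auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .datatypes import DataError


@dataclass(frozen=True)
class MetaTestResult:
    n_universe: int
    n_category: int
    k_window: int
    x_observed: int
    p_strict: float
    p_inclusive: float

    def __post_init__(self) -> None:
        if not (
            0 <= self.x_observed <= min(self.n_category, self.k_window) <= self.n_universe
        ):
            raise DataError("hypergeometric parameters violate their bounds")
        if not (0 <= self.p_strict <= self.p_inclusive <= 1):
            raise DataError("require 0 <= P(X > x) <= P(X >= x) <= 1")


def hypergeometric_tail(
    n_universe: int,
    n_category: int,
    k_window: int,
    x: int,
    strict: bool = False,
) -> float:
    """Exact hypergeometric upper-tail probability.

    P(X > x) when ``strict``, else P(X >= x), for X = number of
    category terms among ``k_window`` draws without replacement from a
    universe of ``n_universe`` terms of which ``n_category`` are in the
    category.  Evaluated exactly (log-space internals); no normal
    approximation.
    """
    if not (0 <= n_category <= n_universe and 0 <= k_window <= n_universe):
        raise DataError("impossible hypergeometric parameters")
    if not (0 <= x <= min(n_category, k_window)):
        raise DataError(f"x={x} outside [0, min(K, k)]")
    dist = stats.hypergeom(M=n_universe, n=n_category, N=k_window)
    return float(dist.sf(x)) if strict else float(dist.sf(x - 1))


def top_k_category_test(
    table: pd.DataFrame,
    category_ids: set[str],
    n_universe: int,
    k: int = 20,
) -> MetaTestResult:
    """Hypergeometric over-representation of a category in the top-k terms.

    ``table`` must be a GSEA result frame already sorted by ascending
    p-value (ties by ID), as produced by :func:`ervcoex.gsea.run_gsea`.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    if k > len(table):
        raise DataError(f"k={k} exceeds table length {len(table)}")
    if n_universe < len(table):
        raise DataError("n_universe must cover every tested term")
    top = set(table["ID"].iloc[:k])
    x = len(top & set(category_ids))
    return MetaTestResult(
        n_universe=n_universe,
        n_category=len(category_ids),
        k_window=k,
        x_observed=x,
        p_strict=hypergeometric_tail(n_universe, len(category_ids), k, x, strict=True),
        p_inclusive=hypergeometric_tail(
            n_universe, len(category_ids), k, x, strict=False
        ),
    )
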