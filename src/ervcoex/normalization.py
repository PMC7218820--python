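"""Median-of-ratios ("geometric") library-size normalization.

For each sample j the size factor is the median, over reference genes,
of count[i, j] / geomean_i, where geomean_i is the geometric mean of
gene i across all samples.  Reference genes are those with a strictly
positive count in every sample (a zero anywhere sends the geometric
mean to zero and removes the gene from the reference set).  Factors are
not rescaled afterwards: what the median returns is what is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .datatypes import CountMatrix, DataError


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive scaling constants."""

    factor_of: Mapping[str, float]

    def __post_init__(self) -> None:
        for sample, f in self.factor_of.items():
            if not (np.isfinite(f) and f > 0):
                raise DataError(f"size factor for {sample!r} must be finite and > 0")

    def __getitem__(self, sample: str) -> float:
        return self.factor_of[sample]


def compute_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factor per sample.

    Raises
    ------
    DataError
        If no gene is positive in every sample (no reference gene).
    """
    arr = counts.values.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise DataError(
            "no gene has strictly positive counts in every sample; "
            "prefilter all-zero/low genes before normalizing"
        )
    ref = arr[positive]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    return SizeFactors(dict(zip(counts.sample_ids, factors.tolist())))


def normalize_counts(counts: CountMatrix, factors: SizeFactors) -> CountMatrix:
    """Divide each sample column by its size factor; order preserved."""
    missing = [s for s in counts.sample_ids if s not in factors.factor_of]
    if missing:
        raise DataError(f"missing size factor for samples: {missing}")
    fvec = np.array([factors[s] for s in counts.sample_ids], dtype=float)
    out = counts.values.astype(float) / fvec
    return counts.with_values(out)
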