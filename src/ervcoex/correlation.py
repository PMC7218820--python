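"""Per-group Pearson co-expression screen against a target feature.

Every gene is correlated with the target's expression across one
group's samples.  Significance uses the exact small-sample transform
t = r * sqrt(n-2) / sqrt(1-r^2) referred to Student's t with n-2
degrees of freedom (two-sided).  Genes with zero variance within the
group have no defined correlation; they are reported with r = NaN and
excluded from downstream ranking rather than silently given a rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, DataError


class UndefinedCorrelationError(DataError):
    """A correlation was requested for a zero-variance vector."""


@dataclass(frozen=True)
class CorrelationTable:
    """Per-gene correlation screen results for one sample group.

    ``frame`` has columns gene_id, r, t, p, n (one row per non-target
    gene; r/t/p are NaN for zero-variance genes).
    """

    group: str
    target_id: str
    frame: pd.DataFrame

    def defined(self) -> pd.DataFrame:
        """Rows with a defined correlation."""
        return self.frame[self.frame["r"].notna()]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DataError("x and y must be 1-D vectors of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return float(np.clip(r, -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n (t transform, n-2 df)."""
    if n < 3:
        raise DataError("need n >= 3 samples")
    if abs(r) > 1:
        raise DataError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_matrix(
    matrix: CountMatrix, target_id: str, group: str
) -> CorrelationTable:
    """Correlate every non-target gene with the target within one group."""
    if target_id not in matrix.values.index:
        raise DataError(f"target {target_id!r} not in matrix")
    samples = matrix.samples_in_group(group)
    n = len(samples)
    if n < 3:
        raise DataError(f"group {group!r} has fewer than 3 samples")
    sub = matrix.values[samples]
    target = sub.loc[target_id].to_numpy(dtype=float)
    if np.ptp(target) == 0:
        raise UndefinedCorrelationError(
            f"target {target_id!r} has zero variance in group {group!r}"
        )
    genes = sub.drop(index=target_id)
    arr = genes.to_numpy(dtype=float)

    tc = target - target.mean()
    gc = arr - arr.mean(axis=1, keepdims=True)
    ss_g = (gc * gc).sum(axis=1)
    denom = np.sqrt(ss_g * np.dot(tc, tc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ss_g > 0, (gc @ tc) / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)

    frame = pd.DataFrame(
        {
            "gene_id": genes.index,
            "r": r,
            "t": tstat,
            "p": p,
            "n": n,
        }
    ).reset_index(drop=True)
    return CorrelationTable(group=group, target_id=target_id, frame=frame)


def strong_gene_sets(
    table: CorrelationTable, threshold: float = 0.7, signed: bool = False
) -> set[str]:
    """Genes whose correlation magnitude reaches *threshold*.

    By default both signs count (|r| >= threshold); with ``signed=True``
    only positive correlations r >= threshold qualify.
    """
    if not (0 < threshold <= 1):
        raise DataError("threshold must be in (0, 1]")
    d = table.defined()
    score = d["r"] if signed else d["r"].abs()
    return set(d.loc[score >= threshold, "gene_id"])


def overlap_strong_sets(a: set[str], b: set[str]) -> tuple[int, int, int, set[str]]:
    """(|a|, |b|, |a ∩ b|, a ∩ b)."""
    inter = set(a) & set(b)
    return len(a), len(b), len(inter), inter


def qq_normal_points(values: np.ndarray) -> np.ndarray:
    """Normal Q-Q coordinates for a sample, for a normality diagnostic.

    The sample is standardized to mean 0 / sd 1 and its order statistics
    are paired with standard-normal quantiles at plotting positions
    (i - 0.5) / n.  Returns an (n, 2) array of (theoretical, sample)
    pairs; both columns are non-decreasing.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise DataError("need a 1-D sample of length >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        raise UndefinedCorrelationError("zero variance sample")
    z = np.sort((v - v.mean()) / sd)
    n = len(z)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([theo, z])
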