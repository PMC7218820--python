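"""Preranked gene-set enrichment analysis (GSEA).

The statistic is the classic weighted Kolmogorov-Smirnov-like running
sum: walking the ranked list, a member gene adds |score|^w / N_R
(N_R = sum of member |score|^w) and a non-member subtracts
1 / (N - N_hits); the enrichment score (ES) is the running sum's value
of maximal absolute deviation from zero.  The null is a gene-label
permutation: with only seven samples per group a phenotype permutation
cannot supply a large permutation count (7! = 5040), so random
equal-size member placements are the only consistent null.  P-values
are one-sided by ES sign with add-one smoothing; the normalized ES
divides by the mean same-sign null ES.  Multiplicity is handled by
Benjamini-Hochberg step-up adjustment plus a fixed-lambda Storey
q-value.

Null placements are drawn by permuting the gene labels of the ranked
list, a draw shared across sets within a batch; each set's member
positions under one permutation are a uniform random size-s subset of
the list, which is exactly the stated null for every set marginally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .correlation import CorrelationTable
from .datatypes import DataError, GeneSetCollection


@dataclass(frozen=True)
class GseaConfig:
    """Tuning parameters of the preranked GSEA run.

    Defaults mirror a conventional GO biological-process analysis:
    gene sets with 25-500 members after restriction to the analyzed
    universe, 100,000 label permutations, weight exponent 1 and a 0.05
    adjusted-p significance level.
    """

    n_perm: int = 100_000
    min_size: int = 25
    max_size: int = 500
    weight_exponent: float = 1.0
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.min_size <= self.max_size):
            raise DataError("require 0 < min_size <= max_size")
        if self.n_perm < 1:
            raise DataError("n_perm must be >= 1")


@dataclass(frozen=True)
class RankedGeneList:
    """Genes in descending score order with deterministic tie order."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise DataError("ids and scores must have equal length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene in ranked list")
        s = np.asarray(self.scores, dtype=float)
        if s.size and not np.isfinite(s).all():
            raise DataError("scores must be finite")
        if np.any(np.diff(s) > 0):
            raise DataError("scores must be non-increasing")
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def positions_of(self, members: Iterable[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        return np.sort([index[g] for g in members if g in index])


def build_ranked_list(table: CorrelationTable) -> RankedGeneList:
    """Rank genes by signed correlation, descending; ties by gene id.

    Zero-variance genes (undefined r) are excluded; the target itself is
    already absent from the correlation table.
    """
    d = table.defined()
    if d.empty:
        raise DataError("correlation table has no defined correlations")
    if d["gene_id"].duplicated().any():
        dup = d.loc[d["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise DataError(f"duplicate gene {dup!r} in correlation table")
    d = d.sort_values(["r", "gene_id"], ascending=[False, True], kind="mergesort")
    return RankedGeneList(tuple(d["gene_id"]), d["r"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------


def enrichment_score(
    ranked: RankedGeneList,
    members: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, int, list[str]]:
    """Running-sum enrichment score of one gene set.

    Returns ``(es, running_sum, peak_index, leading_edge)`` where
    ``running_sum[i]`` is the value after processing position ``i`` and
    ``peak_index`` is the position at which |running_sum| is maximal.
    The leading edge contains the member genes at or before the peak
    for a positive ES, at or after it for a negative ES.
    """
    n = len(ranked)
    member_set = set(members)
    hit = np.fromiter((g in member_set for g in ranked.gene_ids), bool, count=n)
    n_hits = int(hit.sum())
    if n_hits == 0 or n_hits == n:
        raise DataError("gene set must hit a strict, non-empty subset of the list")
    w = np.abs(ranked.scores) ** weight_exponent
    nr = w[hit].sum()
    if nr == 0:
        raise DataError("member scores are all zero; running sum undefined")
    steps = np.where(hit, w / nr, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    hi = float(running.max())
    lo = float(running.min())
    # maximal absolute deviation; an exact +/- tie resolves positive
    es = hi if hi >= -lo else lo
    peak = int(np.argmax(running == es))
    if es >= 0:
        edge_mask = hit & (np.arange(n) <= peak)
    else:
        edge_mask = hit & (np.arange(n) >= peak)
    leading = [g for g, m in zip(ranked.gene_ids, edge_mask) if m]
    return es, running, peak, leading


def _es_batch(
    positions: np.ndarray, score_w: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many size-s member placements.

    ``positions`` is (B, s), each row sorted ascending; ``score_w`` is
    the length-n vector |score|^w of the ranked list.  Only the hit
    positions are needed: between consecutive hits the running sum
    decays linearly, so its extremes occur immediately after a hit
    (maxima) or immediately before one (minima).
    """
    b, s = positions.shape
    w = score_w[positions]
    cumw = np.cumsum(w, axis=1)
    nr = cumw[:, -1:]
    miss = (positions - np.arange(s)) / (n - s)
    after = cumw / nr - miss
    before = (cumw - w) / nr - miss
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def permutation_pvalues(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    config: GseaConfig,
) -> pd.DataFrame:
    """Gene-label permutation p-values and null summaries per set.

    Sets are assumed already restricted to the size bounds.  Returns a
    frame with columns ID, es, pvalue, pvalue_pooled, null_pos_mean,
    null_neg_mean (mean positive null ES and mean |negative| null ES,
    NaN when the sign never occurred).

    Two p-value conventions are reported, both one-sided by the sign of
    the observed ES and add-one smoothed.  ``pvalue`` refers the
    observed ES to the same-sign portion of the null (the convention of
    the original GSEA methodology); it is calibrated, i.e. uniform
    under the null, and is the value used downstream.  ``pvalue_pooled``
    divides the same exceedance count by the total permutation count;
    it is the tail mass of the full signed null, roughly half the
    calibrated value, and is kept because some tools report it.
    """
    if config.n_perm < 1:
        raise DataError("n_perm must be >= 1")
    n = len(ranked)
    score_w = np.abs(ranked.scores) ** config.weight_exponent
    rng = np.random.default_rng(config.seed)

    observed = {}
    member_idx = {}
    for entry in sets:
        pos = ranked.positions_of(entry.members)
        es, _, _, _ = enrichment_score(ranked, entry.members, config.weight_exponent)
        observed[entry.term_id] = es
        member_idx[entry.term_id] = pos

    counts = {t: 0 for t in observed}
    portion_n = {t: 0 for t in observed}  # null draws sharing the observed sign
    pos_sum = {t: 0.0 for t in observed}
    pos_n = {t: 0 for t in observed}
    neg_sum = {t: 0.0 for t in observed}
    neg_n = {t: 0 for t in observed}

    chunk = max(1, min(config.n_perm, int(5e6 // max(n, 1))))
    done = 0
    while done < config.n_perm:
        b = min(chunk, config.n_perm - done)
        # rank of each gene label under b random permutations of the list
        ranks = rng.random((b, n)).argsort(axis=1).argsort(axis=1)
        for term, idx in member_idx.items():
            null_pos = np.sort(ranks[:, idx], axis=1)
            null_es = _es_batch(null_pos, score_w, n)
            obs = observed[term]
            if obs >= 0:
                counts[term] += int((null_es >= obs).sum())
                portion_n[term] += int((null_es >= 0).sum())
            else:
                counts[term] += int((null_es <= obs).sum())
                portion_n[term] += int((null_es < 0).sum())
            p_mask = null_es > 0
            pos_sum[term] += float(null_es[p_mask].sum())
            pos_n[term] += int(p_mask.sum())
            n_mask = null_es < 0
            neg_sum[term] += float(-null_es[n_mask].sum())
            neg_n[term] += int(n_mask.sum())
        done += b

    rows = []
    for entry in sets:
        t = entry.term_id
        rows.append(
            {
                "ID": t,
                "es": observed[t],
                "pvalue": (1 + counts[t]) / (1 + portion_n[t]),
                "pvalue_pooled": (1 + counts[t]) / (1 + config.n_perm),
                "null_pos_mean": pos_sum[t] / pos_n[t] if pos_n[t] else np.nan,
                "null_neg_mean": neg_sum[t] / neg_n[t] if neg_n[t] else np.nan,
            }
        )
    return pd.DataFrame(rows)


def normalize_es(es: float, null_pos_mean: float, null_neg_mean: float) -> float:
    """NES: ES divided by the mean same-sign null ES (absolute value).

    Returns NaN when the matching sign never occurred in the null.
    """
    if es == 0:
        return 0.0
    denom = null_pos_mean if es > 0 else null_neg_mean
    if denom is None or not np.isfinite(denom) or denom == 0:
        return float("nan")
    return float(es / denom)


# ---------------------------------------------------------------------------
# Multiplicity
# ---------------------------------------------------------------------------


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Fixed-lambda (0.5) Storey q-values: q_i = pi0_hat * BH_i.

    pi0_hat = #{p > 0.5} / (0.5 m), clamped to [1/m, 1].  This is the
    simple one-point version of the q-value estimator; the spline
    smoother over a lambda grid is deliberately not implemented.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    bh = adjust_bh(p)
    m = p.size
    pi0 = (p > 0.5).sum() / (0.5 * m)
    pi0 = min(1.0, max(1.0 / m, pi0))
    return pi0 * bh


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_gsea(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    config: GseaConfig | None = None,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Each set is restricted to genes present in the ranked list and kept
    when its restricted size lies in [min_size, max_size].  The result
    frame has one row per tested set with columns ID, description,
    set_size, es, nes, pvalue, p_adjust, qvalue, gene_ratio,
    leading_edge (comma-joined) and significant, sorted by ascending
    pvalue with ties broken by ID.
    """
    config = config or GseaConfig()
    present = set(ranked.gene_ids)
    tested = []
    restricted = {}
    for entry in sets:
        members = tuple(g for g in entry.members if g in present)
        if config.min_size <= len(members) <= config.max_size and len(members) < len(
            ranked
        ):
            tested.append(entry)
            restricted[entry.term_id] = members
    if not tested:
        import logging

        logging.getLogger(__name__).warning(
            "no gene set within size bounds [%d, %d]", config.min_size, config.max_size
        )
        return pd.DataFrame(
            columns=[
                "ID", "description", "set_size", "es", "nes", "pvalue",
                "p_adjust", "qvalue", "gene_ratio", "leading_edge",
                "pvalue_pooled", "significant",
            ]
        )

    sub = GeneSetCollection(
        tuple(
            type(e)(e.term_id, e.description, restricted[e.term_id]) for e in tested
        )
    )
    perm = permutation_pvalues(ranked, sub, config).set_index("ID")

    rows = []
    for entry in sub:
        es, _, _, leading = enrichment_score(
            ranked, entry.members, config.weight_exponent
        )
        rec = perm.loc[entry.term_id]
        nes = normalize_es(es, rec["null_pos_mean"], rec["null_neg_mean"])
        rows.append(
            {
                "ID": entry.term_id,
                "description": entry.description,
                "set_size": entry.size,
                "es": es,
                "nes": nes,
                "pvalue": rec["pvalue"],
                "pvalue_pooled": rec["pvalue_pooled"],
                "leading_edge": ",".join(leading),
                "gene_ratio": len(leading) / entry.size,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjust"] = adjust_bh(out["pvalue"])
    out["qvalue"] = storey_qvalues(out["pvalue"])
    out["significant"] = out["p_adjust"] < config.alpha
    out = out.sort_values(["pvalue", "ID"], kind="mergesort").reset_index(drop=True)
    return out[
        [
            "ID", "description", "set_size", "es", "nes", "pvalue",
            "p_adjust", "qvalue", "gene_ratio", "leading_edge",
            "pvalue_pooled", "significant",
        ]
    ]
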