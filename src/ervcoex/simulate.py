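"""Synthetic two-group RNA-seq studies with planted co-expression.

The generator emulates the design this pipeline targets: two groups of
seven samples, a few thousand genes, one lowly-but-variably expressed
target feature whose group means differ by a configurable fold (1.3 by
default), and a handful of "planted" gene sets whose members co-vary
with the target in one group only.  Counts are negative-binomial
(gamma-Poisson) around log-uniform gene baselines; co-expression is
induced through a shared latent — the target's standardized realized
value z — entering the member genes' log-mean as ``base + beta * z`` in
the planted group.  Everything is reproducible from a single seed via
numpy SeedSequence spawning, so per-module tests can regenerate
sub-streams.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from typing import Mapping

import numpy as np
import pandas as pd

from .correlation import CorrelationTable, strong_gene_sets
from .datatypes import CountMatrix, DataError, GeneSet, GeneSetCollection


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    ``coexpr_strength`` is the log-scale slope beta of planted member
    genes on the standardized target; ``target_fold`` the old/young
    ratio of target means; ``target_location`` the target's mean count
    level in the reference (second) group; ``dispersion`` the
    negative-binomial dispersion (variance = mu + dispersion * mu^2,
    0 gives Poisson).
    """

    seed: int = 0
    n_per_group: int = 7
    n_genes: int = 2000
    n_sets: int = 50
    set_size_range: tuple[int, int] = (30, 60)
    n_planted_sets: int = 2
    coexpr_strength: float = 1.0
    planted_group: str = "old"
    target_fold: float = 1.3
    baseline_log_mean_range: tuple[float, float] = (4.2, 8.0)
    dispersion: float = 0.1
    target_location: float = 40.0
    group_labels: tuple[str, str] = ("old", "young")
    target_id: str = "ERVK-7"

    def __post_init__(self) -> None:
        if self.n_planted_sets > self.n_sets:
            raise DataError("n_planted_sets must be <= n_sets")
        lo, hi = self.set_size_range
        if not (0 < lo <= hi):
            raise DataError("invalid set_size_range")
        if self.coexpr_strength < 0:
            raise DataError("coexpr_strength must be >= 0")
        if self.dispersion < 0:
            raise DataError("dispersion must be >= 0")
        if self.planted_group not in self.group_labels:
            raise DataError("planted_group must be one of group_labels")
        if self.n_planted_sets * hi > self.n_genes:
            raise DataError("planted sets cannot exceed the gene pool")

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "SyntheticConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("set_size_range", "baseline_log_mean_range", "group_labels"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated study."""

    planted_set_ids: tuple[str, ...]
    planted_genes_of: Mapping[str, tuple[str, ...]]
    associated_of_group: Mapping[str, frozenset[str]]
    gene_ids: tuple[str, ...]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson negative binomial with variance mu + dispersion*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def generate_study(
    config: SyntheticConfig,
) -> tuple[CountMatrix, GeneSetCollection, SyntheticTruth]:
    """Generate a count matrix, gene-set collection and ground truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_target, rng_base, rng_sets, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    g1, g2 = config.group_labels
    samples = [f"{g1}_{i+1}" for i in range(config.n_per_group)] + [
        f"{g2}_{i+1}" for i in range(config.n_per_group)
    ]
    group_of = {s: (g1 if s.startswith(f"{g1}_") else g2) for s in samples}
    genes = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]

    # target feature: NB around group means with ratio target_fold (first
    # group over second group)
    mu_ref = config.target_location
    mus = np.array(
        [mu_ref * config.target_fold] * config.n_per_group
        + [mu_ref] * config.n_per_group
    )
    target = _nb_draw(rng_target, mus, config.dispersion).astype(float)
    # standardized realized target, within each group separately
    z = np.zeros_like(target)
    for lo, hi in ((0, config.n_per_group), (config.n_per_group, 2 * config.n_per_group)):
        seg = target[lo:hi]
        sd = seg.std(ddof=1)
        if sd == 0:
            raise DataError("degenerate target draw (zero variance); change seed")
        z[lo:hi] = (seg - seg.mean()) / sd

    # gene-set structure: planted sets claim disjoint member pools first
    lo_s, hi_s = config.set_size_range
    planted_sets: dict[str, tuple[str, ...]] = {}
    pool = np.array(genes)
    rng_sets.shuffle(pool)
    cursor = 0
    for i in range(config.n_planted_sets):
        size = int(rng_sets.integers(lo_s, hi_s + 1))
        members = tuple(pool[cursor : cursor + size])
        cursor += size
        planted_sets[f"PLANTED:{i+1:03d}"] = members
    planted_genes = tuple(pool[:cursor])
    other_pool = pool[cursor:]

    entries = [
        GeneSet(term, f"planted co-expression module {term.split(':')[1]}", members)
        for term, members in planted_sets.items()
    ]
    for i in range(config.n_sets - config.n_planted_sets):
        size = int(rng_sets.integers(lo_s, hi_s + 1))
        if size > len(other_pool):
            raise DataError("set size exceeds the non-planted gene pool")
        members = tuple(rng_sets.choice(other_pool, size=size, replace=False))
        entries.append(GeneSet(f"RANDOM:{i+1:03d}", f"random gene set {i+1}", members))
    collection = GeneSetCollection(tuple(entries))

    # counts: log-uniform baselines; planted members tilt with beta*z in
    # the planted group only
    lo_b, hi_b = config.baseline_log_mean_range
    base = rng_base.uniform(lo_b, hi_b, size=config.n_genes)
    planted_mask = np.isin(genes, planted_genes)
    planted_cols = np.array([group_of[s] == config.planted_group for s in samples])

    log_mu = base[:, None] + np.zeros((config.n_genes, len(samples)))
    beta = config.coexpr_strength
    if beta > 0:
        log_mu[np.ix_(planted_mask, planted_cols)] += beta * z[planted_cols]
    counts = _nb_draw(rng_counts, np.exp(log_mu), config.dispersion)

    values = pd.DataFrame(counts, index=genes, columns=samples, dtype=float)
    values.loc[config.target_id] = np.round(target)
    matrix = CountMatrix(values, group_of)

    associated = {
        g: frozenset(planted_genes)
        if (g == config.planted_group and beta > 0)
        else frozenset()
        for g in config.group_labels
    }
    truth = SyntheticTruth(
        planted_set_ids=tuple(planted_sets),
        planted_genes_of={t: m for t, m in planted_sets.items()},
        associated_of_group=associated,
        gene_ids=tuple(genes),
    )
    return matrix, collection, truth


@dataclass(frozen=True)
class RecoveryReport:
    """How well the pipeline recovered a study's planted structure."""

    group: str
    sensitivity: float
    specificity: float
    n_planted_in_universe: int
    planted_rank_of: Mapping[str, int]
    planted_significant_of: Mapping[str, bool]


def evaluate_recovery(
    truth: SyntheticTruth,
    corr: CorrelationTable,
    gsea_table: pd.DataFrame,
    threshold: float = 0.7,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Sensitivity/specificity of the strong-gene screen and planted-set
    positions in the GSEA table, judged against the generated truth."""
    universe = set(corr.frame["gene_id"])
    if not universe <= set(truth.gene_ids):
        raise DataError("correlation table contains genes outside the study")
    positives = truth.associated_of_group.get(corr.group, frozenset()) & universe
    negatives = universe - positives
    selected = strong_gene_sets(corr, threshold)
    tp = len(selected & positives)
    tn = len(negatives - selected)
    sensitivity = tp / len(positives) if positives else float("nan")
    specificity = tn / len(negatives) if negatives else float("nan")

    rank_of = {}
    signif_of = {}
    ids = list(gsea_table["ID"])
    for term in truth.planted_set_ids:
        if term in ids:
            i = ids.index(term)
            rank_of[term] = i + 1
            signif_of[term] = bool(gsea_table["p_adjust"].iloc[i] < alpha)
    return RecoveryReport(
        group=corr.group,
        sensitivity=sensitivity,
        specificity=specificity,
        n_planted_in_universe=len(positives),
        planted_rank_of=rank_of,
        planted_significant_of=signif_of,
    )
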