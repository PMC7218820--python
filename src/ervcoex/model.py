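"""Model/Results interface tying the pipeline stages together.

:class:`CoexpressionStudy` is constructed from a count matrix, a
gene-set collection and the identifier of the target feature; its
:meth:`~CoexpressionStudy.fit` runs normalization, filtering, the
per-group correlation screen, preranked GSEA and (optionally) the
top-k category over-representation test, and returns a
:class:`CoexpressionResults` holding every intermediate table, with a
``summary()`` and a ``save()`` that writes the artifact directory and
a run manifest.  Identical inputs, configuration and seed produce
identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io
from .correlation import (
    CorrelationTable,
    correlate_matrix,
    overlap_strong_sets,
    strong_gene_sets,
)
from .datatypes import CountMatrix, DataError, GeneSetCollection
from .filtering import FilterReport, apply_filters
from .gsea import GseaConfig, build_ranked_list, run_gsea
from .meta import MetaTestResult, top_k_category_test
from .normalization import SizeFactors, compute_size_factors, normalize_counts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end analysis settings.

    ``corr_threshold`` is the |r| cut defining "strong" co-expression,
    ``mean_threshold`` the normalized mean-count prefilter, ``meta_k``
    the top-k window of the category over-representation test and
    ``n_universe`` its term-vocabulary size (the full vocabulary the
    category was counted against, not merely the tested sets).
    """

    target_id: str
    corr_threshold: float = 0.7
    mean_threshold: float = 50.0
    gsea: GseaConfig = field(default_factory=GseaConfig)
    meta_k: int = 20
    n_universe: int | None = None
    groups: tuple[str, ...] | None = None
    signed_strong: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.corr_threshold <= 1):
            raise DataError("corr_threshold must be in (0, 1]")
        if self.mean_threshold < 0:
            raise DataError("mean_threshold must be >= 0")
        if self.meta_k < 1:
            raise DataError("meta_k must be >= 1")


class CoexpressionStudy:
    """Co-expression + enrichment analysis of one target feature.

    Parameters
    ----------
    counts : CountMatrix
        Raw counts, genes × samples, with a two-group sample labelling.
    gene_sets : GeneSetCollection
        The annotation collection used for filtering and GSEA.
    config : PipelineConfig
        Analysis settings; ``config.target_id`` must name a matrix row.
    category_ids : set of str, optional
        Term ids forming the category of the top-k over-representation
        test; requires ``config.n_universe``.
    """

    def __init__(
        self,
        counts: CountMatrix,
        gene_sets: GeneSetCollection,
        config: PipelineConfig,
        category_ids: set[str] | None = None,
    ) -> None:
        if config.target_id not in counts.values.index:
            raise DataError(f"target {config.target_id!r} not in count matrix")
        if category_ids and config.n_universe is None:
            raise DataError("category test requires an explicit n_universe")
        self.counts = counts
        self.gene_sets = gene_sets
        self.config = config
        self.category_ids = set(category_ids or ())

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        groups_path: str | Path,
        gmt_path: str | Path,
        config: PipelineConfig,
        category_path: str | Path | None = None,
    ) -> "CoexpressionStudy":
        counts = io.read_count_matrix(counts_path, groups_path)
        sets = io.read_gmt(gmt_path)
        category = None
        if category_path is not None:
            category = {
                line.strip()
                for line in open(category_path)
                if line.strip() and not line.startswith("#")
            }
        return cls(counts, sets, config, category)

    def fit(self) -> "CoexpressionResults":
        t0 = time.perf_counter()
        cfg = self.config
        factors = compute_size_factors(self.counts)
        normalized = normalize_counts(self.counts, factors)
        filtered, report = apply_filters(
            normalized,
            self.gene_sets,
            threshold=cfg.mean_threshold,
            keep=(cfg.target_id,),
        )
        groups = cfg.groups or tuple(self.counts.groups)
        correlations: dict[str, CorrelationTable] = {}
        gsea_tables: dict[str, pd.DataFrame] = {}
        meta: dict[str, MetaTestResult] = {}
        strong: dict[str, set[str]] = {}
        for group in groups:
            corr = correlate_matrix(filtered, cfg.target_id, group)
            correlations[group] = corr
            strong[group] = strong_gene_sets(
                corr, cfg.corr_threshold, signed=cfg.signed_strong
            )
            ranked = build_ranked_list(corr)
            table = run_gsea(ranked, self.gene_sets, cfg.gsea)
            gsea_tables[group] = table
            if self.category_ids and len(table) >= cfg.meta_k:
                meta[group] = top_k_category_test(
                    table, self.category_ids, cfg.n_universe, cfg.meta_k
                )
        overlap = None
        if len(groups) == 2:
            overlap = overlap_strong_sets(strong[groups[0]], strong[groups[1]])
        return CoexpressionResults(
            config=cfg,
            groups=tuple(groups),
            size_factors=factors,
            filter_report=report,
            filtered=filtered,
            correlations=correlations,
            strong=strong,
            overlap=overlap,
            gsea_tables=gsea_tables,
            meta=meta,
            wall_seconds=time.perf_counter() - t0,
        )


@dataclass(frozen=True)
class CoexpressionResults:
    """Everything one fitted study produced."""

    config: PipelineConfig
    groups: tuple[str, ...]
    size_factors: SizeFactors
    filter_report: FilterReport
    filtered: CountMatrix
    correlations: Mapping[str, CorrelationTable]
    strong: Mapping[str, set[str]]
    overlap: tuple[int, int, int, set[str]] | None
    gsea_tables: Mapping[str, pd.DataFrame]
    meta: Mapping[str, MetaTestResult]
    wall_seconds: float

    def summary(self, top: int = 10) -> str:
        """Human-readable account of the fitted study."""
        cfg = self.config
        lines = [
            "Provirus co-expression study",
            "=" * 60,
            f"target feature     : {cfg.target_id}",
            f"genes analyzed     : {self.filter_report.n_after_annotation} "
            f"(of {self.filter_report.n_before} before filtering)",
            f"strong |r| cut     : {cfg.corr_threshold}",
        ]
        for g in self.groups:
            n = len(self.correlations[g].frame)
            lines.append(
                f"group {g!r}: {n} genes screened, "
                f"{len(self.strong[g])} strong correlators"
            )
        if self.overlap is not None:
            a, b, inter, _ = self.overlap
            lines.append(
                f"strong-set overlap : |{self.groups[0]}|={a}, "
                f"|{self.groups[1]}|={b}, shared={inter}"
            )
        for g in self.groups:
            table = self.gsea_tables[g]
            lines.append("")
            lines.append(f"GSEA, group {g!r} ({len(table)} sets tested), top {top}:")
            if len(table):
                view = table.head(top)[
                    ["ID", "set_size", "es", "nes", "pvalue", "p_adjust", "gene_ratio"]
                ].copy()
                view["gene_ratio"] = (view["gene_ratio"] * 100).round().astype(int).astype(
                    str
                ) + "%"
                lines.append(view.to_string(index=False))
            if g in self.meta:
                m = self.meta[g]
                lines.append(
                    f"category in top-{m.k_window}: x={m.x_observed} of "
                    f"K={m.n_category} (universe {m.n_universe}); "
                    f"P(X>=x)={m.p_inclusive:.3g}, P(X>x)={m.p_strict:.3g}"
                )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> Path:
        """Write all result tables, the report and a run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "complete": False,
            "config": _config_dict(self.config),
            "versions": _versions(),
            "wall_seconds": self.wall_seconds,
        }
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        io.write_count_matrix(self.filtered, outdir / "filtered.tsv")
        factors = pd.DataFrame(
            {
                "sample_id": list(self.size_factors.factor_of),
                "size_factor": list(self.size_factors.factor_of.values()),
            }
        )
        factors.to_csv(outdir / "size_factors.tsv", sep="\t", index=False)
        rep = self.filter_report
        pd.DataFrame(
            {
                "stage": ["before", "after_expression", "after_annotation"],
                "n_genes": [rep.n_before, rep.n_after_expression, rep.n_after_annotation],
            }
        ).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        for g in self.groups:
            corr = self.correlations[g].frame
            corr.to_csv(outdir / f"correlation_{g}.tsv", sep="\t", index=False,
                        float_format="%.6g")
            io.write_table(self.gsea_tables[g], outdir / f"gsea_{g}.tsv")
        if self.overlap is not None:
            a, b, inter, shared = self.overlap
            with open(outdir / "overlap.tsv", "w") as fh:
                fh.write("n_a\tn_b\tn_shared\tshared_genes\n")
                fh.write(f"{a}\t{b}\t{inter}\t{','.join(sorted(shared))}\n")
        if self.meta:
            rows = [
                {"group": g, **asdict(m)} for g, m in self.meta.items()
            ]
            pd.DataFrame(rows).to_csv(outdir / "metatest.tsv", sep="\t", index=False,
                                      float_format="%.6g")
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        manifest["complete"] = True
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        return outdir


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    if d.get("groups") is not None:
        d["groups"] = list(d["groups"])
    return d


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "ervcoex": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
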