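"""Core in-memory containers for the co-expression pipeline.

A :class:`CountMatrix` is a thin, validated wrapper around a pandas
DataFrame (genes in rows, samples in columns) together with a
sample → group assignment.  A :class:`GeneSetCollection` holds named
gene sets (GMT-style: term id, free-text description, member genes).
Both are immutable by convention: pipeline stages return new objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class CountMatrix:
    """Gene × sample expression matrix with group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns
        (columns = sample ids).  Raw counts are integer-valued;
        normalized matrices hold reals.  All entries must be finite
        and non-negative.
    group_of : mapping
        sample id → group label; must cover every sample column.
    """

    values: pd.DataFrame
    group_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise DataError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise DataError(f"duplicate sample id {dup!r}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise DataError("count matrix contains non-numeric values")
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise DataError("count matrix values must be finite and >= 0")
        missing = [s for s in df.columns if s not in self.group_of]
        if self.group_of and missing:
            raise DataError(f"samples missing from group map: {missing}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order over the sample columns."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        out = [s for s in self.values.columns if self.group_of.get(s) == group]
        if not out:
            raise DataError(f"unknown group {group!r}")
        return out

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        """Return a matrix restricted to *gene_ids*, original order preserved."""
        keep = [g for g in self.values.index if g in set(gene_ids)]
        return CountMatrix(self.values.loc[keep], self.group_of)

    def with_values(self, values: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(values, self.group_of)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"gene set {self.term_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise DataError(f"gene set {self.term_id!r} has duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    entries: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        ids = [e.term_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = next(t for i, t in enumerate(ids) if t in ids[:i])
            raise DataError(f"duplicate term id {dup!r}")

    @classmethod
    def from_dict(
        cls,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        descriptions = descriptions or {}
        entries = []
        for term, genes in sets.items():
            members = tuple(dict.fromkeys(genes))  # de-dup, keep order
            entries.append(GeneSet(term, descriptions.get(term, term), members))
        return cls(tuple(entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, term_id: str) -> GeneSet:
        for e in self.entries:
            if e.term_id == term_id:
                return e
        raise KeyError(term_id)

    @property
    def term_ids(self) -> list[str]:
        return [e.term_id for e in self.entries]

    def all_members(self) -> set[str]:
        """Union of member genes over every set."""
        out: set[str] = set()
        for e in self.entries:
            out.update(e.members)
        return out
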