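"""Multi-source interaction-list integration: dedup union and known-item subtraction.

Interaction pairs collected from several curated databases are merged into
one non-redundant list keyed on the unordered, case-normalised id pair, so
(A, B) and (B, A) collapse.  Source provenance is concatenated per pair.
No alias resolution is attempted: symbols that differ only by naming
convention remain distinct (documented limitation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["InteractionRecord", "UnionResult", "dedup_union", "subtract_set"]


@dataclass(frozen=True)
class InteractionRecord:
    """One undirected interaction between two partners from one source."""

    partner_a: str
    partner_b: str
    source: str = ""
    evidence: str = ""

    @property
    def key(self) -> tuple:
        a = str(self.partner_a).strip().upper()
        b = str(self.partner_b).strip().upper()
        return tuple(sorted((a, b)))


@dataclass(frozen=True)
class UnionResult:
    """Deduplicated union of interaction sources."""

    pairs: pd.DataFrame  # columns: partner_a, partner_b, sources
    per_source_counts: dict
    union_count: int

    @property
    def pair_set(self) -> frozenset:
        return frozenset(
            zip(self.pairs["partner_a"], self.pairs["partner_b"])
        )


def _iter_records(source_name: str, rows) -> Iterable:
    if isinstance(rows, pd.DataFrame):
        for i, row in enumerate(rows.itertuples(index=False), start=1):
            yield i, InteractionRecord(
                partner_a=getattr(row, "partner_a"),
                partner_b=getattr(row, "partner_b"),
                source=source_name,
                evidence=str(getattr(row, "evidence", "")),
            )
    else:
        for i, rec in enumerate(rows, start=1):
            if not isinstance(rec, InteractionRecord):
                rec = InteractionRecord(*rec, source=source_name)
            yield i, rec


def dedup_union(sources: Mapping[str, object]) -> UnionResult:
    """Merge interaction lists into one unique undirected pair set.

    ``sources`` maps a source label to either a DataFrame with columns
    partner_a / partner_b (optional evidence) or an iterable of
    :class:`InteractionRecord`.  Rows with an empty partner id are skipped
    with a logged line number.  The union is order-independent across
    sources and never larger than the summed per-source counts.
    """
    if not sources:
        raise ValueError("need at least one interaction source")
    per_source_counts: dict = {}
    merged: dict = {}
    for name in sources:
        count = 0
        for lineno, rec in _iter_records(name, sources[name]):
            a, b = rec.key
            if not a or not b:
                logger.warning("source %s row %d malformed; skipped", name, lineno)
                continue
            count += 1
            entry = merged.setdefault(rec.key, set())
            entry.add(name)
        per_source_counts[name] = count
    rows = [
        {"partner_a": a, "partner_b": b, "sources": ";".join(sorted(provs))}
        for (a, b), provs in sorted(merged.items())
    ]
    pairs = pd.DataFrame(rows, columns=["partner_a", "partner_b", "sources"])
    return UnionResult(
        pairs=pairs, per_source_counts=per_source_counts, union_count=len(pairs)
    )


def subtract_set(items: Iterable, known: Iterable) -> tuple:
    """Remove known items; returns (remaining set, removed count)."""
    items = frozenset(items)
    remaining = items - frozenset(known)
    return remaining, len(items) - len(remaining)
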