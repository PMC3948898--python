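"""Conformer-ensemble consensus virtual screening.

A receptor ensemble (a crystal structure plus molecular-dynamics snapshots)
is represented purely as columns of a compound × conformer score table with
two score phases per cell: a fast primary ("grid") score used to rank all
compounds, and a secondary ("re-rank", e.g. force-field rescoring) score for
the best pose.  Lower scores are better, the docking-energy convention.

The screening model:

1. rank compounds per conformer by the two-phase rule;
2. evaluate each conformer on an actives/decoys benchmark at top-fraction
   cutoffs (10%..100%) with ACC/PPV/FPR;
3. keep only "valid" conformers that strictly beat the reference structure
   on all three metrics at the operative cutoff (default 10%);
4. call consensus hits: compounds in the top fraction of at least k valid
   conformers; k equal to the ensemble size is the published model, smaller
   k gives the nested comparison strategies.

A compound whose docking failed in a conformer (no scores) ranks last there
and can never enter that conformer's top set, but still counts toward the
ranked length — a failed docking is treated as evidence against binding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import (
    ConfusionCounts,
    MetricTriple,
    StrategyReport,
    TruthSet,
    compute_metrics,
    confusion_from_sets,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConformerScoreTable",
    "CutoffEvaluation",
    "ConsensusResult",
    "DEFAULT_CUTOFFS",
    "two_phase_rank",
    "top_fraction_set",
    "evaluate_conformer_at_cutoffs",
    "select_valid_conformers",
    "consensus_hits",
    "k_of_n_comparison",
]

#: The ten evaluation cutoffs, top 10% through top 100%.
DEFAULT_CUTOFFS = tuple(round(0.1 * i, 1) for i in range(1, 11))


class ConformerScoreTable:
    """Long-format compound × conformer docking scores with a reference conformer.

    Parameters
    ----------
    scores : DataFrame with columns compound_id, conformer_id, primary_score,
        secondary_score.  Either score may be NaN (failed phase); a compound
        absent from a conformer, or with both scores missing, failed docking
        there entirely.
    reference : the designated reference conformer id (the crystal
        structure / 0 ps snapshot).
    """

    REQUIRED = ("compound_id", "conformer_id", "primary_score", "secondary_score")

    def __init__(self, scores: pd.DataFrame, reference: str):
        for col in self.REQUIRED:
            if col not in scores.columns:
                raise ValueError(f"score table missing required column {col!r}")
        df = scores.loc[:, list(self.REQUIRED)].copy()
        df["compound_id"] = df["compound_id"].astype(str)
        df["conformer_id"] = df["conformer_id"].astype(str)
        for col in ("primary_score", "secondary_score"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            bad = np.isinf(df[col].to_numpy(dtype=float))
            if bad.any():
                raise ValueError(f"non-finite {col} values present")
        if df.duplicated(["compound_id", "conformer_id"]).any():
            raise ValueError("duplicate (compound, conformer) rows")
        self._df = df
        self.reference = str(reference)
        if self.reference not in self.conformers:
            raise ValueError(f"reference conformer {reference!r} not in table")

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def compounds(self) -> tuple:
        return tuple(sorted(self._df["compound_id"].unique()))

    @property
    def conformers(self) -> tuple:
        return tuple(sorted(self._df["conformer_id"].unique()))

    def conformer_frame(self, conformer: str) -> pd.DataFrame:
        if conformer not in self.conformers:
            raise ValueError(f"unknown conformer {conformer!r}")
        sub = self._df[self._df["conformer_id"] == conformer]
        return sub.set_index("compound_id")

    def scored_compounds(self, conformer: str) -> frozenset:
        """Compounds with at least one finite score for this conformer."""
        sub = self.conformer_frame(conformer)
        ok = sub["primary_score"].notna() | sub["secondary_score"].notna()
        return frozenset(sub.index[ok])

    @classmethod
    def from_tsv(cls, path, reference: str) -> "ConformerScoreTable":
        return cls(pd.read_csv(path, sep="\t"), reference)


@dataclass(frozen=True)
class CutoffEvaluation:
    """One conformer's benchmark performance at one top-fraction cutoff."""

    conformer: str
    cutoff: float
    counts: ConfusionCounts
    metrics: MetricTriple


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus hit call: compounds in the top fraction of >= k valid conformers."""

    required_hits: int
    valid_conformers: tuple
    hits: frozenset
    report: Optional[StrategyReport] = None


def two_phase_rank(table: ConformerScoreTable, conformer: str) -> list:
    """Deterministic two-phase ranking of all compounds for one conformer.

    Compounds with a secondary (re-rank) score come first, ordered by it
    ascending; compounds with only a primary score follow, ordered by it;
    compounds with neither (failed docking) are placed last.  All ties break
    by compound id, so the ranking is stable across runs.
    """
    sub = table.conformer_frame(conformer)
    universe = table.compounds
    sec, pri, failed = [], [], []
    for cid in universe:
        if cid in sub.index:
            row = sub.loc[cid]
            s, p = row["secondary_score"], row["primary_score"]
            if pd.notna(s):
                sec.append((float(s), cid))
                continue
            if pd.notna(p):
                pri.append((float(p), cid))
                continue
        failed.append(cid)
    sec.sort()
    pri.sort()
    failed.sort()
    return [cid for _, cid in sec] + [cid for _, cid in pri] + failed


def top_fraction_set(ranked: Sequence, q: float) -> frozenset:
    """First ceil(q·n) compounds of a ranked list (top fraction q).

    Ceiling rounding guarantees a non-empty set at q = 10% for any n >= 1
    (e.g. n=15, q=0.10 keeps 2 compounds).
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"fraction q must be in (0, 1], got {q}")
    n = len(ranked)
    m = math.ceil(q * n - 1e-12)  # guard binary representation of e.g. 0.3*10
    return frozenset(ranked[:m])


def _top_set(table: ConformerScoreTable, conformer: str, q: float) -> frozenset:
    """Top-q set for one conformer, excluding compounds that failed docking."""
    ranked = two_phase_rank(table, conformer)
    return top_fraction_set(ranked, q) & table.scored_compounds(conformer)


def evaluate_conformer_at_cutoffs(
    table: ConformerScoreTable,
    conformer: str,
    truth: TruthSet,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> list[CutoffEvaluation]:
    """Benchmark one conformer at each cutoff: positives = its top-q set."""
    missing = frozenset(table.compounds) - truth.universe
    if missing:
        raise ValueError(
            f"{len(missing)} compound(s) in the table lack active/decoy labels"
        )
    ranked = two_phase_rank(table, conformer)
    scored = table.scored_compounds(conformer)
    out = []
    for q in cutoffs:
        pos = top_fraction_set(ranked, q) & scored
        counts = confusion_from_sets(pos, truth)
        out.append(
            CutoffEvaluation(
                conformer=conformer, cutoff=float(q), counts=counts,
                metrics=compute_metrics(counts),
            )
        )
    return out


def select_valid_conformers(
    evals: Sequence[CutoffEvaluation], reference: str
) -> frozenset:
    """Keep the reference plus conformers strictly beating it on all metrics.

    A candidate is valid only if, at the shared cutoff, its ACC and PPV are
    strictly higher and its FPR strictly lower than the reference's; a
    candidate with undefined PPV (no positive call) never qualifies.
    """
    if len({e.cutoff for e in evals}) > 1:
        raise ValueError("conformer evaluations are at mixed cutoffs")
    by_conf = {e.conformer: e for e in evals}
    if reference not in by_conf:
        raise ValueError(f"missing evaluation for reference conformer {reference!r}")
    ref = by_conf[reference].metrics
    valid = {reference}
    for conf, ev in by_conf.items():
        if conf == reference:
            continue
        m = ev.metrics
        if m.ppv is None or ref.ppv is None or m.fpr is None or ref.fpr is None:
            continue
        if m.acc > ref.acc and m.ppv > ref.ppv and m.fpr < ref.fpr:
            valid.add(conf)
    return frozenset(valid)


def consensus_hits(
    table: ConformerScoreTable,
    valid_conformers: Iterable,
    q: float = 0.1,
    required_hits: Optional[int] = None,
) -> ConsensusResult:
    """Compounds ranking in the top fraction q for at least k valid conformers.

    ``required_hits`` (k) defaults to the number of valid conformers — the
    all-conformer consensus model.  Hit sets are nested: raising k can only
    shrink the set.
    """
    valid = tuple(sorted(set(map(str, valid_conformers))))
    if not valid:
        raise ValueError("no valid conformers supplied")
    k = len(valid) if required_hits is None else int(required_hits)
    if not (1 <= k <= len(valid)):
        raise ValueError(f"required_hits must be in [1, {len(valid)}], got {k}")
    hit_counts: dict = {}
    for conf in valid:
        for cid in _top_set(table, conf, q):
            hit_counts[cid] = hit_counts.get(cid, 0) + 1
    hits = frozenset(cid for cid, n in hit_counts.items() if n >= k)
    return ConsensusResult(required_hits=k, valid_conformers=valid, hits=hits)


def k_of_n_comparison(
    table: ConformerScoreTable,
    valid_conformers: Iterable,
    q: float,
    truth: TruthSet,
) -> list[StrategyReport]:
    """Score the at-least-k consensus strategies for k = 1..N valid conformers.

    Because hit sets are nested in k, false positives and FPR are
    non-increasing in k.
    """
    valid = tuple(sorted(set(map(str, valid_conformers))))
    reports = []
    for k in range(1, len(valid) + 1):
        res = consensus_hits(table, valid, q=q, required_hits=k)
        pred = res.hits & truth.universe
        counts = confusion_from_sets(pred, truth)
        reports.append(
            StrategyReport(
                strategy=f"hit>={k}/{len(valid)}",
                counts=counts,
                metrics=compute_metrics(counts),
            )
        )
    return reports
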