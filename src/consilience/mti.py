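"""Consensus miRNA-target interaction (MTI) prediction and its validation.

Three target-prediction programs with different algorithms (a microT-style
CDS+UTR predictor, a miRanda/mirSVR-style downregulation ranker and a
TargetScan-style conservation-based predictor) each emit scored candidate
interactions.  A prediction is kept as "reliable" only if it clears that
program's published high-precision threshold:

* miTG score strictly greater than 0.7;
* mirSVR score of -0.1 or lower (more negative = stronger repression);
* context+ score of -1.67 or higher, optionally a minimum conserved-targeting
  probability (P_CT), and at least one conserved site.

The consensus model takes the intersection of the per-program reliable sets,
removes already-known interactions, and is validated against a truth set
built from pSILAC-style over-expression proteomics (proteins that go UP when
the miRNA is over-expressed contradict targeting and are known-false) and
curated interactions with direct functional evidence such as reporter-gene
assays (known-true).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import (
    ConfusionCounts,
    StrategyReport,
    TruthSet,
    compute_metrics,
    confusion_from_sets,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionRecord",
    "ProgramCriteria",
    "ConsensusPrediction",
    "normalize_mirna",
    "normalize_gene",
    "apply_program_criteria",
    "consensus_predict",
    "build_truth_sets",
    "validate_strategies",
    "DEFAULT_DIRECT_EVIDENCE",
]

#: Evidence classes counted as direct functional support for a true MTI.
DEFAULT_DIRECT_EVIDENCE = frozenset(
    {"reporter gene assay", "reporter assay", "luciferase reporter assay"}
)


def normalize_mirna(name: str) -> str:
    """Case-normalize a miRNA name (lower-case, trimmed)."""
    return str(name).strip().lower()


def normalize_gene(symbol: str) -> str:
    """Upper-case and trim a gene symbol."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class PredictionRecord:
    """One program's scored prediction for a (miRNA, target) pair.

    Only the score fields relevant to the record's program need be present;
    the rest may stay None.
    """

    program: str
    mirna: str
    target: str
    mitg_score: Optional[float] = None
    mirsvr_score: Optional[float] = None
    contextplus_score: Optional[float] = None
    pct_value: Optional[float] = None
    conserved_site_count: Optional[int] = None

    @property
    def item(self) -> tuple:
        return (normalize_mirna(self.mirna), normalize_gene(self.target))


@dataclass(frozen=True)
class ProgramCriteria:
    """Threshold rules defining a reliable prediction for one program.

    ``contextplus_direction`` selects between the literal published reading
    of the context+ rule ("-1.67 or higher" passes, the default) and the
    conventional strong-repression reading (more negative passes).
    ``pct_min`` of None disables the P_CT filter (no published threshold).
    """

    program: str
    mitg_threshold: float = 0.7
    mirsvr_threshold: float = -0.1
    contextplus_threshold: float = -1.67
    contextplus_direction: str = "literal-paper"
    pct_min: Optional[float] = None
    min_conserved_sites: int = 1

    def __post_init__(self):
        if self.contextplus_direction not in ("literal-paper", "strong-repression"):
            raise ValueError(
                f"unknown contextplus_direction {self.contextplus_direction!r}"
            )
        for name in ("mitg_threshold", "mirsvr_threshold", "contextplus_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ConsensusPrediction:
    """Result of the consensus step: novel items plus pre-subtraction size."""

    novel: frozenset
    intersection_size: int
    removed_known: int


def _require(record: PredictionRecord, fieldname: str):
    value = getattr(record, fieldname)
    if value is None:
        raise ValueError(
            f"record {record.item} from program {record.program!r} is missing "
            f"required score field {fieldname!r}"
        )
    return value


def _passes(record: PredictionRecord, criteria: ProgramCriteria) -> bool:
    prog = criteria.program.lower()
    if prog in ("microt", "diana-microt", "diana-microt-cds"):
        return _require(record, "mitg_score") > criteria.mitg_threshold
    if prog in ("miranda", "mirsvr"):
        return _require(record, "mirsvr_score") <= criteria.mirsvr_threshold
    if prog == "targetscan":
        ctx = _require(record, "contextplus_score")
        if criteria.contextplus_direction == "literal-paper":
            ok = ctx >= criteria.contextplus_threshold
        else:
            ok = ctx <= criteria.contextplus_threshold
        if not ok:
            return False
        if criteria.pct_min is not None:
            if _require(record, "pct_value") < criteria.pct_min:
                return False
        sites = _require(record, "conserved_site_count")
        return sites >= criteria.min_conserved_sites
    raise ValueError(f"unknown program {criteria.program!r}")


def apply_program_criteria(
    records: Sequence[PredictionRecord], criteria: ProgramCriteria
) -> frozenset:
    """Return the (miRNA, gene) items passing every threshold of one program."""
    out = set()
    for rec in records:
        if rec.program.lower() != criteria.program.lower():
            raise ValueError(
                f"record from program {rec.program!r} passed to criteria for "
                f"{criteria.program!r}"
            )
        if _passes(rec, criteria):
            out.add(rec.item)
    return frozenset(out)


def consensus_predict(
    per_program_sets: Sequence[Iterable], known_items: Iterable = ()
) -> ConsensusPrediction:
    """Intersect per-program reliable sets, then subtract known items.

    Needs at least two program sets; an empty result is legitimate (the
    hsa-let-7b test case produces exactly that).
    """
    sets = [frozenset(s) for s in per_program_sets]
    if len(sets) < 2:
        raise ValueError("consensus needs at least two program sets")
    inter = frozenset.intersection(*sets)
    known = frozenset(known_items)
    novel = inter - known
    return ConsensusPrediction(
        novel=novel,
        intersection_size=len(inter),
        removed_known=len(inter) - len(novel),
    )


def build_truth_sets(
    downreg_table: pd.DataFrame,
    evidence_table: pd.DataFrame,
    direct_evidence_classes: frozenset = DEFAULT_DIRECT_EVIDENCE,
) -> TruthSet:
    """Construct disjoint known-false / known-true MTI sets.

    ``downreg_table`` holds one log fold change per (mirna, gene) measured
    under that miRNA's over-expression; pairs whose protein went UP
    (log_fold_change > 0) contradict targeting and enter the false set.
    ``evidence_table`` holds (mirna, gene, evidence_class); pairs whose class
    is in ``direct_evidence_classes`` enter the true set.  A pair qualifying
    for both is kept as true (direct experimental evidence wins) and removed
    from the false set with a logged count, keeping the sets disjoint.
    """
    for col in ("mirna", "gene", "log_fold_change"):
        if col not in downreg_table.columns:
            raise ValueError(f"downreg table missing required column {col!r}")
    for col in ("mirna", "gene", "evidence_class"):
        if col not in evidence_table.columns:
            raise ValueError(f"evidence table missing required column {col!r}")
    lfc = pd.to_numeric(downreg_table["log_fold_change"], errors="raise")
    keys = [
        (normalize_mirna(m), normalize_gene(g))
        for m, g in zip(downreg_table["mirna"], downreg_table["gene"])
    ]
    false_set = {k for k, v in zip(keys, lfc) if v > 0}
    classes = {c.strip().lower() for c in direct_evidence_classes}
    true_set = {
        (normalize_mirna(m), normalize_gene(g))
        for m, g, ev in zip(
            evidence_table["mirna"],
            evidence_table["gene"],
            evidence_table["evidence_class"],
        )
        if str(ev).strip().lower() in classes
    }
    conflict = true_set & false_set
    if conflict:
        logger.info(
            "%d pair(s) had both direct evidence and up-regulation; kept as true",
            len(conflict),
        )
        false_set -= conflict
    return TruthSet(true_set=frozenset(true_set), false_set=frozenset(false_set))


def validate_strategies(
    per_program_sets: Mapping[str, Iterable], truth: TruthSet
) -> list[StrategyReport]:
    """Score the 7 intersection strategies of three programs on a truth set.

    The strategies are the three single programs, the three pairwise
    intersections and the triple intersection (labelled "(model)", the
    consensus model).  Each strategy's positives are its set restricted to
    the truth universe.
    """
    names = list(per_program_sets)
    if len(names) != 3:
        raise ValueError("strategy validation expects exactly three program sets")
    sets = {n: frozenset(per_program_sets[n]) for n in names}
    universe = truth.universe
    reports = []
    for r in (1, 2, 3):
        for combo in itertools.combinations(names, r):
            pred = frozenset.intersection(*(sets[n] for n in combo)) & universe
            label = "∩".join(combo)
            if r == 3:
                label += " (model)"
            counts = confusion_from_sets(pred, truth)
            reports.append(
                StrategyReport(strategy=label, counts=counts, metrics=compute_metrics(counts))
            )
    return reports
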