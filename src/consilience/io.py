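"""Typed TSV/JSON table readers and report writers.

All tables are tab-separated text with a header row.  Undefined metrics
(e.g. PPV with no positive calls) serialise as ``NA`` in TSV and ``null``
in JSON; percentages are written to 3 decimals.  Reading back a written
report reproduces the written values exactly (the rounded values are the
canonical output).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import RocCurve, StrategyReport

logger = logging.getLogger(__name__)

__all__ = [
    "TableSchema",
    "read_table",
    "write_table",
    "reports_frame",
    "write_reports",
    "write_roc_points",
    "write_json",
]

#: Columns carrying percentages, rendered to 3 decimals.
_PERCENT_COLS = ("acc", "ppv", "fpr")


@dataclass(frozen=True)
class TableSchema:
    """Required columns and their dtypes for one table dialect."""

    name: str
    required: Mapping[str, type]

    def validate(self, df: pd.DataFrame, path) -> pd.DataFrame:
        missing = [c for c in self.required if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: {self.name} table missing required column(s) "
                f"{', '.join(missing)}"
            )
        extra = [c for c in df.columns if c not in self.required]
        if extra:
            logger.warning("%s: ignoring extra column(s) %s", path, ", ".join(extra))
        out = df.loc[:, list(self.required)].copy()
        for col, typ in self.required.items():
            if typ in (float, int):
                try:
                    out[col] = pd.to_numeric(out[col], errors="raise")
                except (ValueError, TypeError) as exc:
                    bad = pd.to_numeric(out[col], errors="coerce")
                    row = int(np.flatnonzero(bad.isna() & out[col].notna())[0]) + 2
                    raise ValueError(
                        f"{path}: unparsable value in column {col!r} "
                        f"(file line {row})"
                    ) from exc
            else:
                out[col] = out[col].astype(str)
        return out


# Table dialects used across the pipeline
PREDICTIONS = TableSchema(
    "predictions",
    {"program": str, "mirna": str, "gene": str},
)
FOLD_CHANGES = TableSchema(
    "fold-change", {"mirna": str, "gene": str, "log_fold_change": float}
)
EVIDENCE = TableSchema("evidence", {"mirna": str, "gene": str, "evidence_class": str})
DOCK_SCORES = TableSchema(
    "docking scores",
    {"compound_id": str, "conformer_id": str, "primary_score": float,
     "secondary_score": float},
)
LABELS = TableSchema("labels", {"compound_id": str, "label": str})
PAIRS = TableSchema("interaction pairs", {"partner_a": str, "partner_b": str})


def read_table(path, schema: Optional[TableSchema] = None) -> pd.DataFrame:
    """Read a TSV table, validating it against a schema when given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=True)
    if schema is not None:
        df = schema.validate(df, path)
    return df


def _format_cell(col: str, value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if col in _PERCENT_COLS:
        return f"{float(value):.3f}"
    return value


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a TSV with deterministic column order and NA sentinels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        out[col] = [_format_cell(col, v) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)
    return path


def reports_frame(reports: Sequence[StrategyReport]) -> pd.DataFrame:
    """Flatten strategy reports to the standard report columns."""
    return pd.DataFrame(
        [
            {
                "strategy": r.strategy,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "tn": r.counts.tn,
                "fn": r.counts.fn,
                "acc": r.metrics.acc,
                "ppv": r.metrics.ppv,
                "fpr": r.metrics.fpr,
                "positives": r.positives,
            }
            for r in reports
        ]
    )


def write_reports(reports: Sequence[StrategyReport], path, fmt: str = "tsv") -> Path:
    """Write strategy reports as TSV or JSON (undefined metrics -> NA/null)."""
    df = reports_frame(reports)
    if fmt == "tsv":
        return write_table(df, path)
    if fmt == "json":
        records = []
        for rec in df.to_dict(orient="records"):
            for col in _PERCENT_COLS:
                if rec[col] is not None and not (
                    isinstance(rec[col], float) and np.isnan(rec[col])
                ):
                    rec[col] = round(float(rec[col]), 3)
                else:
                    rec[col] = None
            records.append(rec)
        return write_json(records, path)
    raise ValueError(f"unknown report format {fmt!r}")


def write_roc_points(curve: RocCurve, path) -> Path:
    """Write ROC points as a two-column TSV (fpr, tpr)."""
    df = pd.DataFrame(curve.points, columns=["fpr", "tpr"])
    return write_table(df, path)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return path
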