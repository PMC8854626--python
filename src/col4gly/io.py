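"""Tab-separated table and FASTA I/O shared by the pipeline stages.

All tables are tab-separated with a header row; lines beginning with '#'
are comments.  Readers fail loudly on missing required columns, naming
the column; writers round-trip every declared column losslessly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .survival import IndividualRecord

__all__ = [
    "SchemaError",
    "read_table",
    "write_table",
    "read_registry",
    "write_registry",
    "read_fasta_sequence",
    "write_fasta_sequence",
    "write_report",
]


class SchemaError(ValueError):
    """A table is missing a required column."""


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for column in required:
        if column not in frame.columns:
            raise SchemaError(f"{path}: missing required column {column!r}")
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


_REGISTRY_COLUMNS = (
    "family_id",
    "sex",
    "phenotype_text",
    "event_age",
    "event_age_low",
    "event_age_high",
    "last_seen_age",
    "variant_ids",
)


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return float(text) if text else None


def read_registry(path: str | Path) -> list[IndividualRecord]:
    """One row per individual; variant_ids column is semicolon-separated."""
    frame = read_table(path, required=("family_id", "sex", "phenotype_text"))
    records = []
    for _, row in frame.iterrows():
        low = _parse_optional_float(row.get("event_age_low"))
        high = _parse_optional_float(row.get("event_age_high"))
        variant_text = str(row.get("variant_ids") or "").strip()
        records.append(
            IndividualRecord(
                family_id=str(row["family_id"]),
                sex=str(row["sex"]),
                phenotype_text=str(row["phenotype_text"]),
                event_age=_parse_optional_float(row.get("event_age")),
                event_age_range=(low, high) if low is not None and high is not None else None,
                last_seen_age=_parse_optional_float(row.get("last_seen_age")),
                variant_ids=tuple(v for v in variant_text.split(";") if v),
            )
        )
    return records


def write_registry(records: list[IndividualRecord], path: str | Path) -> None:
    rows = []
    for record in records:
        low, high = record.event_age_range or (None, None)
        rows.append(
            {
                "family_id": record.family_id,
                "sex": record.sex,
                "phenotype_text": record.phenotype_text,
                "event_age": record.event_age,
                "event_age_low": low,
                "event_age_high": high,
                "last_seen_age": record.last_seen_age,
                "variant_ids": ";".join(record.variant_ids),
            }
        )
    pd.DataFrame(rows, columns=_REGISTRY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta_sequence(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return str(records[0].seq).upper()


def write_fasta_sequence(sequence: str, path: str | Path, name: str = "seq") -> None:
    lines = [f">{name}"]
    for i in range(0, len(sequence), 70):
        lines.append(sequence[i : i + 70])
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
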