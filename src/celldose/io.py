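"""Readers and writers for the pipeline's tabular formats.

Formats:

- uptake CSV: ``compound, applied_activity_bq, surface_cpm,
  internalized_cpm, nuclear_fraction, time_h`` (header required, UTF-8).
- clonogenic CSV: ``label, activity_bq`` (or ``dose_gy``),
  ``cells_seeded, colonies``.
- S-value matrix JSON: see :meth:`celldose.mird.SValueMatrix.from_json`.

Activity fields accept a plain number (Bq) or a string with a ``kBq`` /
``MBq`` / ``Bq`` suffix; the canonical internal unit is Bq.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .kinetics import UptakeRecord
from .radiobiology import ColonyCount

__all__ = [
    "parse_activity_bq",
    "read_uptake_csv",
    "write_uptake_csv",
    "read_clonogenic_csv",
]

_UNIT_FACTORS = {"bq": 1.0, "kbq": 1e3, "mbq": 1e6}

UPTAKE_COLUMNS = [
    "compound",
    "applied_activity_bq",
    "surface_cpm",
    "internalized_cpm",
    "nuclear_fraction",
    "time_h",
]


def parse_activity_bq(value: "str | float | int") -> float:
    """Parse ``7.4``, ``"7.4 MBq"``, ``"185 kBq"`` ... into Bq."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    for suffix, factor in sorted(_UNIT_FACTORS.items(), key=lambda kv: -len(kv[0])):
        if text.lower().endswith(suffix):
            return float(text[: -len(suffix)].strip()) * factor
    return float(text)


def read_uptake_csv(path: str | Path) -> dict[str, list[UptakeRecord]]:
    """Uptake records grouped by compound label.

    Raises ValueError naming the offending row on any schema violation so
    bad input files fail loudly rather than producing silent zero doses.
    """
    df = pd.read_csv(path)
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out: dict[str, list[UptakeRecord]] = {}
    for idx, row in df.iterrows():
        try:
            rec = UptakeRecord(
                applied_activity_bq=parse_activity_bq(row["applied_activity_bq"]),
                surface_cpm=float(row["surface_cpm"]),
                internalized_cpm=float(row["internalized_cpm"]),
                nuclear_fraction=float(row["nuclear_fraction"]),
                measurement_time_h=float(row["time_h"]),
                compound=str(row["compound"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
        out.setdefault(rec.compound, []).append(rec)
    return out


def write_uptake_csv(records: Iterable[UptakeRecord], path: str | Path) -> None:
    rows = [
        {
            "compound": r.compound or "",
            "applied_activity_bq": r.applied_activity_bq,
            "surface_cpm": r.surface_cpm,
            "internalized_cpm": r.internalized_cpm,
            "nuclear_fraction": r.nuclear_fraction,
            "time_h": r.measurement_time_h,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=UPTAKE_COLUMNS).to_csv(path, index=False)


def read_clonogenic_csv(path: str | Path) -> dict[str, list[ColonyCount]]:
    """Colony counts grouped by treatment label.

    Requires ``label``, ``cells_seeded``, ``colonies`` and at least one of
    ``activity_bq`` / ``dose_gy``.
    """
    df = pd.read_csv(path)
    required = {"label", "cells_seeded", "colonies"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "activity_bq" not in df.columns and "dose_gy" not in df.columns:
        raise ValueError(f"{path}: need an 'activity_bq' or 'dose_gy' column")
    out: dict[str, list[ColonyCount]] = {}
    for idx, row in df.iterrows():
        try:
            cc = ColonyCount(
                cells_seeded=int(row["cells_seeded"]),
                colonies_formed=int(row["colonies"]),
                treatment_label=str(row["label"]),
                applied_activity_bq=(
                    parse_activity_bq(row["activity_bq"])
                    if "activity_bq" in df.columns and pd.notna(row["activity_bq"])
                    else None
                ),
                dose_gy=(
                    float(row["dose_gy"])
                    if "dose_gy" in df.columns and pd.notna(row["dose_gy"])
                    else None
                ),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
        out.setdefault(cc.treatment_label, []).append(cc)
    return out
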