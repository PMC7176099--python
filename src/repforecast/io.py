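"""Reading and writing the study-pair CSV schema.

Columns: ``study, ro, no, rr, nr, pm_belief`` with ``rr``/``nr`` allowed to
be empty (design mode, replication not yet run) and ``pm_belief`` optional.
The same schema fits the published one-to-one replication project tables.
Gzipped files are read transparently via the ``.gz`` extension.
"""

from __future__ import annotations

import math

import pandas as pd

from .transforms import StudyPair

__all__ = ["read_pairs_csv", "write_pairs_csv", "CSV_COLUMNS"]

CSV_COLUMNS = ("study", "ro", "no", "rr", "nr", "pm_belief")
_REQUIRED = ("study", "ro", "no")


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_pairs_csv(path) -> list[StudyPair]:
    """Parse and validate a study-pair CSV; raises on schema or range errors."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    pairs = []
    for idx, row in df.iterrows():
        try:
            pairs.append(
                StudyPair(
                    study_id=str(row["study"]),
                    r_o=float(row["ro"]),
                    n_o=float(row["no"]),
                    r_r=_opt(row.get("rr")),
                    n_r=_opt(row.get("nr")),
                    pm_belief=_opt(row.get("pm_belief")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid study pair in row {idx} of {path}: {exc}") from exc
    return pairs


def write_pairs_csv(pairs, path) -> None:
    """Write study pairs with full float precision (round-trip exact)."""
    import csv

    def fmt(value) -> str:
        if value is None:
            return ""
        return repr(float(value))  # shortest round-trip exact representation

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for p in pairs:
            writer.writerow(
                [p.study_id, fmt(p.r_o), fmt(p.n_o), fmt(p.r_r), fmt(p.n_r), fmt(p.pm_belief)]
            )
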