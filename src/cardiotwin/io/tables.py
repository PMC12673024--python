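"""Patient-record tables and result records.

Patient tables are CSV with a fixed header; units are documented in the
column names (ms, fraction, mm, mL, m2).  Results serialize as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..personalize import PatientRecord, PersonalizationResult

__all__ = ["PATIENT_COLUMNS", "write_patient_table", "read_patient_table",
           "write_results", "read_results"]

PATIENT_COLUMNS = ["patient_id", "sex", "timepoint", "qrs_ms", "ecv",
                   "wall_thickness_mm", "lv_volume_ml", "bsa_m2"]


def write_patient_table(path, records: list[PatientRecord]) -> None:
    rows = [{c: getattr(r, c) for c in PATIENT_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def read_patient_table(path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    missing = [c for c in PATIENT_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: patient table is missing required column(s): "
            f"{', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]), sex=str(row["sex"]),
            timepoint=str(row["timepoint"]), qrs_ms=float(row["qrs_ms"]),
            ecv=float(row["ecv"]),
            wall_thickness_mm=float(row["wall_thickness_mm"]),
            lv_volume_ml=float(row.get("lv_volume_ml", np.nan)),
            bsa_m2=float(row.get("bsa_m2", np.nan))))
    return records


def write_results(path, results: list[PersonalizationResult],
                  provenance: dict | None = None) -> None:
    payload = {"results": [r.as_dict() for r in results]}
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def read_results(path) -> list[dict]:
    return json.loads(Path(path).read_text())["results"]
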