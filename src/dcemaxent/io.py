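"""CSV/JSON readers and writers for concentration curves and fit results.

Curve files use seconds and mM at the boundary (header
``patient_id,time_s,cp_mM,ctis_mM``, one row per sample); times are
converted to minutes on read, since all kinetics run in minutes internally.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import KineticParams
from .synthetic_data import SECONDS_PER_MINUTE, ConcentrationTimeSeries, PatientRecord

__all__ = ["CURVE_COLUMNS", "read_curves", "write_curves", "write_truth", "read_truth"]

CURVE_COLUMNS = ["patient_id", "time_s", "cp_mM", "ctis_mM"]


def read_curves(path: str | Path) -> dict[str, tuple[ConcentrationTimeSeries, ConcentrationTimeSeries]]:
    """Read per-patient (Cp, Ctis) series from a curve CSV.

    Rows may arrive in any order; they are sorted by time within patient.
    Missing columns, non-numeric cells and duplicate (patient, time) pairs
    are rejected with the offending row numbers (1-based, excluding header).
    """
    frame = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"curve file {path} is missing columns: {', '.join(missing)}")
    for column in ("time_s", "cp_mM", "ctis_mM"):
        numeric = pd.to_numeric(frame[column], errors="coerce")
        bad = frame.index[numeric.isna() & frame[column].notna()] + 1
        if len(bad):
            raise ValueError(f"non-numeric {column} values at rows: {list(bad)}")
        if frame[column].isna().any():
            bad = frame.index[frame[column].isna()] + 1
            raise ValueError(f"missing {column} values at rows: {list(bad)}")
        frame[column] = numeric
    duplicated = frame.duplicated(subset=["patient_id", "time_s"], keep=False)
    if duplicated.any():
        raise ValueError(
            f"duplicate (patient_id, time_s) pairs at rows: {list(frame.index[duplicated] + 1)}"
        )
    out: dict[str, tuple[ConcentrationTimeSeries, ConcentrationTimeSeries]] = {}
    for pid, group in frame.groupby("patient_id", sort=True):
        group = group.sort_values("time_s")
        times_min = group["time_s"].to_numpy(dtype=float) / SECONDS_PER_MINUTE
        cp = ConcentrationTimeSeries(str(pid), times_min, group["cp_mM"].to_numpy(dtype=float))
        ctis = ConcentrationTimeSeries(str(pid), times_min.copy(), group["ctis_mM"].to_numpy(dtype=float))
        out[str(pid)] = (cp, ctis)
    return out


def write_curves(
    studies: dict[str, tuple[ConcentrationTimeSeries, ConcentrationTimeSeries]] | list[PatientRecord],
    path: str | Path,
) -> None:
    """Write curves to CSV (seconds/mM at the boundary); inverse of read_curves."""
    if isinstance(studies, list):
        studies = {r.patient_id: (r.cp, r.ctis) for r in studies}
    rows = []
    for pid in sorted(studies):
        cp, ctis = studies[pid]
        if len(cp) != len(ctis) or not np.allclose(cp.times, ctis.times):
            raise ValueError(f"patient {pid}: Cp and Ctis must share one grid")
        for t, a, b in zip(cp.times * SECONDS_PER_MINUTE, cp.values, ctis.values):
            rows.append({"patient_id": pid, "time_s": t, "cp_mM": a, "ctis_mM": b})
    pd.DataFrame(rows, columns=CURVE_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def write_truth(records: list[PatientRecord], path: str | Path) -> None:
    """Ground-truth sidecar JSON: {patient_id: {"k1": ..., "k2": ...}}."""
    payload = {r.patient_id: {"k1": r.truth.k1, "k2": r.truth.k2} for r in records}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> dict[str, KineticParams]:
    payload = json.loads(Path(path).read_text())
    return {pid: KineticParams(k1=v["k1"], k2=v["k2"]) for pid, v in payload.items()}
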