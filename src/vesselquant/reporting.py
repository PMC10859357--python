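"""Serialisation of involvement reports (JSON and CSV)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .involvement import (
    InvolvementMeasurement,
    InvolvementReport,
    VesselInvolvement,
    bin_degree,
)
from .volume_io import VESSELS

__all__ = ["report_to_frame", "write_report", "read_report_json"]


def report_to_frame(report: InvolvementReport) -> pd.DataFrame:
    """One row per vessel: degrees, category, argmax plane, V/TV, warnings."""
    rows = []
    for v in VESSELS:
        vi = report[v]
        m = vi.measurement
        rows.append(
            {
                "vessel": v,
                "max_degrees": round(vi.max_degrees, 1),
                "category": vi.category,
                "argmax_axis": None if vi.argmax_plane is None else vi.argmax_plane[0],
                "argmax_index": None if vi.argmax_plane is None else vi.argmax_plane[1],
                "circumference_V_mm": None if m is None else round(m.circumference_V, 3),
                "contact_TV_mm": None if m is None else round(m.contact_TV, 3),
                "absent": vi.absent,
                "warnings": "; ".join(vi.warnings),
            }
        )
    return pd.DataFrame(rows)


def write_report(report: InvolvementReport, outdir: str | Path, stem: str = "involvement"):
    """Write the report as ``<stem>.json`` and ``<stem>.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = report_to_frame(report)
    csv_path = outdir / f"{stem}.csv"
    frame.to_csv(csv_path, index=False)
    payload = {
        row["vessel"]: {k: v for k, v in row.items() if k != "vessel"}
        for row in frame.to_dict(orient="records")
    }
    # JSON keeps full precision for degrees
    for v in VESSELS:
        payload[v]["max_degrees"] = report[v].max_degrees
    json_path = outdir / f"{stem}.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, ensure_ascii=False)
    return {"json": json_path, "csv": csv_path}


def read_report_json(path: str | Path) -> InvolvementReport:
    """Reconstruct an involvement report from its JSON serialisation."""
    with open(path) as fh:
        payload = json.load(fh)
    vessels: dict[str, VesselInvolvement] = {}
    for v in VESSELS:
        if v not in payload:
            raise ValueError(f"{path}: report is missing vessel {v}")
        rec: Mapping = payload[v]
        deg = float(rec["max_degrees"])
        plane = None
        if rec.get("argmax_axis") is not None:
            plane = (int(rec["argmax_axis"]), int(rec["argmax_index"]))
        meas = None
        if rec.get("circumference_V_mm") is not None and plane is not None:
            meas = InvolvementMeasurement(
                circumference_V=float(rec["circumference_V_mm"]),
                contact_TV=float(rec["contact_TV_mm"]),
                degrees=deg,
                plane_ref=plane,
            )
        vessels[v] = VesselInvolvement(
            vessel=v,
            max_degrees=deg,
            argmax_plane=plane,
            category=rec.get("category", bin_degree(min(max(deg, 0.0), 360.0))),
            measurement=meas,
            absent=bool(rec.get("absent", False)),
            warnings=tuple(w for w in rec.get("warnings", "").split("; ") if w),
        )
    return InvolvementReport(vessels=vessels)
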