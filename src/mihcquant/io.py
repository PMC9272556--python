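"""CSV I/O for per-cell tables, patient tables and report tables.

Cell tables model inForm-style per-cell exports: one row per segmented cell
with columns ``cell_id, roi_id, patient_id, region, x_um, y_um, cell_class``
plus one column per marker. Marker intensities must lie in {0, 1, 2, 3}.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    VALID_CLASSES,
    VALID_INTENSITIES,
    VALID_REGIONS,
    Cell,
    PatientRecord,
    ROI,
    SchemaError,
)

CELL_TABLE_COLUMNS = (
    "cell_id",
    "roi_id",
    "patient_id",
    "region",
    "x_um",
    "y_um",
    "cell_class",
)

_SURVIVAL_TIME_COLS = ("os_months", "iros_months", "irpfs_months")
_SURVIVAL_EVENT_COLS = ("os_event", "iros_event", "irpfs_event")
_PATIENT_FIXED_COLS = (
    ("patient_id", "cldn_status", "cldn_proportion", "response")
    + _SURVIVAL_TIME_COLS
    + _SURVIVAL_EVENT_COLS
)


def read_cell_table(
    path: str | Path,
    markers: Optional[Sequence[str]] = None,
    roi_width: float = 930.0,
    roi_height: float = 700.0,
) -> list[ROI]:
    """Read a per-cell CSV and group cells into ROIs.

    Parameters
    ----------
    path
        CSV file with the mandatory header columns plus one column per marker.
    markers
        Marker columns to read. ``None`` treats every non-mandatory column as
        a marker.
    roi_width, roi_height
        Field dimensions in μm applied to every ROI (the stamp size is fixed
        per acquisition, not stored per row).

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in CELL_TABLE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table {path}: missing mandatory column {col!r}")
    if markers is None:
        markers = [c for c in df.columns if c not in CELL_TABLE_COLUMNS]
    else:
        for m in markers:
            if m not in df.columns:
                raise SchemaError(f"cell table {path}: missing marker column {m!r}")

    grouped: dict[str, list[Cell]] = {}
    roi_meta: dict[str, tuple[str, str]] = {}
    columns = list(df.columns)
    for i, values in enumerate(df.itertuples(index=False, name=None), start=1):
        rec = dict(zip(columns, values))
        try:
            x = float(rec["x_um"])
            y = float(rec["y_um"])
        except ValueError:
            raise ValueError(f"row {i}: non-numeric coordinate "
                             f"x_um={rec['x_um']!r} y_um={rec['y_um']!r}") from None
        region = str(rec["region"]).strip().upper()
        if region not in VALID_REGIONS:
            raise ValueError(f"row {i}: unknown region label {rec['region']!r}")
        cell_class = str(rec["cell_class"]).strip().lower()
        if cell_class not in VALID_CLASSES:
            raise ValueError(f"row {i}: unknown cell_class {rec['cell_class']!r}")
        marker_values: dict[str, int] = {}
        for m in markers:
            raw = rec[m]
            try:
                val = int(float(raw))
            except ValueError:
                raise ValueError(f"row {i}: marker {m!r} intensity {raw!r} "
                                 "is not numeric") from None
            if val not in VALID_INTENSITIES or float(raw) != val:
                raise ValueError(f"row {i}: marker {m!r} intensity {raw!r} "
                                 "not in {0,1,2,3}")
            marker_values[m] = val
        roi_id = str(rec["roi_id"])
        cell = Cell(
            cell_id=str(rec["cell_id"]),
            x=x,
            y=y,
            cell_class=cell_class,
            markers=marker_values,
        )
        meta = (str(rec["patient_id"]), region)
        if roi_id in roi_meta and roi_meta[roi_id] != meta:
            raise ValueError(
                f"row {i}: roi_id {roi_id!r} has inconsistent patient/region"
            )
        roi_meta[roi_id] = meta
        grouped.setdefault(roi_id, []).append(cell)

    rois = [
        ROI(
            roi_id=roi_id,
            patient_id=roi_meta[roi_id][0],
            region=roi_meta[roi_id][1],
            cells=cells,
            width=roi_width,
            height=roi_height,
        )
        for roi_id, cells in grouped.items()
    ]
    assert sum(r.n_cells for r in rois) == len(df)  # no row silently dropped
    return rois


def _parse_optional_float(raw: str, col: str, row: int):
    raw = raw.strip()
    if raw == "" or raw.lower() in ("na", "nan", "none"):
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"row {row}: column {col!r} value {raw!r} is not numeric") from None


def _parse_optional_bool(raw: str, col: str, row: int):
    raw = raw.strip().lower()
    if raw in ("", "na", "nan", "none"):
        return None
    if raw in ("1", "true", "yes", "event", "1.0"):
        return True
    if raw in ("0", "false", "no", "censored", "0.0"):
        return False
    raise ValueError(f"row {row}: column {col!r} value {raw!r} is not boolean")


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read a per-patient clinical CSV.

    Only ``patient_id`` is mandatory; blank survival cells become missing
    values, never zeros. Any column that is not a recognized fixed field is
    kept as a covariate. Duplicate patient ids raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise SchemaError(f"patient table {path}: missing column 'patient_id'")
    covariate_cols = [c for c in df.columns if c not in _PATIENT_FIXED_COLS]

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, values in enumerate(df.itertuples(index=False, name=None), start=1):
        rec = dict(zip(df.columns, values))
        pid = str(rec["patient_id"]).strip()
        if pid in seen:
            raise ValueError(f"row {i}: duplicate patient_id {pid!r}")
        seen.add(pid)
        kwargs: dict = {"patient_id": pid}
        if "cldn_status" in rec and str(rec["cldn_status"]).strip():
            kwargs["cldn_status"] = str(rec["cldn_status"]).strip().lower()
        if "cldn_proportion" in rec:
            v = _parse_optional_float(rec["cldn_proportion"], "cldn_proportion", i)
            if v is not None:
                kwargs["cldn_proportion"] = v
        if "response" in rec and str(rec["response"]).strip():
            kwargs["response"] = str(rec["response"]).strip().lower()
        for col in _SURVIVAL_TIME_COLS:
            if col in rec:
                kwargs[col] = _parse_optional_float(rec[col], col, i)
        for col in _SURVIVAL_EVENT_COLS:
            if col in rec:
                kwargs[col] = _parse_optional_bool(rec[col], col, i)
        kwargs["covariates"] = {
            c: rec[c] for c in covariate_cols if str(rec[c]).strip() != ""
        }
        records.append(PatientRecord(**kwargs))
    return records


def write_report_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as CSV with deterministic column order.

    Missing values are written as empty fields so that a round-trip read
    returns the same table.
    """
    rows.to_csv(path, index=False)


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_report_table`."""
    return pd.read_csv(path)


def write_cell_table(rois: Iterable[ROI], path: str | Path) -> None:
    """Write ROIs to the per-cell CSV schema (inverse of read_cell_table)."""
    rois = list(rois)
    markers: list[str] = []
    for roi in rois:
        for cell in roi.cells:
            for m in cell.markers:
                if m not in markers:
                    markers.append(m)
    records = []
    for roi in rois:
        for cell in roi.cells:
            rec = {
                "cell_id": cell.cell_id,
                "roi_id": roi.roi_id,
                "patient_id": roi.patient_id,
                "region": roi.region,
                "x_um": cell.x,
                "y_um": cell.y,
                "cell_class": cell.cell_class,
            }
            for m in markers:
                rec[m] = cell.markers.get(m, 0)
            records.append(rec)
    cols = list(CELL_TABLE_COLUMNS) + markers
    pd.DataFrame(records, columns=cols).to_csv(path, index=False)


def write_patient_table(patients: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patient records to the clinical CSV schema."""
    patients = list(patients)
    cov_cols: list[str] = []
    for p in patients:
        for c in p.covariates:
            if c not in cov_cols:
                cov_cols.append(c)
    records = []
    for p in patients:
        rec = {
            "patient_id": p.patient_id,
            "cldn_status": p.cldn_status if p.cldn_status != "unset" else "",
            "cldn_proportion": "" if p.cldn_proportion is None else p.cldn_proportion,
            "response": p.response if p.response != "missing" else "",
        }
        for name in ("os", "iros", "irpfs"):
            t = getattr(p, f"{name}_months")
            e = getattr(p, f"{name}_event")
            rec[f"{name}_months"] = "" if t is None else t
            rec[f"{name}_event"] = "" if e is None else int(e)
        for c in cov_cols:
            rec[c] = p.covariates.get(c, "")
        records.append(rec)
    cols = list(_PATIENT_FIXED_COLS) + cov_cols
    pd.DataFrame(records, columns=cols).to_csv(path, index=False)
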