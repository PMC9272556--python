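"""Core domain types: cells, regions of interest, patients, cohorts.

The data model mirrors per-cell tables exported by supervised image-analysis
software after multispectral unmixing and segmentation: each row is one
DAPI-identified cell with a nucleus centroid in micrometers, a tumor/immune/
other class label, and per-marker staining readouts. Marker readouts use a
single ordinal 0-3 scale; binary (fluorescence-gated) markers occupy {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

VALID_REGIONS = ("TC", "IM", "N")
VALID_CLASSES = ("tumor", "immune", "other")
VALID_INTENSITIES = (0, 1, 2, 3)

CLDN_MARKER = "CLDN18.2"


class SchemaError(ValueError):
    """A table is missing a mandatory column or has a malformed header."""


@dataclass(frozen=True)
class Cell:
    """One segmented cell: nucleus centroid (μm), class, marker intensities."""

    cell_id: str
    x: float
    y: float
    cell_class: str
    markers: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_class not in VALID_CLASSES:
            raise ValueError(
                f"cell {self.cell_id!r}: cell_class {self.cell_class!r} "
                f"not in {VALID_CLASSES}"
            )
        for marker, value in self.markers.items():
            if value not in VALID_INTENSITIES:
                raise ValueError(
                    f"cell {self.cell_id!r}: marker {marker!r} intensity "
                    f"{value!r} not in {{0,1,2,3}}"
                )

    def intensity(self, marker: str) -> int:
        try:
            return self.markers[marker]
        except KeyError:
            raise KeyError(
                f"cell {self.cell_id!r} has no readout for marker {marker!r}"
            ) from None


@dataclass
class ROI:
    """A fixed-size imaged field (default 930 × 700 μm stamp) of one region.

    ``region`` is one of TC (tumor core), IM (invasion margin) or N
    (tumor-adjacent normal tissue). Coordinates of member cells are local to
    the ROI, origin at the top-left corner, y increasing downward.
    """

    roi_id: str
    patient_id: str
    region: str
    cells: list[Cell] = field(default_factory=list)
    width: float = 930.0
    height: float = 700.0

    def __post_init__(self) -> None:
        if self.region not in VALID_REGIONS:
            raise ValueError(
                f"ROI {self.roi_id!r}: region {self.region!r} not in {VALID_REGIONS}"
            )
        if not (self.width > 0 and self.height > 0):
            raise ValueError(f"ROI {self.roi_id!r}: non-positive dimensions")
        seen: set[str] = set()
        for cell in self.cells:
            if cell.cell_id in seen:
                raise ValueError(
                    f"ROI {self.roi_id!r}: duplicate cell_id {cell.cell_id!r}"
                )
            seen.add(cell.cell_id)
            if not (0.0 <= cell.x <= self.width and 0.0 <= cell.y <= self.height):
                raise ValueError(
                    f"ROI {self.roi_id!r}: cell {cell.cell_id!r} at "
                    f"({cell.x}, {cell.y}) outside {self.width}×{self.height} field"
                )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cells_of_class(self, cell_class: str) -> list[Cell]:
        return [c for c in self.cells if c.cell_class == cell_class]


@dataclass
class PatientRecord:
    """Clinical record: CLDN18.2 status, covariates, survival endpoints.

    Survival times are months; a missing time is ``None`` (never zero), and an
    event flag must be present whenever its time is. ``response`` follows
    RECIST: CR/PR are responders, SD/PD non-responders.
    """

    patient_id: str
    cldn_status: str = "unset"  # positive | negative | unset
    cldn_proportion: Optional[float] = None
    covariates: dict = field(default_factory=dict)
    os_months: Optional[float] = None
    os_event: Optional[bool] = None
    iros_months: Optional[float] = None
    iros_event: Optional[bool] = None
    irpfs_months: Optional[float] = None
    irpfs_event: Optional[bool] = None
    response: str = "missing"  # responder | non_responder | missing

    def __post_init__(self) -> None:
        if self.cldn_status not in ("positive", "negative", "unset"):
            raise ValueError(f"bad cldn_status {self.cldn_status!r}")
        if self.response not in ("responder", "non_responder", "missing"):
            raise ValueError(f"bad response {self.response!r}")
        if self.cldn_proportion is not None and not (0.0 <= self.cldn_proportion <= 1.0):
            raise ValueError("cldn_proportion outside [0, 1]")
        for name in ("os", "iros", "irpfs"):
            t = getattr(self, f"{name}_months")
            e = getattr(self, f"{name}_event")
            if t is not None:
                if t < 0:
                    raise ValueError(
                        f"patient {self.patient_id!r}: negative {name}_months"
                    )
                if e is None:
                    raise ValueError(
                        f"patient {self.patient_id!r}: {name}_months present "
                        f"but {name}_event missing"
                    )


@dataclass
class Cohort:
    """All patients and their ROIs; every ROI must resolve to one patient."""

    patients: list[PatientRecord]
    rois: list[ROI]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient_id in cohort")
        known = set(ids)
        for roi in self.rois:
            if roi.patient_id not in known:
                raise ValueError(
                    f"ROI {roi.roi_id!r} references unknown patient "
                    f"{roi.patient_id!r}"
                )

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def rois_of(self, patient_id: str, region: Optional[str] = None) -> list[ROI]:
        out = [r for r in self.rois if r.patient_id == patient_id]
        if region is not None:
            out = [r for r in out if r.region == region]
        return out
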