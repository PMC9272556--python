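"""Marker-combination phenotyping and sample-level CLDN18.2 calling.

Immune subtypes are defined by boolean marker gates (e.g. ``CD8+PD-1−`` is
CD8 ≥ 1 and PD-1 = 0 on an immune-class cell). Phenotyping is multi-label:
a cell receives every phenotype whose rule it satisfies, so nested subtypes
(CD8+ ⊃ CD8+PD-1−) are counted consistently.

Sample-level CLDN18.2 positivity follows the FAST-trial rule: a patient is
positive when at least 40% of tumor cells show membrane staining intensity
of 2+ or stronger, pooled over the patient's tumor-core fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .types import CLDN_MARKER, Cell, ROI


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A boolean marker-combination rule naming one cell subtype.

    ``positive`` maps marker name to the minimum intensity required
    (defaulting to 1 when built from a bare marker list); ``negative`` maps
    marker name to the maximum intensity allowed (default 0).
    """

    name: str
    require_class: str = "immune"  # tumor | immune | any
    positive: Mapping[str, int] = field(default_factory=dict)
    negative: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.require_class not in ("tumor", "immune", "any"):
            raise ValueError(f"{self.name}: bad require_class {self.require_class!r}")
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(
                f"{self.name}: markers {sorted(overlap)} both positive and negative"
            )

    @property
    def markers(self) -> set[str]:
        return set(self.positive) | set(self.negative)

    def matches(self, cell: Cell) -> bool:
        if self.require_class != "any" and cell.cell_class != self.require_class:
            return False
        for marker, lo in self.positive.items():
            if cell.intensity(marker) < lo:
                return False
        for marker, hi in self.negative.items():
            if cell.intensity(marker) > hi:
                return False
        return True


@dataclass
class PanelConfig:
    """A marker panel with its phenotype catalogue and CLDN18.2 cutoffs."""

    markers: list[str]
    phenotypes: list[PhenotypeDefinition]
    cldn_marker: str = CLDN_MARKER
    cldn_intensity_cutoff: int = 2
    cldn_proportion_cutoff: float = 0.40

    def __post_init__(self) -> None:
        names = [p.name for p in self.phenotypes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate phenotype names in panel")
        known = set(self.markers)
        for p in self.phenotypes:
            missing = p.markers - known
            if missing:
                raise ValueError(
                    f"phenotype {p.name!r} references markers {sorted(missing)} "
                    "absent from the panel"
                )
        if self.cldn_intensity_cutoff not in (1, 2, 3):
            raise ValueError("cldn_intensity_cutoff must be 1, 2 or 3")
        if not (0.0 <= self.cldn_proportion_cutoff <= 1.0):
            raise ValueError("cldn_proportion_cutoff outside [0, 1]")

    def phenotype(self, name: str) -> PhenotypeDefinition:
        for p in self.phenotypes:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def phenotype_names(self) -> list[str]:
        return [p.name for p in self.phenotypes]

    @classmethod
    def from_dict(cls, data: Mapping) -> "PanelConfig":
        phenos = []
        for spec in data.get("phenotypes", []):
            pos = spec.get("positive", {})
            if isinstance(pos, (list, tuple)):
                pos = {m: 1 for m in pos}
            neg = spec.get("negative", {})
            if isinstance(neg, (list, tuple)):
                neg = {m: 0 for m in neg}
            phenos.append(
                PhenotypeDefinition(
                    name=spec["name"],
                    require_class=spec.get("class", "immune"),
                    positive=dict(pos),
                    negative=dict(neg),
                )
            )
        return cls(
            markers=list(data["markers"]),
            phenotypes=phenos,
            cldn_marker=data.get("cldn_marker", CLDN_MARKER),
            cldn_intensity_cutoff=int(data.get("cldn_intensity_cutoff", 2)),
            cldn_proportion_cutoff=float(data.get("cldn_proportion_cutoff", 0.40)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "phenotypes": [
                {
                    "name": p.name,
                    "class": p.require_class,
                    "positive": dict(p.positive),
                    "negative": dict(p.negative),
                }
                for p in self.phenotypes
            ],
            "cldn_marker": self.cldn_marker,
            "cldn_intensity_cutoff": self.cldn_intensity_cutoff,
            "cldn_proportion_cutoff": self.cldn_proportion_cutoff,
        }


def default_panel() -> PanelConfig:
    """The built-in panel: lymphoid/myeloid subtypes gated on checkpoint markers.

    Covers the subtypes commonly reported for gastric-cancer m-IHC panels:
    CD8 T cells split by PD-1/LAG-3/TIM-3, CD4 T cells split by FoxP3
    (Tregs), CTLA-4 and PD-L1, CD20 B cells, CD66b neutrophils, and
    CD68/CD163/HLA-DR macrophage M1/M2 polarization. Users can extend or
    replace it via a YAML panel file.
    """
    P = PhenotypeDefinition
    phenotypes = [
        P("CD8+", positive={"CD8": 1}),
        P("CD8+PD-1-", positive={"CD8": 1}, negative={"PD-1": 0}),
        P("CD8+PD-1+", positive={"CD8": 1, "PD-1": 1}),
        P("CD8+LAG-3-", positive={"CD8": 1}, negative={"LAG-3": 0}),
        P("CD8+LAG-3+", positive={"CD8": 1, "LAG-3": 1}),
        P("CD8+TIM-3-", positive={"CD8": 1}, negative={"TIM-3": 0}),
        P("CD8+TIM-3+", positive={"CD8": 1, "TIM-3": 1}),
        P("CD4+", positive={"CD4": 1}),
        P("CD4+FoxP3-", positive={"CD4": 1}, negative={"FoxP3": 0}),
        P("Treg", positive={"CD4": 1, "FoxP3": 1}),
        P("CD4+CTLA-4+", positive={"CD4": 1, "CTLA-4": 1}),
        P("CD4+PD-L1+", positive={"CD4": 1, "PD-L1": 1}),
        P("B cell", positive={"CD20": 1}),
        P("Neutrophil", positive={"CD66b": 1}),
        P("Macrophage", positive={"CD68": 1}),
        P("M1", positive={"CD68": 1, "HLA-DR": 1}, negative={"CD163": 0}),
        P("M2", positive={"CD68": 1, "CD163": 1}, negative={"HLA-DR": 0}),
    ]
    markers = [
        "CD8",
        "PD-1",
        "LAG-3",
        "TIM-3",
        "CD4",
        "FoxP3",
        "CTLA-4",
        "PD-L1",
        "CD20",
        "CD66b",
        "CD68",
        "CD163",
        "HLA-DR",
        CLDN_MARKER,
    ]
    return PanelConfig(markers=markers, phenotypes=phenotypes)


def assign_phenotypes(
    cells: Iterable[Cell], panel: PanelConfig
) -> dict[str, set[str]]:
    """Label each cell with every panel phenotype whose gate it satisfies.

    Returns a map cell_id → set of phenotype names (empty set when no rule
    matches). Raises ``KeyError`` naming the cell and marker if a referenced
    marker readout is absent.
    """
    labels: dict[str, set[str]] = {}
    for cell in cells:
        hits = {p.name for p in panel.phenotypes if p.matches(cell)}
        labels[cell.cell_id] = hits
    return labels


def classify_cldn_status(
    rois: Sequence[ROI],
    panel: PanelConfig,
    region: str = "TC",
) -> tuple[str, float]:
    """Call a patient's CLDN18.2 status from their tumor-core fields.

    Pools tumor cells across the patient's ROIs of ``region`` and computes
    the fraction with CLDN18.2 intensity at or above the panel's intensity
    cutoff (default 2+). Status is positive when that fraction reaches the
    proportion cutoff (default 40%, inclusive).
    """
    n_tumor = 0
    n_stained = 0
    for roi in rois:
        if roi.region != region:
            continue
        for cell in roi.cells_of_class("tumor"):
            n_tumor += 1
            if cell.intensity(panel.cldn_marker) >= panel.cldn_intensity_cutoff:
                n_stained += 1
    if n_tumor == 0:
        raise ValueError("no tumor cells for CLDN18.2 call")
    proportion = n_stained / n_tumor
    status = (
        "positive" if proportion >= panel.cldn_proportion_cutoff else "negative"
    )
    return status, proportion


def compute_rate(
    roi: ROI, phenotype: str, labels: Mapping[str, set[str]]
) -> float:
    """Rate of one phenotype in one field: target cells / all cells."""
    if roi.n_cells == 0:
        raise ValueError(f"ROI {roi.roi_id!r} is empty; rate undefined")
    n_target = sum(1 for c in roi.cells if phenotype in labels[c.cell_id])
    return n_target / roi.n_cells


def aggregate_patient_rate(
    rois: Sequence[ROI],
    region: str,
    phenotype: str,
    labels: Mapping[str, set[str]],
    mode: str = "mean",
) -> Optional[float]:
    """One rate per patient per region, aggregated over their ROIs.

    ``mean`` (default) averages per-ROI rates with equal weight; ``pooled``
    divides total target cells by total cells across the ROIs. Returns
    ``None`` when the patient has no non-empty ROI of the region.
    """
    if mode not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    qualifying = [r for r in rois if r.region == region and r.n_cells > 0]
    if not qualifying:
        return None
    if mode == "mean":
        return sum(compute_rate(r, phenotype, labels) for r in qualifying) / len(
            qualifying
        )
    n_target = sum(
        1
        for r in qualifying
        for c in r.cells
        if phenotype in labels[c.cell_id]
    )
    n_total = sum(r.n_cells for r in qualifying)
    return n_target / n_total
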