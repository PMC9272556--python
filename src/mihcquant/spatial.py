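"""Fixed-radius tumor-centric neighbor graphs and their summary statistics.

Within one imaged field, every central (tumor/epithelial) cell is paired
with every peripheral (immune) cell whose nucleus centroid lies within a
fixed radius (default 20 μm, boundary inclusive). The resulting bipartite
edge set yields two statistics:

- effective score  = number of edges / number of central cells — the mean
  number of immune neighbors per tumor cell;
- effective percent = central cells with at least one edge / central cells —
  the fraction of tumor cells in contact range of the immune phenotype.

Both are computed per ROI; patient-level values aggregate over the
patient's fields of a region (mean of per-ROI values by default, or pooled
counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .types import Cell, Cohort, ROI

DEFAULT_RADIUS_UM = 20.0


@dataclass
class NeighborGraph:
    """Bipartite central–peripheral pairing within a fixed radius."""

    central_ids: list[str]
    peripheral_ids: list[str]
    edges: set[tuple[str, str]]  # (central_id, peripheral_id)
    radius: float

    def __post_init__(self) -> None:
        central = set(self.central_ids)
        peripheral = set(self.peripheral_ids)
        if central & peripheral:
            raise ValueError(
                "central and peripheral cell sets overlap: "
                f"{sorted(central & peripheral)[:5]}"
            )
        for c, p in self.edges:
            if c not in central or p not in peripheral:
                raise ValueError(f"edge ({c!r}, {p!r}) references unknown cell")

    @property
    def n_central(self) -> int:
        return len(self.central_ids)

    @property
    def n_peripheral(self) -> int:
        return len(self.peripheral_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def central_degrees(self) -> dict[str, int]:
        deg = {c: 0 for c in self.central_ids}
        for c, _ in self.edges:
            deg[c] += 1
        return deg


@dataclass
class SpatialResult:
    roi_id: str
    phenotype: str
    n_central: int
    n_peripheral: int
    n_edges: int
    effective_score: float  # NaN when no central cells
    effective_percent: float


def build_neighbor_graph(
    central: Sequence[Cell],
    peripheral: Sequence[Cell],
    radius: float = DEFAULT_RADIUS_UM,
    toroidal: Optional[tuple[float, float]] = None,
) -> NeighborGraph:
    """Pair central with peripheral cells within ``radius`` μm (inclusive).

    Equivalent to the all-pairs rule: edge (c, p) exists iff the Euclidean
    nucleus-to-nucleus distance is ≤ radius. A k-d tree is used for speed.

    ``toroidal=(width, height)`` wraps distances on a torus; this exists for
    calibration against the homogeneous-Poisson closed form, where border
    truncation would otherwise bias the score downward. Pipeline analyses
    never wrap.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    central_ids = [c.cell_id for c in central]
    peripheral_ids = [p.cell_id for p in peripheral]
    edges: set[tuple[str, str]] = set()
    if central and peripheral:
        cxy = np.array([[c.x, c.y] for c in central], dtype=float)
        pxy = np.array([[p.x, p.y] for p in peripheral], dtype=float)
        if toroidal is not None:
            boxsize = np.array(toroidal, dtype=float)
            tree = cKDTree(np.mod(pxy, boxsize), boxsize=boxsize)
            neighbors = tree.query_ball_point(np.mod(cxy, boxsize), r=radius)
        else:
            tree = cKDTree(pxy)
            neighbors = tree.query_ball_point(cxy, r=radius)
        for ci, plist in enumerate(neighbors):
            for pi in plist:
                edges.add((central_ids[ci], peripheral_ids[pi]))
    return NeighborGraph(
        central_ids=central_ids,
        peripheral_ids=peripheral_ids,
        edges=edges,
        radius=radius,
    )


def effective_score(graph: NeighborGraph) -> float:
    """Edges per central cell; NaN when the field has no central cells."""
    if graph.n_central == 0:
        return float("nan")
    return graph.n_edges / graph.n_central


def effective_percent(graph: NeighborGraph) -> float:
    """Fraction of central cells with ≥1 peripheral neighbor; NaN if none."""
    if graph.n_central == 0:
        return float("nan")
    with_edge = len({c for c, _ in graph.edges})
    return with_edge / graph.n_central


def csr_expected_score(lambda_peripheral: float, radius: float) -> float:
    """Expected effective score under complete spatial randomness: λ·π·r².

    ``lambda_peripheral`` is the peripheral-cell intensity in cells/μm².
    Ignores edge effects (exact on a torus).
    """
    if lambda_peripheral < 0:
        raise ValueError("lambda_peripheral must be non-negative")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    return lambda_peripheral * math.pi * radius * radius


def roi_spatial_result(
    roi: ROI,
    phenotype: str,
    labels: Mapping[str, set[str]],
    radius: float = DEFAULT_RADIUS_UM,
    toroidal: bool = False,
) -> SpatialResult:
    """Spatial statistics of one phenotype in one field.

    Central cells are the ROI's tumor-class cells (in normal-tissue fields
    these are the epithelial cells); peripheral cells are the non-tumor
    cells carrying the phenotype label.
    """
    central = roi.cells_of_class("tumor")
    peripheral = [
        c
        for c in roi.cells
        if c.cell_class != "tumor" and phenotype in labels[c.cell_id]
    ]
    graph = build_neighbor_graph(
        central,
        peripheral,
        radius=radius,
        toroidal=(roi.width, roi.height) if toroidal else None,
    )
    return SpatialResult(
        roi_id=roi.roi_id,
        phenotype=phenotype,
        n_central=graph.n_central,
        n_peripheral=graph.n_peripheral,
        n_edges=graph.n_edges,
        effective_score=effective_score(graph),
        effective_percent=effective_percent(graph),
    )


def aggregate_patient_spatial(
    rois: Sequence[ROI],
    region: str,
    phenotype: str,
    labels: Mapping[str, set[str]],
    radius: float = DEFAULT_RADIUS_UM,
    mode: str = "mean",
) -> tuple[Optional[float], Optional[float]]:
    """Patient-level (effective_score, effective_percent) over a region.

    Fields without central cells are excluded. ``mean`` averages per-ROI
    values; ``pooled`` sums edges/centrals across fields. Returns
    ``(None, None)`` when no field qualifies.
    """
    if mode not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    results = [
        roi_spatial_result(r, phenotype, labels, radius=radius)
        for r in rois
        if r.region == region
    ]
    results = [r for r in results if r.n_central > 0]
    if not results:
        return None, None
    if mode == "mean":
        score = sum(r.effective_score for r in results) / len(results)
        percent = sum(r.effective_percent for r in results) / len(results)
        return score, percent
    n_central = sum(r.n_central for r in results)
    n_edges = sum(r.n_edges for r in results)
    # pooled percent needs per-ROI counts of centrals with an edge
    n_with = sum(round(r.effective_percent * r.n_central) for r in results)
    return n_edges / n_central, n_with / n_central


def spatial_table(
    cohort: Cohort,
    phenotypes: Sequence[str],
    labels: Mapping[str, set[str]],
    radius: float = DEFAULT_RADIUS_UM,
    regions: Sequence[str] = ("TC",),
) -> pd.DataFrame:
    """Per-ROI spatial statistics for each phenotype and region."""
    rows = []
    for roi in cohort.rois:
        if roi.region not in regions:
            continue
        for ph in phenotypes:
            res = roi_spatial_result(roi, ph, labels, radius=radius)
            rows.append(
                {
                    "roi_id": roi.roi_id,
                    "patient_id": roi.patient_id,
                    "region": roi.region,
                    "phenotype": ph,
                    "n_central": res.n_central,
                    "n_peripheral": res.n_peripheral,
                    "n_edges": res.n_edges,
                    "effective_score": res.effective_score,
                    "effective_percent": res.effective_percent,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "roi_id",
            "patient_id",
            "region",
            "phenotype",
            "n_central",
            "n_peripheral",
            "n_edges",
            "effective_score",
            "effective_percent",
        ],
    )
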