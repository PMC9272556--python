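"""End-to-end orchestration: phenotype → spatial → stats → survival → reports.

``analyze_cohort`` is the in-memory core (returns a dict of DataFrames);
``run_pipeline`` wraps it with file I/O, a run manifest and all-or-nothing
output handling. Outputs are deterministic given inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    read_cell_table,
    read_patient_table,
    write_report_table,
)
from .phenotyping import (
    PanelConfig,
    aggregate_patient_rate,
    assign_phenotypes,
    classify_cldn_status,
    default_panel,
)
from .spatial import DEFAULT_RADIUS_UM, aggregate_patient_spatial, spatial_table
from .stats import PsiRecord, compare_groups, filter_psi
from .survival import km_curve_table, survival_report
from .types import Cohort

REPORT_FILES = (
    "rates.csv",
    "spatial.csv",
    "comparisons.csv",
    "correlations.csv",
    "survival.csv",
    "km_curves.csv",
    "manifest.json",
)


@dataclass
class RunConfig:
    cells: str
    patients: str
    panel: Optional[str] = None
    psi: Optional[str] = None
    out: str = "reports"
    radius: float = DEFAULT_RADIUS_UM
    agg: str = "mean"  # mean | pooled
    ttest: str = "welch"  # welch | pooled
    alpha: float = 0.05
    regions: tuple[str, ...] = ("TC", "N")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


class PipelineError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def call_cldn_status(cohort: Cohort, panel: PanelConfig) -> None:
    """Fill in each patient's CLDN18.2 status from their TC fields.

    Patients with a preset status keep it; patients without tumor-core
    cells stay unset and are excluded from group comparisons.
    """
    for patient in cohort.patients:
        if patient.cldn_status != "unset":
            continue
        rois = cohort.rois_of(patient.patient_id, region="TC")
        try:
            status, prop = classify_cldn_status(rois, panel)
        except ValueError:
            continue
        patient.cldn_status = status
        patient.cldn_proportion = prop


def rate_table(
    cohort: Cohort,
    panel: PanelConfig,
    labels,
    regions: Sequence[str] = ("TC", "N"),
    mode: str = "mean",
) -> pd.DataFrame:
    """Per-patient per-region rates of every panel phenotype."""
    rows = []
    for patient in cohort.patients:
        rois = cohort.rois_of(patient.patient_id)
        for region in regions:
            for ph in panel.phenotype_names:
                rate = aggregate_patient_rate(rois, region, ph, labels, mode=mode)
                rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "region": region,
                        "phenotype": ph,
                        "rate": np.nan if rate is None else rate,
                        "cldn_status": patient.cldn_status,
                    }
                )
    return pd.DataFrame(
        rows, columns=["patient_id", "region", "phenotype", "rate", "cldn_status"]
    )


def patient_spatial_table(
    cohort: Cohort,
    panel: PanelConfig,
    labels,
    radius: float,
    regions: Sequence[str] = ("TC",),
    mode: str = "mean",
) -> pd.DataFrame:
    """Per-patient aggregated effective score / percent per phenotype."""
    rows = []
    for patient in cohort.patients:
        rois = cohort.rois_of(patient.patient_id)
        for region in regions:
            for ph in panel.phenotype_names:
                score, percent = aggregate_patient_spatial(
                    rois, region, ph, labels, radius=radius, mode=mode
                )
                rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "region": region,
                        "phenotype": ph,
                        "effective_score": np.nan if score is None else score,
                        "effective_percent": np.nan if percent is None else percent,
                        "cldn_status": patient.cldn_status,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "region",
            "phenotype",
            "effective_score",
            "effective_percent",
            "cldn_status",
        ],
    )


def comparison_table(
    patient_rates: pd.DataFrame,
    patient_spatial: pd.DataFrame,
    ttest_mode: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """CLDN18.2-positive vs -negative t-tests for every variable.

    Variables are each phenotype's rate per region plus its effective score
    and percent. Rows where either group has fewer than two patients with a
    value are skipped.
    """
    rows = []

    def add(variable: str, region: str, sub: pd.DataFrame, col: str) -> None:
        a = sub.loc[sub["cldn_status"] == "positive", col].dropna()
        b = sub.loc[sub["cldn_status"] == "negative", col].dropna()
        if len(a) < 2 or len(b) < 2:
            return
        res = compare_groups(
            a.tolist(),
            b.tolist(),
            mode=ttest_mode,
            variable=variable,
            group_a="positive",
            group_b="negative",
        )
        rows.append(
            {
                "variable": variable,
                "region": region,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "mean_a": res.mean_a,
                "mean_b": res.mean_b,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "test": res.test,
                "significant": int(res.p_value < alpha),
            }
        )

    for (region, ph), sub in patient_rates.groupby(["region", "phenotype"], sort=True):
        add(f"rate:{ph}", region, sub, "rate")
    for (region, ph), sub in patient_spatial.groupby(
        ["region", "phenotype"], sort=True
    ):
        add(f"effective_score:{ph}", region, sub, "effective_score")
        add(f"effective_percent:{ph}", region, sub, "effective_percent")
    return pd.DataFrame(
        rows,
        columns=[
            "variable",
            "region",
            "n_a",
            "n_b",
            "mean_a",
            "mean_b",
            "statistic",
            "p_value",
            "test",
            "significant",
        ],
    )


def correlation_table(patient_rates: pd.DataFrame, region: str = "TC") -> pd.DataFrame:
    """Pearson correlation matrix of per-patient phenotype rates."""
    wide = (
        patient_rates[patient_rates["region"] == region]
        .pivot(index="patient_id", columns="phenotype", values="rate")
        .dropna(axis=1, how="all")
    )
    corr = wide.corr(method="pearson")
    corr.index.name = "phenotype"
    return corr.reset_index()


def analyze_cohort(
    cohort: Cohort,
    panel: Optional[PanelConfig] = None,
    radius: float = DEFAULT_RADIUS_UM,
    agg: str = "mean",
    ttest: str = "welch",
    alpha: float = 0.05,
    regions: Sequence[str] = ("TC", "N"),
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage in memory and return the report tables."""
    panel = panel or default_panel()
    all_cells = [c for roi in cohort.rois for c in roi.cells]

    t0 = time.perf_counter()
    labels = assign_phenotypes(all_cells, panel)
    _log(f"[phenotype] {len(all_cells)} cells labeled "
         f"({time.perf_counter() - t0:.1f}s)")

    call_cldn_status(cohort, panel)
    n_pos = sum(1 for p in cohort.patients if p.cldn_status == "positive")
    _log(f"[cldn] {n_pos}/{len(cohort.patients)} patients CLDN18.2-positive")

    rates = rate_table(cohort, panel, labels, regions=regions, mode=agg)
    spatial_rois = spatial_table(
        cohort, panel.phenotype_names, labels, radius=radius,
        regions=[r for r in regions if r != "IM"],
    )
    n_excluded = int((spatial_rois["n_central"] == 0).sum())
    if n_excluded:
        _log(f"[spatial] {n_excluded} ROI×phenotype entries had no central "
             "cells and are excluded from aggregation")
    pspatial = patient_spatial_table(
        cohort, panel, labels, radius=radius,
        regions=[r for r in regions if r != "IM"], mode=agg,
    )
    comparisons = comparison_table(rates, pspatial, ttest_mode=ttest, alpha=alpha)
    correlations = correlation_table(rates)
    survival = survival_report(cohort.patients)
    km = km_curve_table(cohort.patients)
    return {
        "rates": rates,
        "spatial": spatial_rois,
        "patient_spatial": pspatial,
        "comparisons": comparisons,
        "correlations": correlations,
        "survival": survival,
        "km_curves": km,
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """File-to-file pipeline run; writes the report bundle to ``config.out``.

    Any stage failure removes partial outputs and re-raises as
    ``PipelineError`` naming the stage.
    """
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read"
    try:
        panel = (
            PanelConfig.from_yaml(config.panel) if config.panel else default_panel()
        )
        rois = read_cell_table(config.cells, markers=panel.markers)
        patients = read_patient_table(config.patients)
        cohort = Cohort(patients=patients, rois=rois)
        _log(f"[read] {len(patients)} patients, {len(rois)} ROIs, "
             f"{sum(r.n_cells for r in rois)} cells")

        stage = "analyze"
        tables = analyze_cohort(
            cohort,
            panel,
            radius=config.radius,
            agg=config.agg,
            ttest=config.ttest,
            alpha=config.alpha,
            regions=config.regions,
        )

        stage = "psi_filter"
        psi_kept = None
        if config.psi:
            psi_df = pd.read_csv(config.psi)
            if not {"sample_id", "psi"} <= set(psi_df.columns):
                raise ValueError("PSI table needs columns sample_id, psi")
            records = [
                PsiRecord(str(r.sample_id), float(r.psi))
                for r in psi_df.itertuples(index=False)
            ]
            psi_kept = filter_psi(records)
            _log(f"[psi] kept {len(psi_kept)}/{len(records)} samples "
                 "with PSI > 0.9")

        stage = "write"
        paths: dict[str, Path] = {}
        for name in (
            "rates",
            "spatial",
            "comparisons",
            "correlations",
            "survival",
            "km_curves",
        ):
            path = out_dir / f"{name}.csv"
            write_report_table(tables[name], path)
            written.append(path)
            paths[name] = path
        if psi_kept is not None:
            path = out_dir / "psi_filtered.csv"
            write_report_table(
                pd.DataFrame(
                    {
                        "sample_id": [r.sample_id for r in psi_kept],
                        "psi": [r.psi for r in psi_kept],
                    }
                ),
                path,
            )
            written.append(path)
            paths["psi_filtered"] = path
        manifest = {
            "tool": "mihcquant",
            "version": __version__,
            "config": dataclasses.asdict(config),
        }
        mpath = out_dir / "manifest.json"
        with open(mpath, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(mpath)
        paths["manifest"] = mpath
        return paths
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
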