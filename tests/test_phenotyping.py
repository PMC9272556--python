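"""Marker-gate phenotyping, CLDN18.2 calling, and rate computation."""

import itertools

import numpy as np
import pytest

from mihcquant.phenotyping import (
    PanelConfig,
    PhenotypeDefinition,
    aggregate_patient_rate,
    assign_phenotypes,
    classify_cldn_status,
    compute_rate,
    default_panel,
)
from mihcquant.types import CLDN_MARKER, Cell, ROI

from conftest import random_cells


def small_panel():
    return PanelConfig(
        markers=["CD8", "PD-1"],
        phenotypes=[
            PhenotypeDefinition("CD8+", positive={"CD8": 1}),
            PhenotypeDefinition("CD8+PD-1-", positive={"CD8": 1}, negative={"PD-1": 0}),
            PhenotypeDefinition("CD8+PD-1+", positive={"CD8": 1, "PD-1": 1}),
        ],
    )


def tumor_roi(intensities, roi_id="r", region="TC", patient="p"):
    cells = [
        Cell(f"t{i}", float(i % 30) * 10 + 1, float(i // 30) * 10 + 1, "tumor",
             {CLDN_MARKER: v})
        for i, v in enumerate(intensities)
    ]
    return ROI(roi_id, patient, region, cells=cells)


def cldn_panel():
    return PanelConfig(markers=[CLDN_MARKER], phenotypes=[])


class TestAssignPhenotypes:
    def test_nested_gates_are_multilabel(self):
        cell = Cell("c", 1, 1, "immune", {"CD8": 1, "PD-1": 0})
        labels = assign_phenotypes([cell], small_panel())
        assert labels["c"] == {"CD8+", "CD8+PD-1-"}

    def test_all_negative_cell_gets_empty_set(self):
        cell = Cell("c", 1, 1, "immune", {"CD8": 0, "PD-1": 0})
        assert assign_phenotypes([cell], small_panel())["c"] == set()

    def test_class_requirement_blocks_tumor_cells(self):
        cell = Cell("c", 1, 1, "tumor", {"CD8": 1, "PD-1": 0})
        assert assign_phenotypes([cell], small_panel())["c"] == set()

    def test_missing_marker_raises_naming_cell_and_marker(self):
        cell = Cell("c9", 1, 1, "immune", {"CD8": 1})
        with pytest.raises(KeyError, match="c9.*PD-1"):
            assign_phenotypes([cell], small_panel())

    def test_matches_brute_force_rule_oracle(self, panel):
        """1000 random cells: labels equal an independent re-evaluation."""
        rng = np.random.default_rng(42)
        cells = random_cells(rng, 1000, panel.markers)
        labels = assign_phenotypes(cells, panel)

        def oracle(cell, pheno):
            if pheno.require_class != "any" and cell.cell_class != pheno.require_class:
                return False
            ok = all(cell.markers[m] >= lo for m, lo in pheno.positive.items())
            return ok and all(cell.markers[m] <= hi for m, hi in pheno.negative.items())

        for cell in cells:
            expected = {p.name for p in panel.phenotypes if oracle(cell, p)}
            assert labels[cell.cell_id] == expected

    def test_idempotent_and_order_independent(self, panel):
        rng = np.random.default_rng(7)
        cells = random_cells(rng, 100, panel.markers)
        first = assign_phenotypes(cells, panel)
        again = assign_phenotypes(cells, panel)
        reversed_ = assign_phenotypes(list(reversed(cells)), panel)
        assert first == again == reversed_


class TestClassifyCldnStatus:
    def test_exact_forty_percent_is_positive(self):
        roi = tumor_roi([2] * 40 + [0] * 60)
        assert classify_cldn_status([roi], cldn_panel()) == ("positive", 0.40)

    def test_thirty_nine_percent_is_negative(self):
        roi = tumor_roi([2] * 39 + [0] * 61)
        status, prop = classify_cldn_status([roi], cldn_panel())
        assert status == "negative" and prop == pytest.approx(0.39)

    def test_half_above_cutoff_is_positive(self):
        roi = tumor_roi([3, 3, 1, 0])
        assert classify_cldn_status([roi], cldn_panel()) == ("positive", 0.5)

    def test_pools_across_rois(self):
        r1 = tumor_roi([2] * 10, roi_id="r1")  # 10/10
        r2 = tumor_roi([0] * 30, roi_id="r2")  # 0/30
        status, prop = classify_cldn_status([r1, r2], cldn_panel())
        assert prop == pytest.approx(0.25) and status == "negative"

    def test_non_tc_rois_ignored(self):
        tc = tumor_roi([0] * 10, roi_id="tc", region="TC")
        n = tumor_roi([3] * 90, roi_id="n", region="N")
        status, prop = classify_cldn_status([tc, n], cldn_panel())
        assert prop == 0.0 and status == "negative"

    def test_no_tumor_cells_raises(self):
        roi = ROI("r", "p", "TC", cells=[Cell("i", 1, 1, "immune", {CLDN_MARKER: 0})])
        with pytest.raises(ValueError, match="no tumor cells"):
            classify_cldn_status([roi], cldn_panel())

    def test_exhaustive_boundary_and_monotonicity(self):
        """All intensity assignments on ≤6 tumor cells: the 40% boundary is
        inclusive and raising any intensity never flips positive→negative."""
        panel = cldn_panel()
        for n in (3, 5, 6):
            for combo in itertools.product(range(4), repeat=n):
                status, prop = classify_cldn_status([tumor_roi(combo)], panel)
                expected = sum(1 for v in combo if v >= 2) / n
                assert prop == pytest.approx(expected)
                assert (status == "positive") == (prop >= 0.40)
                # raise one cell's intensity: call may only move toward positive
                for i in range(n):
                    if combo[i] == 3:
                        continue
                    bumped = list(combo)
                    bumped[i] += 1
                    status2, _ = classify_cldn_status([tumor_roi(bumped)], panel)
                    assert not (status == "positive" and status2 == "negative")


class TestRates:
    def test_rate_is_target_over_total(self):
        rng = np.random.default_rng(0)
        cells = [
            Cell(f"c{i}", float(rng.random() * 900), float(rng.random() * 690),
                 "immune", {"CD8": 1 if i < 53 else 0, "PD-1": 0})
            for i in range(1000)
        ]
        roi = ROI("r", "p", "TC", cells=cells)
        labels = assign_phenotypes(cells, small_panel())
        assert compute_rate(roi, "CD8+", labels) == pytest.approx(0.053)

    def test_rate_extremes(self):
        cells = [Cell(f"c{i}", 1.0 + i, 1.0, "immune", {"CD8": 1, "PD-1": 0})
                 for i in range(10)]
        roi = ROI("r", "p", "TC", cells=cells)
        labels = assign_phenotypes(cells, small_panel())
        assert compute_rate(roi, "CD8+", labels) == 1.0
        assert compute_rate(roi, "CD8+PD-1+", labels) == 0.0

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compute_rate(ROI("r", "p", "TC", cells=[]), "CD8+", {})

    def test_exhaustive_partition_rates_sum_to_one(self, small_cohort):
        """Mutually exclusive, jointly exhaustive phenotypes partition every
        field, so their rates sum to 1."""
        partition_panel = PanelConfig(
            markers=["CD8"],
            phenotypes=[
                PhenotypeDefinition("CD8-any-pos", require_class="any",
                                    positive={"CD8": 1}),
                PhenotypeDefinition("CD8-any-neg", require_class="any",
                                    negative={"CD8": 0}),
            ],
        )
        for roi in small_cohort.rois[:4]:
            labels = assign_phenotypes(roi.cells, partition_panel)
            total = sum(
                compute_rate(roi, name, labels)
                for name in ("CD8-any-pos", "CD8-any-neg")
            )
            assert total == pytest.approx(1.0)

    def test_aggregate_mean_mode(self):
        labels = {}
        rois = []
        for i, (n_pos, n_tot) in enumerate([(2, 100), (4, 100)]):
            cells = [
                Cell(f"r{i}c{j}", 1.0 + j, 1.0, "immune",
                     {"CD8": 1 if j < n_pos else 0, "PD-1": 0})
                for j in range(n_tot)
            ]
            rois.append(ROI(f"r{i}", "p", "TC", cells=cells))
            labels.update(assign_phenotypes(cells, small_panel()))
        assert aggregate_patient_rate(rois, "TC", "CD8+", labels) == pytest.approx(0.03)

    def test_aggregate_pooled_mode_weights_by_cell_count(self):
        labels = {}
        rois = []
        for i, (n_pos, n_tot) in enumerate([(50, 1000), (200, 4000)]):
            cells = [
                Cell(f"r{i}c{j}", 1.0 + (j % 900), 1.0 + (j // 900), "immune",
                     {"CD8": 1 if j < n_pos else 0, "PD-1": 0})
                for j in range(n_tot)
            ]
            rois.append(ROI(f"r{i}", "p", "TC", cells=cells))
            labels.update(assign_phenotypes(cells, small_panel()))
        pooled = aggregate_patient_rate(rois, "TC", "CD8+", labels, mode="pooled")
        assert pooled == pytest.approx(0.05)  # 250 / 5000

    def test_single_roi_identical_in_both_modes(self):
        cells = [Cell(f"c{j}", 1.0 + j, 1.0, "immune",
                      {"CD8": int(j < 3), "PD-1": 0}) for j in range(10)]
        roi = ROI("r", "p", "TC", cells=cells)
        labels = assign_phenotypes(cells, small_panel())
        mean = aggregate_patient_rate([roi], "TC", "CD8+", labels, mode="mean")
        pooled = aggregate_patient_rate([roi], "TC", "CD8+", labels, mode="pooled")
        assert mean == pooled == pytest.approx(0.3)

    def test_no_qualifying_roi_gives_missing(self):
        assert aggregate_patient_rate([], "TC", "CD8+", {}) is None


class TestPanelConfig:
    def test_phenotype_referencing_unknown_marker_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            PanelConfig(
                markers=["CD8"],
                phenotypes=[PhenotypeDefinition("x", positive={"CD4": 1})],
            )

    def test_positive_negative_overlap_rejected(self):
        with pytest.raises(ValueError, match="both"):
            PhenotypeDefinition("x", positive={"CD8": 1}, negative={"CD8": 0})

    def test_yaml_round_trip(self, tmp_path, panel):
        import yaml

        path = tmp_path / "panel.yaml"
        path.write_text(yaml.safe_dump(panel.to_dict()))
        back = PanelConfig.from_yaml(path)
        assert back.markers == panel.markers
        assert back.phenotype_names == panel.phenotype_names
        assert back.cldn_proportion_cutoff == 0.40

    def test_default_panel_m1_m2_disjoint(self, panel):
        m1 = panel.phenotype("M1")
        m2 = panel.phenotype("M2")
        for cd163 in (0, 1):
            for hladr in (0, 1):
                cell = Cell("c", 1, 1, "immune",
                            {"CD68": 1, "CD163": cd163, "HLA-DR": hladr})
                assert not (m1.matches(cell) and m2.matches(cell))
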