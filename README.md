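# mihcquant

Quantification of the tumor immune microenvironment from multiplex
immunohistochemistry (m-IHC) per-cell tables, built around CLDN18.2-stratified
gastric cancer but usable for any marker panel.

Given segmented-cell exports (one row per cell: field, coordinates in μm,
tumor/immune/other class, per-marker intensity 0–3), the package:

1. **phenotypes** cells by boolean marker gates (e.g. CD8+PD-1− := CD8 ≥ 1 ∧
   PD-1 = 0), multi-label so nested subtypes stay consistent;
2. **calls sample-level CLDN18.2 status** by the FAST-trial rule — positive
   when ≥ 40% of tumor cells show ≥ 2+ membrane staining, pooled over the
   patient's tumor-core fields;
3. **quantifies tumor–immune proximity** with fixed-radius (default 20 μm)
   bipartite pairing networks between central tumor cells and peripheral
   immune cells:

   - *effective score* = number of edges / number of central tumor cells
     (mean immune neighbors per tumor cell),
   - *effective percent* = central tumor cells with ≥ 1 edge / central tumor
     cells;

4. **compares patient groups** (per-phenotype rates = target cells / all
   cells, and the spatial metrics) with two-tailed t-tests, ANOVA, Pearson
   correlation and ROC-AUC, plus a strict PSI > 0.9 splice-isoform sample
   filter;
5. **analyzes survival** (OS, irOS, irPFS) with Kaplan–Meier curves, the
   Mantel–Cox log-rank test and a single-covariate proportional-hazards
   hazard ratio;
6. **simulates cohorts** with planted group differences (rates, spatial
   attraction, CLDN18.2 intensity, survival) so the whole pipeline is
   testable end to end without clinical data.

## Worked example

A tiny hand-placed 100 × 100 μm field with 4 tumor cells (CLDN18.2
intensities 3, 2, 1, 0), 4 CD8 T cells and 2 stromal cells:

```python
import mihcquant as m
from mihcquant.spatial import roi_spatial_result

roi = m.generate_worked_roi()
panel = m.default_panel()
labels = m.assign_phenotypes(roi.cells, panel)

status, prop = m.classify_cldn_status([roi], panel)
print(f"CLDN18.2 call: {status} ({prop:.0%} of tumor cells >= 2+)")

res = roi_spatial_result(roi, "CD8+", labels)
print(f"CD8+ rate: {m.compute_rate(roi, 'CD8+', labels):.2f}")
print(f"CD8+ effective score:   {res.effective_score:.2f}  "
      f"({res.n_edges} edges / {res.n_central} tumor cells)")
print(f"CD8+ effective percent: {res.effective_percent:.2f}")
```

prints

```
CLDN18.2 call: positive (50% of tumor cells >= 2+)
CD8+ rate: 0.40
CD8+ effective score:   1.00  (4 edges / 4 tumor cells)
CD8+ effective percent: 0.75
```

2 of the 4 tumor cells stain ≥ 2+, clearing the 40% cutoff; 4 of the 10
cells are CD8+; the 20-μm pairing network has 4 edges over 4 tumor cells of
which 3 have at least one CD8 neighbor.

## Command line

```sh
mihcquant simulate --n-per-group 40 --rois-per-patient 3 --seed 1 --out sim/
mihcquant run --cells sim/cells.csv --patients sim/patients.csv --out reports/
```

`run` writes per-patient rate and spatial tables, the positive-vs-negative
comparison table, a correlation matrix, the survival report with KM step
curves, and a manifest; reruns with the same inputs and seed are
byte-identical. `phenotype`, `spatial`, `stats` and `survival` run single
stages; `fixtures` writes a small demo cohort.

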