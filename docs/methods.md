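# Methods

## Data model

The pipeline consumes per-cell tables of the kind exported by supervised
multispectral image analysis after segmentation: one row per DAPI-identified
cell with a nucleus centroid (μm), a `tumor`/`immune`/`other` class assigned
upstream, and one ordinal intensity per marker. All marker readouts share a
single 0–3 scale; binary fluorescence gates occupy {0, 1}, the IHC-style
CLDN18.2 membrane stain uses the full range. Fields (ROIs) are fixed-size
stamps, 930 × 700 μm by default, tagged with a region: tumor core (TC),
invasion margin (IM) or tumor-adjacent normal tissue (N). Coordinates are
local to each field with the origin at the top-left corner and y increasing
downward (image convention); only relative distances enter any statistic, so
the choice of origin is immaterial. The pipeline never re-derives tumor vs
stroma — segmentation is upstream and trusted. IM fields are carried by the
schema but excluded from the default analyses, which use TC and N only.

## Phenotyping

An immune subtype is a boolean marker gate: a set of markers with minimum
intensities (default ≥ 1) and a set with maximum intensities (default 0),
restricted to a cell class. Phenotyping is multi-label — a CD8+PD-1− cell is
also CD8+ — because nested subtype counts require it. The built-in panel
covers CD8 T cells split by PD-1/LAG-3/TIM-3, CD4 T cells split by FoxP3
(Tregs), CTLA-4 and PD-L1, CD20 B cells, CD66b neutrophils and
CD68/CD163/HLA-DR macrophages with M1 (CD68+CD163−HLA-DR+) and M2
(CD68+CD163+HLA-DR−) polarization; arbitrary panels load from YAML.

Sample-level CLDN18.2 positivity follows the FAST-trial rule: a patient is
positive when ≥ 40% of tumor cells show ≥ 2+ membrane staining. Both cutoffs
are inclusive. The call pools tumor cells across the patient's TC fields
rather than voting per field, because positivity is a property of the
patient. The same rule applied to N fields (with epithelial cells classed as
`tumor` in those fields) gives a normal-tissue call.

The rate of a phenotype in a field is target cells / all cells. A patient's
per-region rate is, by default, the unweighted mean of their per-field
rates; a pooled mode (total target / total cells) is provided because the
aggregation rule is a genuinely open choice and the two differ when fields
vary in cellularity. The mean mode weights fields equally, which matches
treating fields as repeated measurements of the same tissue.

## Spatial statistics

Within one field, every central cell (tumor; epithelial in N fields) is
paired with every peripheral cell (immune cells of one phenotype) whose
nucleus lies within radius r of its own, Euclidean, boundary inclusive
(d ≤ r). Default r = 20 μm, roughly two cell diameters — the range over
which ligand–receptor contact is plausible. The pairing defines a bipartite
graph, and:

- effective score = edges / central cells (mean immune neighbors per tumor
  cell; unbounded above);
- effective percent = central cells with ≥ 1 edge / central cells.

Effective percent ≤ effective score always, with equality exactly when no
central cell has two neighbors. Both are non-decreasing in r and invariant
under rigid motions. Construction uses a k-d tree but is defined — and
tested — as identical to the O(n²) all-pairs rule. A peripheral cell may
pair with several centrals. Fields with zero central cells have undefined
metrics; they are flagged and excluded from patient aggregation, which
otherwise mirrors rate aggregation (mean over fields, pooled optional).

No edge-effect correction is applied to cells near field borders: border
discs are truncated, which biases both metrics slightly downward on real
fields. The CSR closed form E[score] = λπr² (λ = peripheral intensity in
cells/μm²) therefore holds exactly only with toroidal wrapping, which the
calibration tests use to isolate the estimator from that known bias;
analyses never wrap.

## Group statistics and survival

Patient-level variables (rates, spatial metrics) are compared between
CLDN18.2-positive and -negative patients with two-tailed independent-sample
t-tests — Welch by default, since equal variances between biologically
distinct groups is an assumption we prefer not to make; a pooled mode
exists. One-way ANOVA serves multi-group covariate comparisons, Pearson's r
the correlations, and a rank-statistic AUC (ties at 1/2) the
score-vs-response discrimination. Missing values are dropped per variable.
Significance is two-tailed P < 0.05 with no multiplicity correction by
default, matching common practice for exploratory microenvironment panels;
a Benjamini–Hochberg helper is available. The PSI filter keeps samples
whose percent-spliced-in value strictly exceeds 0.9, restricting expression
cohorts to those dominated by the isoform of interest.

Survival uses the Kaplan–Meier product-limit estimator (median = first t
with S(t) ≤ 0.5, reported as "not reached" when the curve stays above 0.5),
the Mantel–Cox log-rank test for two-group comparison, and a
single-covariate proportional-hazards fit on the group indicator for the
hazard ratio with a Wald 95% CI. Ties use Efron's method — the default of
standard survival software and robust at monthly granularity. Endpoints: OS
from diagnosis; irOS and irPFS from the start of immunotherapy, present
only for treated patients. On degenerate inputs (tiny groups with complete
separation) the partial likelihood is monotone and the HR is reported as
infinite rather than failing the run.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not images:
tumor cells are a homogeneous Poisson process over the field; immune cells
draw a lineage (CD8/CD4/CD20/CD66b/CD68) and conditional checkpoint markers
from per-group probabilities, so nested phenotypes are consistent by
construction; CLDN18.2 intensities on tumor cells follow a per-group
categorical over {0..3}; survival is exponential per group with independent
exponential censoring. Spatial attraction is a parent–offspring thinning:
with probability θ/(1+θ) an immune cell is placed uniformly in a 30-μm disc
around a random tumor cell, otherwise uniformly — monotone in θ, with θ = 0
giving complete spatial randomness. A Gibbs interaction model would be more
flexible but is harder to seed and calibrate; thinning is sufficient to
plant a detectable, monotone spatial effect.

Default conditions: 40 patients per group, 3 TC fields each, ~800 tumor /
700 immune / 300 stromal cells per field (typical ×20 high-power-field
cellularity). Group parameters are set so the planted differences match
the magnitudes reported for CLDN18.2-stratified gastric cancer: CD8+PD-1−
rates near 0.039 vs 0.026 (similarly LAG-3−/TIM-3− and CD66b), effective
scores near 0.15 vs 0.09, P(CLDN18.2 ≥ 2+) of 0.6 vs 0.2, and exponential
OS/irOS medians near 23.3/36.6 and 10.0/20.1 months. All randomness flows
from one integer seed through a hierarchical `SeedSequence` split
(cohort → group → patient → field), so any subset regenerates identically.

What the generator does not emulate — segmentation error, intensity
spillover between markers, within-patient field heterogeneity beyond
Poisson noise, non-exponential hazards, informative censoring — bounds what
passing tests show: they validate the estimators and the pipeline's
plumbing under the stated model, not robustness to imaging artifacts.

## Numerical and testing choices

- Boundary ties at exactly d = r are included; for continuous coordinates
  they are measure-zero, so the choice is test-relevant only.
- Rigid-motion invariance is asserted to 1e-9 (floating rotation error).
- Calibration checks are replicate-averaged to keep Monte-Carlo error well
  inside the asserted band: the CSR check pools ≥ 24,000 central cells
  (relative SE ≈ 0.6% against a 2% band); the KM-median check averages 20
  replicates of n = 500, since a single sample median at n = 500 has a
  standard error (~0.77 months) comparable to the 5% band itself.
- Null-calibration checks (type-I error 0.05 ± 0.02) use 1000 replicates,
  where the binomial SE (0.007) makes the band a ~3σ test.
- Problem sizes in the test suite (cohorts of 4–15 patients/group, fields
  of a few hundred cells) are chosen to exercise every code path at
  desk-scale; the acceptance script runs the full 40/group default.
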