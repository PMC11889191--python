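# Methods

This note documents the models and conventions behind `tmespat`: what the
synthetic generator simulates, how each statistic is defined and
calibrated, which choices were genuinely open, and what the passing tests
do and do not establish about real tissue data.

## Synthetic TMA model

The generator emits what a multiplex-immunofluorescence workflow produces
*after* segmentation and tissue classification: per-cell coordinate tables
with compartment labels and region-wise marker intensities. It does not
synthesize pixels, spectra or nuclei.

**Geometry.** A core is a disc (default diameter 0.6 mm) or a rectangle
(default 0.93 × 0.7 mm, one multispectral imaging field), rasterized on a
1 µm grid for area bookkeeping. Tumor nests are the upper level set of a
sum of random Gaussian bumps (default 20 bumps, σ ∈ [20, 60] µm),
thresholded at the quantile that puts exactly `tumor_fraction` (default
0.3) of core pixels inside. Thresholding a smooth field at a quantile
makes the tumor-area fraction exact by construction while keeping the
masks nest-like; a union of hard discs was considered and rejected because
it overshoots the target fraction by up to one disc. Compartment areas are
pixel counts, so `total = tumor + stroma` holds exactly.

**Cell placement.** Tumor cells are a Poisson sample inside the tumor
mask with the configured density *per mm² of tumor compartment* (nests are
locally dense, as in carcinoma); all other classes use density per mm² of
total core area. Immune classes follow the mixing regime by thinning a
homogeneous Poisson candidate process with acceptance probability
exp(−d/τ) to the nearest tumor cell (attraction) or 1 − exp(−d/τ)
(repulsion); τ = `mixing_strength` (default 30 µm) spans both regimes with
one knob. The candidate rate is inflated by the empirical mean acceptance
so the realized density matches the configured one in expectation. The
non-immune "other" class is always CSR.

**Intensities.** Each marker has a two-component log-normal model
(default log-means 0 and 2.5, log-SD 0.35 — well-separated components,
i.e., a clean staining panel). A cell draws from the positive component
only in the marker's designated region (FoxP3: nucleus; CD4: whole cell;
others: cytoplasm) and only when its true class — or its checkpoint flag
for PD-1/PD-L1 — expresses the marker; every other region and cell draws
background. Log-normal components keep intensities nonnegative and
right-skewed, like photon counts.

**Outcomes.** pCR labels are Bernoulli draws from a logistic model on
standardized per-patient features; subtype and TP53 labels are categorical
draws. Ground-truth classes and checkpoint flags are written to a separate
`truth.csv`, never into the analysis inputs.

**What the generator does not emulate:** segmentation errors, staining
artifacts and necrosis (real studies remove these by manual review),
spatially varying background, core-to-core staining batch effects, and
marker spillover. Tests passing on synthetic data therefore demonstrate
the correctness and calibration of the *statistics*, not robustness to
upstream imaging pathology.

## Cutoffs

`ecdf_cutoff` reproduces an annotation-guided workflow: the cutoff is the
minimum intensity among annotated positive cells when their ECDF rises
steeply and monotonically; when the normalized ECDF dips below the chord
joining its endpoints by more than 0.1 (maximum *signed* perpendicular
distance — a kneedle-style criterion), the cutoff moves to the kneepoint,
so isolated low-level outliers below the knee are treated as negative. The
signed (below-chord) form matters: a plain right-skewed positive
population bows *above* the chord and must not trigger the knee, which
would otherwise land mid-mass. Diagnostics report the knee score and the
fraction of all-negative annotated cells above the cutoff (background
check).

`otsu_cutoff` minimizes the weighted intra-class variance over the 255
interior edges of a fixed 256-bin equal-width histogram, with variances
computed exactly on the raw values via prefix sums and ties broken toward
the smaller threshold — bit-stable and equal by construction to an
exhaustive search over the same candidate set. It is used for cytokeratin
(bimodal pooled intensity) and as the fallback when no annotations exist.

Positivity is inclusive (≥ cutoff). The rule table is ordered by lineage
dominance (CK > CD68 > FoxP3 > CD8 > CD4 > other), which makes classes
disjoint and puts CD4⁺FoxP3⁺ cells in the regulatory-T class; it is
user-overridable via the run config because panel-specific tables vary
between laboratories.

## Densities

Multi-core patients are merged by pooled counts over pooled compartment
areas — never by averaging per-core densities, which would weight a small
core equally with a large one. Zero compartment area yields a missing
density (stroma-only cores are common in practice). Checkpoint-flagged
subclasses (e.g., `cytotoxic_t/pd1_pos`) are emitted alongside — i.e.,
overlapping with — their parent class, since exclusive counting would make
the subclass densities depend on the other flag's cutoff. The display
transform is log2(density + 1); the pseudocount of 1 cell/mm² maps zero
density to zero.

## Spatial statistics

`count_interactions` counts unordered reference–target and distinct
reference–reference pairs within an inclusive Euclidean radius via a
KD-tree; it equals the O(n²) definition exactly (tested), and duplicated
coordinates count as distinct cells. The NMS normalization

    NMS(r) = [I_rt · n_r(n_r−1)/2] / [I_rr · n_r · n_t]

makes the score ≈ 1 under complete spatial randomness (mean 1.001–1.009
at n = 100 + 100 over 500 simulations, within [0.95, 1.05]). I_rr = 0
yields a missing value rather than infinity: a patient with no co-located
reference pairs carries no mixing information at that radius.

The aggregated entropy pools neighbor counts over reference-cell
neighborhoods (center cell included, so the reference pool is never
empty) and takes the binary Shannon entropy of the pooled composition.
Pooled counting was chosen over averaging per-cell entropies: per-cell
entropies at small radii are dominated by small-count noise and Jensen
bias. The pattern label comes from the slope over the two smallest ladder
radii (ε = 1e-4 /µm for "flat"; the ε is a package convention, as the
field has no standard value).

### Calibration properties and their operating ranges

Two estimator properties matter for interpretation and set the conditions
of the calibration tests:

1. *Center-inclusion bias.* Including the center cell lifts the reference
   share at small radii, so under CSR E[H(r)] rises toward 1 with radius —
   a small positive (repulsion-signed) slope bias that shrinks as the
   expected neighbor count grows. It falls below ε at per-class densities
   around 1000/mm² and above. The CSR null calibration therefore uses
   n = 100 cells per class in a 250 × 250 µm window (≈1600/mm² per class,
   a realistic carcinoma cellularity), where the flat-pattern rate is
   ~95%. At sparse densities (≲500/mm²) the same estimator calls CSR
   "repulsion" more often; users analyzing sparse patterns should widen ε
   accordingly.

2. *Dynamic range of the gradient.* The entropy gradient measures how the
   class-composition imbalance changes across scales, so attraction is
   detectable only when the global composition is imbalanced while the
   small-radius neighborhoods are better mixed. With compact nests and an
   immune-dominated core (the default generator conditions), regime
   recovery at τ = 30 µm and 500 cells/mm² per class is ≥98% for both
   attraction and repulsion (100 cores each, pooled immune reference).
   With globally balanced class totals or very large nests, the entropy
   curve is flat at all radii and carries no attraction signal — a
   property of the statistic, not a bug in the estimator.

3. *Large-radius saturation of the NMS.* At radii comparable to the
   imaging-field size the cumulative pair counts saturate and the NMS is
   governed by each class's clustering relative to the window rather than
   by cross-class mixing; the expected attraction-vs-repulsion ordering
   holds robustly at close-interaction radii (≤ ~250–300 µm on a
   0.93 × 0.7 mm field) and inverts near the field scale. Group contrasts
   of NMS curves are therefore most informative at the lower half of the
   ladder.

Stitching places cores on a grid with boundary gaps strictly larger than
the maximal ladder radius, so statistics on a stitched multi-core patient
decompose exactly into per-core sums (tested against per-core oracles).

## Cohort statistics

Two-group contrasts use the Wilcoxon rank-sum test — exact null
distribution when both groups have ≤ 25 observations and no ties,
otherwise the tie-corrected normal approximation; k > 2 groups use
Kruskal–Wallis. All tests are two-sided at the 5% level with no
multiplicity adjustment. The type-I error of the two-group path is
calibrated ([3.5%, 6.5%] over 2000 null replicates at n = 50/group), and
its power against a 0.5-SD shift in log2 density at n = 100/group is
~92%. Contingency tables use Pearson's χ² unless an expected count is
below 5, in which case 2 × 2 tables switch to Fisher's exact test; larger
sparse tables keep χ² with a flag in the test name, as no exact r × c
test is available in the dependency set. Correlation matrices are
pairwise-complete Spearman with missing entries for constant columns or
fewer than three complete pairs.

## Pipeline

All inter-stage exchange is flat CSV plus a JSON manifest (seed, config
hash, file lists — no timestamps), so a clinical-adjacent analysis stays
auditable and a rerun with the same config and seed is byte-identical.
Default cohort sizes (24 patients × 2 cores) keep a full pipeline run
under ~20 s on one CPU; the calibration experiments in the test and
acceptance suites use 100–500 replicates, sized so each property is
measured with comfortable margin at interactive runtimes.

## Known limitations

- The classification rule table is a reconstruction of common lineage
  conventions, not a published reference table; override it per panel.
- The entropy-gradient ε and the kneedle threshold 0.1 are package
  conventions; both are documented knobs rather than field standards.
- The attraction/repulsion thinning model is phenomenological: it
  reproduces conditional intensity gradients around tumor cells, not any
  mechanistic migration model.
- easTILs is capped at 100%; the uncapped ratio is reported as a
  diagnostic.
- PD-1/PD-L1 subclass densities overlap their parent classes; consumers
  needing exclusive partitions must subtract.
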