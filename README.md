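# tmespat

Quantitative analysis of the tumor-immune microenvironment on
tissue-microarray (TMA) cell tables: digital tumor-infiltrating-lymphocyte
(dTIL) scoring, multiplex-immunofluorescence marker phenotyping via
intensity cutoffs, compartment-normalized cell densities, and two spatial
colocalization statistics — the normalized mixing score and the
aggregated-entropy gradient — with attraction/repulsion pattern
classification.

The package is aimed at computational-pathology and translational-research
groups who work with *post-segmentation* single-cell tables (e.g., exported
from inForm or QuPath): per-cell coordinates in µm, a tumor/stroma
compartment label, and per-marker intensities by cellular region (nucleus,
cytoplasm, whole cell). Because clinical trial data of this kind usually
cannot be shared, the package ships a synthetic TMA generator that emulates
the relevant statistical structure (0.6 mm cores or 0.93 × 0.7 mm imaging
fields, blob-shaped tumor nests, attraction/CSR/repulsion immune-tumor
mixing, bimodal marker intensities, outcome labels linked to features), so
every stage of the pipeline is testable end to end.

## The statistics

**dTIL scores** from H&E classifier annotations (lymphocyte, tumor,
fibroblast, "other" counts and areas), intratumoral TILs included:

- eTILs (%) = 100 · TILs / (tumor cells + TILs)
- etTILs (%) = 100 · TILs / all detected cells
- esTILs (%) = 100 · TILs / (TILs + fibroblasts + other cells)
- eaTILs (cells/mm²) = TILs / analyzed tumor-region area
- easTILs (%) = 100 · TILs area / stroma area (capped at 100)

**Marker cutoffs.** Most markers: the minimum intensity of manually
annotated positive cells, replaced by an ECDF kneepoint when one is
prominent (which demotes isolated low-level outliers to negative).
Cytokeratin, whose pooled intensity is bimodal, uses Otsu's threshold
(minimum weighted intra-class variance). Positivity is inclusive
(intensity ≥ cutoff) and evaluated in each marker's designated region:
FoxP3 in the nucleus, CD4 on the whole cell, all others in the cytoplasm.
An ordered rule table maps call vectors to one class per cell
(CK⁺ → tumor; CD68⁺ → macrophage; FoxP3⁺ → regulatory T cell; CD8⁺ →
cytotoxic T cell; CD4⁺ → T helper; else "other"), with PD-1/PD-L1 flags
attached independently.

**Cell densities** are pooled per patient: counts summed over that
patient's cores divided by the summed compartment area (tumor, stroma,
total), in cells/mm², log2(x+1)-transformed for display. A patient with no
tissue in a compartment gets a missing value there.

**Normalized mixing score (NMS).** With I_rt the number of
reference–target cell pairs within radius r, I_rr the number of distinct
reference–reference pairs, and n_r, n_t the class totals:

    NMS(r) = [ I_rt · n_r(n_r − 1)/2 ] / [ I_rr · n_r · n_t ]

i.e., the mixing ratio I_rt/I_rr normalized by the ratio of maximal pair
counts. NMS ≈ 1 under complete spatial randomness and grows with
reference–target colocalization; it is undefined (missing) when I_rr = 0.

**Aggregated-entropy gradient.** For each radius, reference and target
cells within r of every reference cell (center included) are pooled; with
p the reference share, H(r) = −p log₂ p − (1−p) log₂(1−p) ∈ [0, 1]. The
slope of H over the two smallest ladder radii classifies the interaction:
negative → attraction (colocalization strongest near the reference cells),
positive → repulsion, |slope| ≤ ε → flat (ε = 1e-4 /µm by default). The
default radius ladder is 50, 100, …, 600 µm. Multi-core patients are
stitched with inter-core gaps larger than the maximal radius so no
cross-core pair is ever counted.

The cohort layer compares metrics between outcome groups (Wilcoxon
rank-sum / Kruskal–Wallis, two-sided, no multiplicity adjustment), tests
pattern × outcome contingency tables (Pearson χ² or Fisher's exact), and
computes Spearman correlation matrices.

## Worked example

```python
from tmespat import DTILsInput, compute_dtils, count_interactions, nms

m = compute_dtils(DTILsInput(n_tils=20, n_tumor=60, n_fibro=15, n_other=5,
                             tils_area_mm2=0.02, stroma_area_mm2=0.10,
                             tumor_region_area_mm2=0.25))
print(f"eTILs={m.etils_pct}%  etTILs={m.ettils_pct}%  esTILs={m.estils_pct}%  "
      f"eaTILs={m.eatils_per_mm2}/mm2  easTILs={m.eastils_pct}%")

c = count_interactions([(0, 0), (10, 0)], [(0, 5)], radius=10)
print(f"I_rt={c.i_rt} I_rr={c.i_rr} -> NMS={nms(c)}")
```

prints

```
eTILs=25.0%  etTILs=20.0%  esTILs=50.0%  eaTILs=80.0/mm2  easTILs=20.0%
I_rt=1 I_rr=1 -> NMS=0.5
```

20 of 80 tumor-bed cells are TILs (eTILs 25%), half of the stromal cells
are TILs (esTILs 50%), and the two-reference/one-target toy configuration
has one cross pair and one reference pair, giving a mixing score of 0.5.

Running the synthetic generator and the full phenotyping + spatial path on
an attraction-regime cohort (four patients, two cores each, 500 cells/mm²
per class, mixing length τ = 30 µm):

```python
from tmespat.config import SimConfig, IMMUNE_CLASSES
from tmespat.phenotyping import determine_cutoffs, phenotype_cells
from tmespat.spatial import patient_spatial_analysis
from tmespat.synthetic import simulate_cohort

dens = {c: 500.0 for c in IMMUNE_CLASSES}
dens["tumor"] = 500.0
cfg = SimConfig(n_patients=4, cores_per_patient=2, cell_density_per_class=dens,
                mixing_regime="attraction", mixing_strength=30.0, seed=11)
tables = simulate_cohort(cfg)
cutoffs = determine_cutoffs(tables["cells"], tables["annotations"])
cells = phenotype_cells(tables["cells"], cutoffs)
curves, patterns = patient_spatial_analysis(cells, reference_classes=("immune",))
print(patterns[["patient_id", "slope", "pattern"]].to_string(index=False))
```

prints

```
patient_id     slope    pattern
      P000 -0.000539 attraction
      P001 -0.000709 attraction
      P002 -0.000279 attraction
      P003 -0.000114 attraction
```

— all four patients show the negative entropy-gradient slope of an
attraction (high-colocalization) pattern, matching the generating regime;
their NMS values at the 50 µm radius (1.22–1.36) sit above the CSR value
of 1 for the same reason.

The same pipeline runs from the shell:

```bash
tmespat run --config config.yaml --seed 11 --out results/
# or stage by stage:
tmespat simulate --config config.yaml --out results/
tmespat phenotype --out results/
tmespat spatial --out results/
```

Each stage writes flat CSV files (`cells.csv`, `cutoffs.csv`,
`classified_cells.csv`, `densities.csv`, `spatial_curves.csv`,
`patterns.csv`, …) plus a `manifest.json` recording the seed and a
configuration hash; re-running with the same config and seed reproduces
the outputs byte for byte.

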