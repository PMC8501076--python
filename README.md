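# mimcseg

Cell-type-prioritised segmentation and spatial analysis for imaging mass
cytometry (IMC) of mouse tissue.

IMC images a tissue section with a panel of metal-isotope-tagged antibodies,
yielding one intensity channel per metal at 1 µm/pixel resolution. Turning
those images into single-cell data requires segmentation, and a single set of
nucleus-detection parameters fails on real tumour tissue: small lymphocyte
nuclei are missed by size thresholds tuned for tumour cells, spindle-shaped
fibroblasts have no detectable nucleus at all, and tight cell packing bleeds
signal between neighbours ("spatial spillover"). `mimcseg` implements and
compares four whole-cell segmentation strategies:

* **1-px / 3-px expansion** — detected nuclei grown by a fixed distance;
* **propagation** — each pixel joins the nucleus of minimal intensity-aware
  geodesic cost over a membrane probability map, with 4-connected step cost
  `sqrt(λ + Δg²)`;
* **sequential** — an ordered stack of segmentation layers (lymphocytes,
  macrophages, fibroblasts, normal, tumour, remaining), each with its own
  probability class and nucleus-detection settings; nuclei consumed by an
  earlier layer are subtracted from later ones, fibroblasts are segmented
  from their probability map alone (no seed), and a terminal one-pixel
  expansion captures whatever remains.

Around the segmenters the package provides the full desk-side workflow:
reading IMC plain-text pixel tables and TIFF stacks against a channel panel
CSV, preprocessing (hot-pixel removal, median filtering, Ir191+Ir193 DNA
summation, histogram equalisation, per-class marker merging), a
scribble-trained random-forest pixel classifier producing probability maps
(with an optional two-stage autocontext variant), tissue-domain segmentation
(normal / tumour / structural, interface = overlap of normal and tumour),
single-cell quantification with CellProfiler-compatible `cells.csv` /
`object_relationships.csv` output, segmentation-quality metrics (top-k
enrichment, signal/noise matrices, annotation matching), Phenograph-style
clustering (kNN graph, Jaccard weights, Louvain), and spatial statistics:

* **neighbourhood permutation test** — for each ordered cell-type pair
  (A, B), the mean number of B-neighbours per A-cell on the 15-px neighbour
  graph, against a null of shuffled type labels;
  `p = (1 + #extreme) / (1 + n_perm)`, effect size
  `log2FC = log2((baseline + ε) / (perm_mean + ε))` with `ε = 1/n_cells`;
* **nearest-type distances** (per-cell Euclidean distance to the nearest
  cell of a target type) and **binned neighbourhood profiles**
  (0–20 … 80–100 px, columns scaled to sum to one);
* **domain composition** summaries with per-ROI means and SEM.

A synthetic-tissue generator plants ground-truthed cells (five phenotypes
with distinct nucleus sizes, a nucleus-free spindle type, coherent tissue
domains, Poisson count noise, boundary spillover, hot pixels), so every
stage is testable offline against known truth.

## Worked example

```sh
python examples/01_simulate_and_segment.py
```

prints (abridged):

```
planted 148 cells: {'tumour': 50, 'normal': 45, 'lymphocyte': 25, 'macrophage': 20, 'fibroblast': 8}
segmented 195 cells across layers: {'tumour': 60, 'normal': 57, 'lymphocytes': 32, 'macrophages': 23, 'remaining': 16, 'fibroblasts': 7}
recovery (fraction of planted cells with a detected centroid within 5 px):
lymphocyte     1.000
macrophage     1.000
normal         1.000
tumour         0.980
fibroblast     0.750
non_spindle    0.993
overall        0.980
```

Recovery is the fraction of planted cells matched one-to-one by a detected
centroid within 5 px. The `non_spindle` row covers all nucleated cells; the
fibroblast row exists only because the probability-only layer segments
spindle cells without a nuclear seed — the expansion strategies recover none
of them. `examples/02_strategy_comparison.py` prints the enrichment table
comparing all four strategies, `03_spatial_analysis.py` the neighbourhood
statistics, `04_phenotyping.py` the clustering/gating path.

## Command line

```sh
mimcseg simulate --config tissue.yaml --out data/        # synthetic ROI + ground truth
mimcseg run-all  --config run.yaml                       # segment + quantify (+ phenotype/spatial)
mimcseg validate --config run.yaml                       # all 4 strategies, metrics CSV
```

Configs are YAML; outputs follow the organised per-ROI folder layout
(`full_stack/`, `probability_maps/`, `masks/`, `cells.csv`,
`object_relationships.csv`) plus a JSON/Markdown run report. Exit codes:
0 success, 2 config error, 3 stage failure. Runs are byte-identical given
the same config seeds.

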