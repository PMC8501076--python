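# Methods

This note documents the models and procedures implemented in `mimcseg`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

**Hot-pixel removal.** IMC detectors occasionally record isolated single-
pixel counts far above their surroundings. A pixel is declared hot when its
value exceeds the maximum of its 8-neighbourhood by more than `t`
(default `t = 50` raw counts) and is replaced by the neighbourhood median.
Because a replacement lowers the local maxima of adjacent pixels and can
expose further outliers, passes repeat to a fixpoint, making the operation
idempotent. The rule is our own reconstruction of the behaviour of
unpublished outlier-removal plugins used in this field; it is exact for the
isolated-spike artefacts the generator plants.

**Median filter.** Square window of side `2·ceil(r)+1`; default radius 0.5
(3×3), the minimal smoothing conventional for IMC counts.

**Histogram equalisation.** Exact empirical-CDF rank map rescaled to span
[0, 1]; monotone, so order statistics are preserved. Used to normalise the
summed DNA image for the pixel classifier. Note a degeneracy that matters
on count data: a pure rank map flattens the histogram to uniform, so
bimodal thresholding (Otsu) of an *equalised* image is ill-posed —
nucleus **detection** therefore thresholds the smoothed unequalised summed
counts (see below).

**Channel merging.** Class composites for pixel classification are sums of
member channels, each first rescaled to its own 99th percentile and clipped
to [0, 1], so a bright channel cannot dominate the composite. The member
scaling is our choice; merging tools in common use leave it unstated.

## Pixel classification

Interactive pixel classification is recast as a scribble-supervised random
forest (100 trees, `min_samples_leaf = 2`, fixed seed): sparse labelled
pixels train on a feature bank of Gaussian-smoothed intensity, gradient
magnitude and Laplacian of Gaussian per channel at scales {1, 2, 4} px.
The optional *autocontext* variant trains a second forest on the original
features plus the first stage's predicted probabilities, approximating
two-stage interactive workflows without interaction. Probability maps are
normalised per pixel; externally produced maps (multichannel float TIFF in
[0, 1]) are accepted interchangeably.

## Nucleus detection

The DNA image is the sum of the two iridium-intercalator channels, smoothed
(σ = 1 px). Binarisation uses Otsu by default (quantile and manual
thresholds available); touching nuclei are split by watershed, seeded from
peaks of the smoothed intensity ("intensity" declump) or of the lightly
smoothed distance transform ("shape" declump; the σ = 1 px smoothing of the
EDT suppresses noise-induced spurious peaks). Objects outside the
`[min_diameter, max_diameter]` equivalent-diameter window are removed and
labels renumbered. Quantile thresholds make the object count invariant to
positive rescaling of the image.

## Whole-cell strategies

**Expansion.** Each background pixel within Euclidean distance `n` of a
nucleus adopts the nearest nucleus's label. Distances are exact integer
squared Euclidean (feature transform + KD-tree tie resolution), and exact
ties go to the lowest label id — not whatever tie the EDT implementation
happens to make — so results are deterministic and order-independent.

**Propagation.** Pixels with membrane/cell probability ≥ `map_threshold`
(plus all nucleus pixels) form the region; each in-region pixel is assigned
to the seed of minimal geodesic cost over the 4-connected pixel graph with
step cost `sqrt(λ + (g(p) − g(q))²)` on the guidance image `g`. `λ`
(default 0.05) trades pure path length against intensity-awareness: large
`λ` approaches a geodesic Voronoi partition, small `λ` makes boundaries
hug guidance ridges. Implementation is a multi-source Dijkstra with
lexicographic `(cost, label)` keys, which provably yields the per-label
minimal cost with lowest-label tie-breaks even when zero-cost edges exist;
the test suite checks exact label-for-label agreement with an independent
sparse-graph Dijkstra oracle, and its geodesic-Voronoi limit against a
unit-cost BFS oracle. (On a pixel grid the 4-connected geodesic metric is
not the Euclidean metric, so the Voronoi-limit check uses the geodesic
oracle, not Euclidean expansion.)

**Sequential.** A permissive "pool" detection (diameter 1.5–40 px, shape
declump, σ = 0.5 px) runs once; layers then execute in priority order —
lymphocytes, macrophages, fibroblasts, normal, tumour, remaining. A
propagate-mode layer seeds from the remaining pool nuclei that (i) pass the
layer's diameter window and (ii) lie in the layer's own class region (mean
class probability over the nucleus support ≥ 0.5 — without this gate a
nucleus of some other type would seed a nucleus-sized junk cell wherever it
forms its own island in the region). The fibroblast layer is
probability-only: connected components of the thresholded class map,
area-filtered, no seed — this is what captures spindle cells with no
detectable nucleus. The terminal layer applies one-pixel expansion to all
leftover pool nuclei. After each layer, every pool nucleus whose area
overlaps a newly created cell by more than 50% is removed from the pool
(the paper-level "mask subtraction" made precise; the 50% rule is robust to
1-px boundary disagreements). Already-claimed pixels are never reassigned,
so layer masks are pairwise disjoint by construction, their union is the
total mask, and labels are globally unique with a per-cell layer record.

## Tissue domains

Each domain class map (normal, tumour, structural) is Gaussian-smoothed
(σ = 2 px), thresholded at 0.5, and cleaned of regions smaller than
`min_region_area` (default 625 px² ≈ 25×25). *Interface* — the tumour
margin — is assigned first wherever smoothed normal and tumour are both
≥ 0.5; remaining contested pixels take the class of largest smoothed
probability; pixels below every threshold are `none`. Cells inherit the
majority domain of their pixels, ties resolved by the priority
interface > tumour > normal > structural > none.

## Quantification

Per cell: unweighted pixel centroid (0-based, x = column, y = row), pixel
count, per-channel mean. Neighbour pairs are cells whose supports come
within 15 px *edge-to-edge* (exact minimum boundary-pixel distance, checked
against an O(n²) oracle in the tests); a centroid-distance variant is
available (`metric="centroid"`). Region exclusion removes cells whose
centroid lies in a closed axis-aligned rectangle (for acquisition
artefacts).

## Validation metrics

Top-k enrichment = mean marker intensity over the k brightest cells /
mean over the rest; ties at rank k resolve by ascending cell id (the ratio
is invariant to which tied cells enter). Signal/noise = mean of the key
marker in its own top-k over the mean of a "polluting" marker in those same
cells; scale-invariant. Annotation match = percent of annotated points with
a top-k centroid within 5 px, greedy nearest-pair-first one-to-one matching
so one bright cell cannot satisfy two annotations. Infinite ratios are
capped at 1e6 in CSV output.

## Phenotyping

Per-ROI normalisation to the mean of an ambient reference channel (Xe134),
then 99th-percentile scaling per marker over the concatenated multi-ROI
dataset, clipped to [0, 1]; the percentile is the lower order statistic, so
the scaling is exactly idempotent. Clustering builds the exact kNN graph
(k = 20, Euclidean) on the scaled marker space, weights edges by Jaccard
overlap of neighbour sets, and partitions by Louvain with a fixed seed and
canonical internal row ordering (partitions are invariant to row
shuffling). The Louvain resolution parameter is exposed: at the default 1.0
the resolution limit of modularity tiles large uniform populations into
patches — the behaviour of Phenograph-class pipelines, whose cluster counts
are then consolidated by annotation; at small resolution (≲ 0.1) merging
proceeds up to graph components, recovering coarse well-separated structure
exactly (disconnected communities are never merged, because that strictly
decreases modularity at any positive resolution). Gating rules split one
cluster on one marker threshold each, in order; the type map must cover
every cluster.

## Spatial statistics

The permutation test shuffles type labels over cells with the neighbour
graph fixed, preserving per-type counts exactly. P-values use the add-one
estimator (never zero; minimum attainable `1/(n_perm+1)`); the log2 fold
change uses pseudocount `ε = 1/n_cells` to avoid infinities. Domain
stratification restricts cells and edges to the stratum and permutes within
it, preserving stratum composition. Nearest-type distances are computed per
ROI, excluding self for target-type cells, NaN when an ROI lacks targets.
Binned profiles use half-open bins `[lo, hi)` with edges 0–100 px in steps
of 20 and columns scaled to sum to one.

## Synthetic tissue

The generator emulates: a wavy tumour blob (radius 170 px at the default
512-px size) with an interface band (width 6 px) and vessel ribbons;
per-type cell counts placed by hard-core sampling (centres at least the sum
of the two cells' placement radii apart; bounded rejection, error when the
density is infeasible); cells as disks clipped to the Voronoi region of
their centre; concentric nuclei with per-type diameter mean ± sd;
fibroblasts as bent 3-px-wide Bezier ribbons with no nucleus; per-type
marker signatures painted uniformly on the cell support; boundary spillover
(a fraction `f = 0.15` of every cell-boundary pixel adjacent to a foreign
cell is replaced by the mean of the foreign neighbours' expected signal —
the spatial "signal bleed" failure mode); Poisson counts on the expected
intensities; a flat ambient reference channel (5 expected counts, the
Xe134 analogue — the ambient-gas signal model is our choice); nonspecific
antibody background (0.3 expected counts on every antibody channel, drawn
as part of the Poisson noise model — real acquisitions never produce
exactly-zero channels, and without a noise floor top-k enrichment
denominators degenerate to zero); and hot pixels (rate 3e-4, +500 counts).
With spillover and noise disabled, every cell's mean marker intensity
equals its signature exactly. Default study conditions: 512×512 px,
~590 cells (220 tumour, 150 normal, 90 lymphocyte, 90 macrophage,
40 fibroblast).

**What the synthetic benchmark does not show.** Cells are convex disks (or
single ribbons) with uniform signatures; real nuclei are lobed, membranes
irregular, staining heterogeneous within cells, and channel crosstalk has
spectral structure the boundary-mixing model lacks. Passing the recovery
and ordering checks therefore establishes correctness of the algorithms and
the *direction* of the strategy differences under a controlled failure
model, not absolute segmentation accuracy on tissue.

## Problem sizes and determinism

The test suite and acceptance script run everything at the sizes above
(one 512-px ROI for the end-to-end checks; 160–320 px fixtures for unit
tests; the permutation calibration at n = 300 cells, 500 permutations, 200
replicates), which keeps a full run in the minutes range on one core. All
randomness flows from explicit seeds: the generator, the forests, Louvain,
and the permutation test are bit-reproducible, and a CLI rerun with the
same config produces byte-identical CSVs.

## Known limitations

Layer nucleus "re-detection" is realised as size- and class-filtering of
the one-off permissive pool rather than an independent per-layer detection
pass; the pool's threshold therefore bounds what any layer can see. The
sequential strategy over-segments noisy DNA blobs into extra small cells
rather than missing real ones (conservative for recovery, inflationary for
counts; the QC report tracks disconnected labels). The propagation
implementation is exact but single-threaded Python; very large regions
(full-image guidance at low thresholds) are its slow path. `.mcd` binary
acquisition files are out of scope — convert to pixel-text or TIFF first.
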