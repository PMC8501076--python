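"""Compare the four segmentation strategies with the validation metrics.

Runs 1-px expansion, 3-px expansion, propagation and sequential segmentation
on the same synthetic ROI and prints top-k signal enrichment per marker: the
mean marker intensity in the brightest k cells over the mean in the rest.
Higher is better — it means the marker's signal is concentrated in the cells
that should carry it, rather than bled across neighbours.
"""

from mimcseg import pipeline, preprocess, synthetic, validate

from mimcseg.synthetic import CellTypeSpec, TissueConfig

config = TissueConfig(
    size=320,
    tumour_radius=105.0,
    cell_types=(
        CellTypeSpec("lymphocyte", 30, 7.0, 5.0, 0.5, {"CD3": 20.0},
                     ("normal", "interface")),
        CellTypeSpec("macrophage", 25, 12.0, 7.0, 0.8, {"F480": 20.0},
                     ("tumour", "interface")),
        CellTypeSpec("fibroblast", 10, 0.0, 0.0, 0.0, {"aSMA": 20.0},
                     ("tumour", "structural"), spindle=True),
        CellTypeSpec("normal", 55, 12.0, 8.0, 0.8, {"PECAM": 18.0}, ("normal",)),
        CellTypeSpec("tumour", 65, 14.0, 10.0, 1.0, {"CD44": 18.0}, ("tumour",)),
    ),
    seed=4,
)
gt = synthetic.generate_tissue(config)
stack = preprocess.preprocess_stack(gt.stack)
cell_maps, domain_maps = pipeline.probability_maps_from_truth(stack, gt, seed=2)

tables = {}
for strategy in ("expand1", "expand3", "propagation", "sequential"):
    result = pipeline.segment_roi(stack, strategy, cell_maps, domain_maps)
    tables[strategy], _ = pipeline.quantify_roi(stack, result)

metrics = validate.metrics_table(
    tables, markers=["CD3", "F480", "aSMA", "CD44"], k=30
)
enrichment = metrics[metrics["metric"] == "enrichment"].pivot_table(
    index="strategy", columns="marker", values="value"
)
print("top-30 signal enrichment (rows: strategy, columns: marker):")
print(enrichment.round(1).to_string())
# Expect the sequential strategy to dominate for the small-cell marker (CD3)
# and the spindle-cell marker (aSMA): those cell types need their own
# detection settings, which the single-pass strategies lack.
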