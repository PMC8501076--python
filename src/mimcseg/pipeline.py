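"""End-to-end orchestration of the segmentation workflow.

Mirrors the input/output contract of the original Nextflow-based pipeline as
a native library/CLI: a single YAML config names the inputs (a plain-text
pixel table, a TIFF stack, or a synthetic-tissue simulation), the panel, the
segmentation strategy (``expand1`` / ``expand3`` / ``propagation`` /
``sequential``), classifier source (scribble-trained or externally supplied
probability maps) and downstream toggles.  Outputs land in an organised
per-ROI results folder, together with a run report (per-stage timing, cell
counts, QC flags).  All randomness flows from config seeds, so a rerun is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import io_formats, preprocess, quantify, segmentation, synthetic, validate
from .io_formats import ImageStack
from .pixel_classifier import (
    ProbabilityMaps,
    extract_features,
    predict_probabilities,
    train_pixel_model,
)
from .segmentation import LayerSpec, NucleusParams

logger = logging.getLogger(__name__)

__all__ = [
    "CELL_CLASSES",
    "DOMAIN_CLASSES",
    "default_layer_specs",
    "default_nucleus_params",
    "nuclear_image",
    "classify_stack",
    "segment_roi",
    "quantify_roi",
    "SegmentationResult",
    "run_pipeline",
    "run_validation",
    "ConfigError",
    "StageError",
]

#: classifier class rosters (order fixed: scribble id k = class_names[k-1])
CELL_CLASSES = ["background", "lymphocytes", "macrophages", "fibroblasts", "normal", "tumour"]
DOMAIN_CLASSES = ["background", "normal", "tumour", "structural"]

#: marker groups merged into per-class composites for classification
DEFAULT_CHANNEL_GROUPS = {
    "lymphocytes": ["CD3"],
    "macrophages": ["F480"],
    "fibroblasts": ["aSMA"],
    "normal": ["PECAM"],
    "tumour": ["CD44"],
    "structural": ["EPCAM", "aSMA"],
}

#: map synthetic ground-truth cell types -> classifier classes
TYPE_TO_CLASS = {
    "lymphocyte": "lymphocytes",
    "macrophage": "macrophages",
    "fibroblast": "fibroblasts",
    "normal": "normal",
    "tumour": "tumour",
}


class ConfigError(ValueError):
    """Raised before any computation when the config is unusable (exit 2)."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and ROI (exit 3)."""


def default_nucleus_params() -> NucleusParams:
    """The single nucleus-detection setting shared by the non-sequential
    strategies (sized for an 'average' cell, deliberately missing the
    smallest lymphocyte nuclei — the failure mode the sequential strategy
    exists to fix)."""
    return NucleusParams(min_diameter=6.0, max_diameter=30.0, declump="intensity")


def default_layer_specs() -> list[LayerSpec]:
    """Layer stack for the sequential strategy, ordered by priority:
    lymphocytes, macrophages, fibroblasts (probability-map only, no seed),
    normal, tumour, then a terminal one-pixel-expansion layer for whatever
    nuclei remain."""
    return [
        LayerSpec("lymphocytes", "lymphocytes",
                  NucleusParams(min_diameter=2.5, max_diameter=8.0, declump="intensity"),
                  mode="propagate"),
        LayerSpec("macrophages", "macrophages",
                  NucleusParams(min_diameter=4.0, max_diameter=16.0, declump="intensity"),
                  mode="propagate"),
        LayerSpec("fibroblasts", "fibroblasts", None,
                  mode="probability_only", min_area=20.0),
        LayerSpec("normal", "normal",
                  NucleusParams(min_diameter=4.0, max_diameter=20.0, declump="intensity"),
                  mode="propagate"),
        LayerSpec("tumour", "tumour",
                  NucleusParams(min_diameter=5.0, max_diameter=24.0, declump="intensity"),
                  mode="propagate"),
        LayerSpec("remaining", "", None, mode="expand1"),
    ]


def nuclear_image(
    stack: ImageStack,
    dna_tags=("Ir191", "Ir193"),
    presmooth: float = 1.0,
    equalize: bool = True,
) -> np.ndarray:
    """Summed iridium channels, lightly smoothed; optionally histogram
    equalised.

    The equalised variant normalises staining variation and feeds the pixel
    classifier.  Nucleus *detection* uses the unequalised counts
    (``equalize=False``): rank-map equalisation flattens the intensity
    histogram to uniform, which makes bimodal thresholding of the result
    degenerate, whereas Otsu on the smoothed raw counts separates the
    count-noise floor from nuclei cleanly.
    """
    from scipy import ndimage as ndi

    summed = preprocess.sum_channels(stack, list(dna_tags))
    if presmooth > 0:
        summed = ndi.gaussian_filter(summed, presmooth)
    return preprocess.equalize_hist(summed) if equalize else summed


def classify_stack(
    stack: ImageStack,
    cell_scribbles: np.ndarray,
    domain_scribbles: np.ndarray,
    seed: int = 0,
    scales=(1.0, 2.0, 4.0),
    autocontext: bool = False,
    channel_groups=None,
) -> tuple[ProbabilityMaps, ProbabilityMaps]:
    """Train the two scribble classifiers (cell classes, domain classes) on
    merged marker composites plus the nuclear image, and predict both
    probability-map sets."""
    groups = dict(channel_groups or DEFAULT_CHANNEL_GROUPS)
    merged = preprocess.merge_channel_groups(stack, groups)
    dna = nuclear_image(stack)
    planes = np.concatenate([merged.pixels, dna[None]], axis=0)
    feats = extract_features(planes, scales)
    cell_model = train_pixel_model(
        feats, cell_scribbles, CELL_CLASSES, seed=seed, autocontext=autocontext
    )
    cell_maps = predict_probabilities(cell_model, feats)
    dom_model = train_pixel_model(
        feats, domain_scribbles, DOMAIN_CLASSES, seed=seed + 1, autocontext=autocontext
    )
    dom_maps = predict_probabilities(dom_model, feats)
    return cell_maps, dom_maps


@dataclass
class SegmentationResult:
    total_mask: np.ndarray
    nuclei: np.ndarray
    layer_table: pd.DataFrame  # cell_id, layer
    layer_masks: dict[str, np.ndarray] = field(default_factory=dict)
    domain_mask: np.ndarray | None = None


def segment_roi(
    stack: ImageStack,
    strategy: str,
    cell_probmaps: ProbabilityMaps | None = None,
    domain_probmaps: ProbabilityMaps | None = None,
    layers: list[LayerSpec] | None = None,
    nucleus_params: NucleusParams | None = None,
    propagation_lambda: float = 0.05,
    map_threshold: float = 0.5,
    min_region_area: int = 625,
) -> SegmentationResult:
    """Run one whole-cell segmentation strategy (plus domain segmentation).

    ``expand1`` / ``expand3`` need no probability maps; ``propagation`` uses
    the total cell probability (1 - background class) as guidance;
    ``sequential`` consumes one probability class per layer.
    """
    dna = nuclear_image(stack, equalize=False)
    params = nucleus_params or default_nucleus_params()

    if strategy in ("expand1", "expand3"):
        nuclei = segmentation.detect_nuclei(dna, params)
        n_px = 1 if strategy == "expand1" else 3
        total = segmentation.expand_labels(nuclei, n_px)
        layer_table = pd.DataFrame(
            {"cell_id": np.unique(total[total > 0]), "layer": strategy}
        )
        result = SegmentationResult(total, nuclei, layer_table, {strategy: total})
    elif strategy == "propagation":
        if cell_probmaps is None:
            raise ValueError("propagation strategy requires cell probability maps")
        nuclei = segmentation.detect_nuclei(dna, params)
        guidance = 1.0 - cell_probmaps.get("background")
        total = segmentation.propagate_labels(
            nuclei, guidance, propagation_lambda, map_threshold
        )
        layer_table = pd.DataFrame(
            {"cell_id": np.unique(total[total > 0]), "layer": "propagation"}
        )
        result = SegmentationResult(total, nuclei, layer_table, {"propagation": total})
    elif strategy == "sequential":
        if cell_probmaps is None:
            raise ValueError("sequential strategy requires cell probability maps")
        layers = layers or default_layer_specs()
        probmap_dict = {
            name: cell_probmaps.get(name)
            for name in cell_probmaps.class_names
            if name != "background"
        }
        total, layer_table, layer_masks = segmentation.sequential_segment(
            probmap_dict, dna, layers
        )
        nuclei = segmentation.detect_nuclei(
            dna,
            NucleusParams(min_diameter=1.5, max_diameter=40.0, declump="shape",
                          smoothing_sigma=0.5),
        )
        result = SegmentationResult(total, nuclei, layer_table, layer_masks)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    if domain_probmaps is not None:
        result.domain_mask = segmentation.segment_domains(
            domain_probmaps, min_region_area=min_region_area
        )
    return result


def quantify_roi(
    stack: ImageStack,
    result: SegmentationResult,
    treatment: str = "",
    max_neighbour_dist: float = 15.0,
    neighbour_metric: str = "edge",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell table + neighbour graph from a segmentation result."""
    table = quantify.measure_cells(result.total_mask, stack)
    if result.domain_mask is not None:
        table = quantify.assign_domains(table, result.total_mask, result.domain_mask)
    if len(result.layer_table):
        table = table.merge(result.layer_table, on="cell_id", how="left")
    if treatment:
        table["treatment"] = treatment
    relationships = quantify.object_relationships(
        result.total_mask, max_neighbour_dist, metric=neighbour_metric,
        cell_table=table,
    )
    return table, relationships


# ---------------------------------------------------------------------------
# config-driven entry points
# ---------------------------------------------------------------------------

def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _load_inputs(cfg: dict):
    """Resolve the input block to (stack, ground_truth-or-None)."""
    inp = cfg.get("input")
    if not inp:
        raise ConfigError("config has no 'input' block")
    if "simulate" in inp:
        sim = dict(inp["simulate"] or {})
        sim.setdefault("seed", cfg.get("seed", 0))
        gt = synthetic.generate_tissue(synthetic.TissueConfig(**sim))
        return gt.stack, gt
    panel_path = inp.get("panel")
    if not panel_path:
        raise ConfigError("non-simulated input requires a 'panel' file")
    if not Path(panel_path).exists():
        raise ConfigError(f"panel file {panel_path} does not exist")
    panel = io_formats.read_panel(panel_path)
    if "pixel_text" in inp:
        if not Path(inp["pixel_text"]).exists():
            raise ConfigError(f"input file {inp['pixel_text']} does not exist")
        return io_formats.read_pixel_text(inp["pixel_text"], panel), None
    if "tiff" in inp:
        if not Path(inp["tiff"]).exists():
            raise ConfigError(f"input file {inp['tiff']} does not exist")
        return io_formats.read_tiff_stack(inp["tiff"], panel), None
    raise ConfigError("input block needs one of: simulate, pixel_text, tiff")


def _probmaps_for(cfg: dict, stack: ImageStack, gt, seed: int):
    """Classifier stage: train on scribbles or load external maps."""
    cls = cfg.get("classifier", {}) or {}
    source = cls.get("source", "train")
    if source == "external":
        ext = cls.get("external", {})
        cell = ProbabilityMaps.read(ext["cells"], CELL_CLASSES)
        dom = ProbabilityMaps.read(ext["domains"], DOMAIN_CLASSES)
        return cell, dom
    if source != "train":
        raise ConfigError(f"unknown classifier source {source!r}")
    n_scrib = int(cls.get("n_scribbles", 400))
    if gt is not None:
        # scribble in the ground-truth type vocabulary, then remap ids onto
        # the classifier's class roster
        roster = ["background"] + list(TYPE_TO_CLASS)
        cell_scr = synthetic.scribbles_from_truth(
            gt, roster, n_per_class=n_scrib, seed=seed, kind="cells",
        )
        remap = np.zeros(len(roster) + 1, dtype=np.int32)
        remap[1] = CELL_CLASSES.index("background") + 1
        for k, name in enumerate(list(TYPE_TO_CLASS), start=2):
            remap[k] = CELL_CLASSES.index(TYPE_TO_CLASS[name]) + 1
        cell_scr = remap[cell_scr]
        dom_scr = synthetic.scribbles_from_truth(
            gt, ["none", "normal", "tumour", "structural"],
            n_per_class=n_scrib, seed=seed + 1, kind="domains",
        )
    else:
        scr = cls.get("scribbles", {})
        if "cells" not in scr or "domains" not in scr:
            raise ConfigError(
                "training on real input requires classifier.scribbles.cells "
                "and .domains TIFF paths"
            )
        cell_scr = tifffile.imread(scr["cells"]).astype(np.int32)
        dom_scr = tifffile.imread(scr["domains"]).astype(np.int32)
    return classify_stack(
        stack, cell_scr, dom_scr, seed=seed,
        scales=tuple(cls.get("scales", (1.0, 2.0, 4.0))),
        autocontext=bool(cls.get("autocontext", False)),
    )


def probability_maps_from_truth(
    stack: ImageStack,
    ground_truth,
    seed: int = 0,
    n_scribbles: int = 400,
    autocontext: bool = False,
) -> tuple[ProbabilityMaps, ProbabilityMaps]:
    """Train both pixel classifiers from scribbles sampled off a synthetic
    ground truth and predict (cell-class, domain-class) probability maps."""
    cfg = {"classifier": {"n_scribbles": n_scribbles, "autocontext": autocontext}}
    return _probmaps_for(cfg, stack, ground_truth, seed)


def run_pipeline(config) -> dict:
    """Run the full workflow from a config mapping or YAML path.

    Returns the run report (also written as JSON + Markdown next to the
    outputs).  Any stage failure raises :class:`StageError` naming the stage
    and ROI.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg.get("output_dir", "results"))
    seed = int(cfg.get("seed", 0))
    strategy = cfg.get("strategy", "sequential")
    if strategy not in ("expand1", "expand3", "propagation", "sequential"):
        raise ConfigError(f"unknown strategy {strategy!r}")

    report: dict = {"strategy": strategy, "seed": seed, "stages": {}, "qc": {}}
    roi_id = "?"
    # load before touching the output directory, so a config error (missing
    # panel or input file) aborts without writing anything
    try:
        t0 = time.perf_counter()
        stack, gt = _load_inputs(cfg)
        roi_id = stack.roi_id
        report["roi_id"] = roi_id
        report["stages"]["load"] = time.perf_counter() - t0
    except ConfigError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"stage 'load' failed for ROI {roi_id}: {exc}") from exc

    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mimcseg")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        stage = "preprocess"
        t0 = time.perf_counter()
        pp = preprocess.PreprocessConfig(**(cfg.get("preprocess") or {}))
        stack = preprocess.preprocess_stack(stack, pp)
        report["stages"][stage] = time.perf_counter() - t0

        cell_maps = dom_maps = None
        if strategy in ("propagation", "sequential"):
            stage = "classify"
            t0 = time.perf_counter()
            cell_maps, dom_maps = _probmaps_for(cfg, stack, gt, seed)
            report["stages"][stage] = time.perf_counter() - t0

        stage = "segment"
        t0 = time.perf_counter()
        seg = cfg.get("segmentation", {}) or {}
        result = segment_roi(
            stack, strategy, cell_maps, dom_maps,
            propagation_lambda=float(seg.get("propagation_lambda", 0.05)),
            map_threshold=float(seg.get("map_threshold", 0.5)),
            min_region_area=int(seg.get("min_region_area", 625)),
        )
        report["stages"][stage] = time.perf_counter() - t0
        report["n_cells"] = int(len(result.layer_table))
        report["qc"]["disconnected_labels"] = segmentation.count_disconnected_labels(
            result.total_mask
        )
        report["qc"]["empty_layers"] = [
            name for name, m in result.layer_masks.items() if m.max() == 0
        ]

        stage = "quantify"
        t0 = time.perf_counter()
        q = cfg.get("quantify", {}) or {}
        table, relationships = quantify_roi(
            stack, result,
            treatment=str(cfg.get("treatment", "")),
            max_neighbour_dist=float(q.get("max_neighbour_dist", 15.0)),
            neighbour_metric=str(q.get("neighbour_metric", "edge")),
        )
        report["stages"][stage] = time.perf_counter() - t0
        report["n_relationships"] = int(len(relationships))

        stage = "write"
        t0 = time.perf_counter()
        masks = {"total_cell": result.total_mask, "nuclei": result.nuclei}
        for name, m in result.layer_masks.items():
            masks[f"layer_{name}"] = m
        if result.domain_mask is not None:
            masks["domain"] = result.domain_mask
        probmaps = {}
        if cell_maps is not None:
            probmaps["cell_classes"] = cell_maps
        if dom_maps is not None:
            probmaps["domain_classes"] = dom_maps
        io_formats.write_outputs(
            out_dir, stack, probmaps or None, masks, table, relationships
        )
        report["stages"][stage] = time.perf_counter() - t0
    except (ConfigError, StageError):
        root.removeHandler(handler)
        raise
    except Exception as exc:
        root.removeHandler(handler)
        raise StageError(f"stage {stage!r} failed for ROI {roi_id}: {exc}") from exc

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    lines = [f"# Run report — ROI {roi_id}", "",
             f"strategy: {strategy}, seed: {seed}, cells: {report.get('n_cells', 0)}", "",
             "| stage | seconds |", "|---|---|"]
    lines += [f"| {k} | {v:.2f} |" for k, v in report["stages"].items()]
    lines += ["", f"QC: {json.dumps(report['qc'])}", ""]
    (out_dir / "report.md").write_text("\n".join(lines))
    root.removeHandler(handler)
    handler.close()
    return report


def run_validation(config) -> pd.DataFrame:
    """Run all four strategies on one input and emit the three validation
    metrics per strategy and marker (the strategy-comparison harness).

    Config keys: the shared ``input`` / ``classifier`` blocks, plus
    ``validation``: ``markers`` (list), ``top_k`` (int), ``pollutants``
    (marker -> list), ``annotations`` (csv path or ``n_per_type`` for
    simulated input).  Returns the tidy metrics table and writes it to
    ``<output_dir>/validation_metrics.csv``.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg.get("output_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    vcfg = cfg.get("validation", {}) or {}

    stack, gt = _load_inputs(cfg)
    stack = preprocess.preprocess_stack(
        stack, preprocess.PreprocessConfig(**(cfg.get("preprocess") or {}))
    )
    cell_maps, dom_maps = _probmaps_for(cfg, stack, gt, seed)

    markers = list(vcfg.get("markers", synthetic.MARKER_CHANNELS))
    top_k = int(vcfg.get("top_k", 50))
    pollutants = vcfg.get("pollutants")

    annotations = None
    if "annotations" in vcfg and vcfg["annotations"]:
        annotations = io_formats.read_annotations(vcfg["annotations"])
    elif gt is not None and vcfg.get("n_annotations_per_type"):
        annotations = synthetic.generate_annotations(
            gt, int(vcfg["n_annotations_per_type"]), jitter_sd=1.0, seed=seed
        )
    if annotations is None:
        logger.warning("no annotations available; annotation metric rows omitted")

    tables = {}
    for strategy in ("expand1", "expand3", "propagation", "sequential"):
        result = segment_roi(stack, strategy, cell_maps, dom_maps)
        table, _ = quantify_roi(stack, result, treatment=str(cfg.get("treatment", "")))
        tables[strategy] = table
    metrics = validate.metrics_table(
        tables, markers, k=top_k, pollutant_map=pollutants, annotations=annotations
    )
    metrics.to_csv(out_dir / "validation_metrics.csv", index=False, lineterminator="\n")
    return metrics
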