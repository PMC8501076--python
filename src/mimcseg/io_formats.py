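"""Readers and writers for every external artefact the pipeline touches.

Imaging mass cytometry (IMC) acquisitions arrive either as plain-text pixel
tables (one row per pixel, columns ``X``, ``Y``, ``Z`` plus one column per
metal channel) or as multichannel/multi-page TIFF stacks.  A channel panel
CSV with binary include flags selects which metals enter the analysis.
Outputs follow a CellProfiler-compatible folder layout (``full_stack/``,
``probability_maps/``, ``masks/``, ``cells.csv``,
``object_relationships.csv``) so downstream consumers of the original
Nextflow pipeline's results can switch seamlessly.

Coordinate convention, shared by every module in the package: 0-based pixel
units, origin at the top-left, ``x`` = column, ``y`` = row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "PanelEntry",
    "ImageStack",
    "AnnotationSet",
    "read_panel",
    "read_pixel_text",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_annotations",
    "write_annotations",
    "write_outputs",
    "read_cells_csv",
    "write_cells_csv",
    "write_relationships_csv",
    "read_relationships_csv",
]

# Canonical in-memory cell-table columns <-> CellProfiler-style CSV names.
_CP_FIXED = {
    "cell_id": "ObjectNumber",
    "centroid_x": "Location_Center_X",
    "centroid_y": "Location_Center_Y",
    "area": "AreaShape_Area",
    "layer": "Metadata_layer",
    "domain": "Metadata_domain",
}
_CP_OPTIONAL = {
    "roi_id": "Metadata_roi",
    "treatment": "Metadata_treatment",
    "cluster": "Metadata_cluster",
    "cell_type": "Metadata_cell_type",
}
_INTENSITY_PREFIX = "Intensity_MeanIntensity_"


@dataclass(frozen=True)
class PanelEntry:
    """One channel of the antibody panel.

    Parameters
    ----------
    metal_tag
        Metal isotope tag, e.g. ``"Ir191"``.
    marker
        Human-readable marker name (antibody target); defaults to the tag.
    use_for_full_stack, use_for_ilastik_stack
        Binary include flags mirroring the panel CSV columns.
    """

    metal_tag: str
    marker: str = ""
    use_for_full_stack: int = 1
    use_for_ilastik_stack: int = 0

    def __post_init__(self):
        if not self.metal_tag:
            raise ValueError("metal_tag must be non-empty")
        if not self.marker:
            object.__setattr__(self, "marker", self.metal_tag)


@dataclass
class ImageStack:
    """Channel-indexed 2-D intensity images with panel metadata.

    ``pixels`` has shape ``(n_channels, height, width)``; every channel shares
    the same shape and intensities are finite and non-negative.
    """

    channels: list[PanelEntry]
    pixels: np.ndarray
    roi_id: str = "roi"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (channels, height, width)")
        if len(self.channels) != self.pixels.shape[0]:
            raise ValueError(
                f"{len(self.channels)} panel entries vs {self.pixels.shape[0]} planes"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        tags = [c.metal_tag for c in self.channels]
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate metal tags in stack")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    @property
    def metal_tags(self) -> list[str]:
        return [c.metal_tag for c in self.channels]

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels]

    def index_of(self, tag: str) -> int:
        """Resolve a metal tag or marker name to a channel index.

        Matching is case-insensitive substring on the metal tag, falling back
        to exact marker name; ambiguity is an error, never a silent pick.
        """
        low = tag.lower()
        hits = [i for i, c in enumerate(self.channels) if low in c.metal_tag.lower()]
        if not hits:
            hits = [i for i, c in enumerate(self.channels) if c.marker.lower() == low]
        if len(hits) == 0:
            raise KeyError(f"channel {tag!r} not found in stack")
        if len(hits) > 1:
            matched = [self.channels[i].metal_tag for i in hits]
            raise KeyError(f"channel {tag!r} is ambiguous: matches {matched}")
        return hits[0]

    def get(self, tag: str) -> np.ndarray:
        return self.pixels[self.index_of(tag)]


@dataclass
class AnnotationSet:
    """Manually annotated cell positions: records of (x, y, label)."""

    x: np.ndarray
    y: np.ndarray
    label: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        if not (len(self.x) == len(self.y) == len(self.label)):
            raise ValueError("x, y, label must have equal length")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, label: str) -> "AnnotationSet":
        keep = self.label == label
        return AnnotationSet(self.x[keep], self.y[keep], self.label[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "label": self.label})


def read_panel(
    path,
    metal_col: str = "metal",
    full_col: str = "full_stack",
    ilastik_col: str = "ilastik_stack",
    marker_col: str = "marker",
) -> list[PanelEntry]:
    """Read the channel panel CSV (binary include flags per metal channel)."""
    df = pd.read_csv(path)
    if metal_col not in df.columns:
        raise ValueError(f"panel is missing the {metal_col!r} column")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            PanelEntry(
                metal_tag=str(row[metal_col]),
                marker=str(row[marker_col]) if marker_col in df.columns else "",
                use_for_full_stack=int(row[full_col]) if full_col in df.columns else 1,
                use_for_ilastik_stack=(
                    int(row[ilastik_col]) if ilastik_col in df.columns else 0
                ),
            )
        )
    tags = [e.metal_tag for e in entries]
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate metal tags in panel")
    if not any(e.use_for_full_stack for e in entries):
        raise ValueError("panel flags no channel for the full stack")
    return entries


def _included(panel: Sequence[PanelEntry]) -> list[PanelEntry]:
    return [e for e in panel if e.use_for_full_stack]


def _match_column(tag: str, columns: Sequence[str]) -> str:
    low = tag.lower()
    hits = [c for c in columns if low in c.lower()]
    if len(hits) == 0:
        raise ValueError(f"panel metal tag {tag!r} matches no column")
    if len(hits) > 1:
        raise ValueError(f"panel metal tag {tag!r} matches several columns: {hits}")
    return hits[0]


def read_pixel_text(path, panel: Sequence[PanelEntry], roi_id: str | None = None) -> ImageStack:
    """Read an IMC plain-text pixel table into an :class:`ImageStack`.

    The file must have a header row containing ``X`` and ``Y`` columns plus one
    column per metal channel; panel metal tags are resolved to columns by
    case-insensitive substring match.  Pixels absent from the table are filled
    with zero (and logged), duplicated coordinates are an error.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip(): c for c in df.columns}
    xcol = next((cols[c] for c in cols if c.upper() == "X"), None)
    ycol = next((cols[c] for c in cols if c.upper() == "Y"), None)
    if xcol is None or ycol is None:
        raise ValueError("pixel table must contain X and Y columns")

    xs = df[xcol].to_numpy(dtype=np.int64)
    ys = df[ycol].to_numpy(dtype=np.int64)
    if xs.min(initial=0) < 0 or ys.min(initial=0) < 0:
        raise ValueError("negative pixel coordinates")
    h, w = int(ys.max()) + 1, int(xs.max()) + 1

    flat = ys * w + xs
    uniq, counts = np.unique(flat, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[np.argmax(counts > 1)]
        raise ValueError(f"duplicate pixel at (X={dup % w}, Y={dup // w})")
    if len(uniq) < h * w:
        logger.info(
            "pixel table %s covers %d of %d pixels; missing pixels zero-filled",
            path, len(uniq), h * w,
        )

    included = _included(panel)
    channel_cols = [c for c in df.columns if c not in (xcol, ycol)]
    planes = np.zeros((len(included), h, w), dtype=np.float64)
    for i, entry in enumerate(included):
        col = _match_column(entry.metal_tag, channel_cols)
        planes[i].flat[flat] = df[col].to_numpy(dtype=np.float64)
    return ImageStack(included, planes, roi_id=roi_id or Path(path).stem)


def read_tiff_stack(path, panel: Sequence[PanelEntry], roi_id: str | None = None) -> ImageStack:
    """Read a multi-page/multichannel TIFF; page *i* maps to the *i*-th
    included panel entry."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    included = _included(panel)
    if arr.shape[0] != len(included):
        raise ValueError(
            f"TIFF has {arr.shape[0]} pages but panel includes {len(included)} channels"
        )
    return ImageStack(included, arr.astype(np.float64), roi_id=roi_id or Path(path).stem)


def write_tiff_stack(path, stack: ImageStack) -> None:
    """Write all channels of a stack to one multi-page float32 TIFF."""
    tifffile.imwrite(path, stack.pixels.astype(np.float32), photometric="minisblack")


def read_annotations(path) -> AnnotationSet:
    df = pd.read_csv(path)
    return AnnotationSet(df["x"].to_numpy(), df["y"].to_numpy(), df["label"].to_numpy())


def write_annotations(path, annotations: AnnotationSet) -> None:
    annotations.to_frame().to_csv(path, index=False)


def write_cells_csv(path, cell_table: pd.DataFrame) -> None:
    """Write the single-cell table with CellProfiler-style column names.

    Marker mean-intensity columns become ``Intensity_MeanIntensity_<marker>``;
    absent optional columns are simply not written.
    """
    out = pd.DataFrame()
    for internal, cp in _CP_FIXED.items():
        if internal in cell_table.columns:
            out[cp] = cell_table[internal]
    for internal, cp in _CP_OPTIONAL.items():
        if internal in cell_table.columns:
            out[cp] = cell_table[internal]
    known = set(_CP_FIXED) | set(_CP_OPTIONAL)
    for col in cell_table.columns:
        if col not in known:
            out[_INTENSITY_PREFIX + str(col)] = cell_table[col]
    out.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_cells_csv(path) -> pd.DataFrame:
    """Read ``cells.csv`` back into the canonical in-memory cell table."""
    df = pd.read_csv(path)
    out = pd.DataFrame()
    inverse = {cp: internal for internal, cp in {**_CP_FIXED, **_CP_OPTIONAL}.items()}
    for col in df.columns:
        if col in inverse:
            out[inverse[col]] = df[col]
        elif col.startswith(_INTENSITY_PREFIX):
            out[col[len(_INTENSITY_PREFIX):]] = df[col]
        else:
            out[col] = df[col]
    return out


def write_relationships_csv(path, relationships: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "First Object Number": relationships["cell_id_a"].astype(int),
            "Second Object Number": relationships["cell_id_b"].astype(int),
            "Relationship": "Neighbors",
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_relationships_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame(
        {
            "cell_id_a": df["First Object Number"].astype(int),
            "cell_id_b": df["Second Object Number"].astype(int),
        }
    )


def _write_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    dtype = np.uint16 if mask.max(initial=0) <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(path, mask.astype(dtype))


def write_outputs(
    results_dir,
    stack: ImageStack,
    probmaps=None,
    masks: dict[str, np.ndarray] | None = None,
    cell_table: pd.DataFrame | None = None,
    relationships: pd.DataFrame | None = None,
) -> Path:
    """Write the organised per-ROI results folder.

    Layout: ``<results_dir>/<roi_id>/full_stack/<marker>.tiff``,
    ``probability_maps/``, ``masks/``, ``cells.csv`` and
    ``object_relationships.csv``.  Returns the ROI directory path.
    """
    roi_dir = Path(results_dir) / stack.roi_id
    (roi_dir / "full_stack").mkdir(parents=True, exist_ok=True)
    for ch, plane in zip(stack.channels, stack.pixels):
        tifffile.imwrite(
            roi_dir / "full_stack" / f"{ch.marker}.tiff", plane.astype(np.float32)
        )
    if probmaps is not None:
        pdir = roi_dir / "probability_maps"
        pdir.mkdir(exist_ok=True)
        for name, pm in (
            probmaps.items() if isinstance(probmaps, dict) else [("probmap", probmaps)]
        ):
            pm.write(pdir / f"{name}.tiff")
    if masks:
        mdir = roi_dir / "masks"
        mdir.mkdir(exist_ok=True)
        for name, mask in masks.items():
            _write_mask(mdir / f"{name}.tiff", mask)
    if cell_table is not None:
        if relationships is not None and len(relationships):
            ids = set(cell_table["cell_id"].astype(int))
            rel_ids = set(relationships["cell_id_a"].astype(int)) | set(
                relationships["cell_id_b"].astype(int)
            )
            missing = sorted(rel_ids - ids)
            if missing:
                raise ValueError(
                    f"relationship cell ids absent from cell table: {missing[:5]}"
                )
        write_cells_csv(roi_dir / "cells.csv", cell_table)
        if relationships is not None:
            write_relationships_csv(roi_dir / "object_relationships.csv", relationships)
    return roi_dir
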