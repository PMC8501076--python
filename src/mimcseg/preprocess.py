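"""Image-level cleanup and channel arithmetic preceding classification.

IMC detectors occasionally record isolated "hot" pixels — single-pixel counts
far above their surroundings — which are removed before any smoothing.  The
two DNA-intercalator channels (Ir191/Ir193) are summed and histogram equalised
to give a single well-conditioned nuclear image, and marker channels are
merged into per-class composites (each member rescaled to its own 99th
percentile so bright channels do not dominate) for pixel classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .io_formats import ImageStack, PanelEntry

__all__ = [
    "PreprocessConfig",
    "remove_hot_pixels",
    "median_filter",
    "sum_channels",
    "equalize_hist",
    "merge_channel_groups",
    "preprocess_stack",
]


@dataclass
class PreprocessConfig:
    hot_pixel_threshold: float = 50.0
    median_radius: float = 0.5
    equalize_bins: int = 256

    def __post_init__(self):
        if self.hot_pixel_threshold < 0 or self.median_radius < 0 or self.equalize_bins < 0:
            raise ValueError("preprocess parameters must be >= 0")


def remove_hot_pixels(image: np.ndarray, t: float = 50.0) -> np.ndarray:
    """Replace isolated outlier pixels by their neighbourhood median.

    A pixel is a hot pixel when its value exceeds the *maximum* of its
    8-neighbourhood by more than ``t``; it is replaced by the median of that
    neighbourhood.  All other pixels are unchanged.  Because replacing a
    spike lowers its neighbours' local maxima (which can expose further
    outliers), passes repeat until nothing changes, so the operation is
    idempotent.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        return image.copy()
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    out = image.copy()
    for _ in range(image.size):  # fixpoint is reached long before this
        neigh_max = ndi.maximum_filter(out, footprint=footprint, mode="reflect")
        hot = out > neigh_max + t
        if not np.any(hot):
            break
        neigh_med = ndi.median_filter(out, footprint=footprint, mode="reflect")
        out[hot] = neigh_med[hot]
    return out


def median_filter(image: np.ndarray, radius: float = 0.5) -> np.ndarray:
    """Square-window median filter; radius ``r`` uses a window of side
    ``2*ceil(r) + 1``; radius 0 is the identity."""
    image = np.asarray(image, dtype=np.float64)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0 or image.size == 0:
        return image.copy()
    size = 2 * int(np.ceil(radius)) + 1
    return ndi.median_filter(image, size=size, mode="reflect")


def sum_channels(stack: ImageStack, tags: Sequence[str]) -> np.ndarray:
    """Element-wise sum of the named channels (e.g. Ir191 + Ir193)."""
    if not tags:
        raise ValueError("no channels given")
    return np.sum([stack.get(tag) for tag in tags], axis=0)


def equalize_hist(image: np.ndarray, bins: int = 256) -> np.ndarray:
    """Histogram equalisation via the empirical CDF.

    Output lies in [0, 1], the mapping is monotone non-decreasing in the
    input ranks, and a continuous-valued input yields a near-uniform output
    histogram.  Constant images map to a constant.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        return image.copy()
    flat = image.ravel()
    if flat.max() == flat.min():
        return np.full_like(image, 0.5 if flat[0] != 0 else 0.0)
    # Empirical CDF evaluated at each pixel, rescaled so the smallest value
    # maps to 0 and the largest to 1 (a pure rank map on distinct values).
    values, counts = np.unique(flat, return_counts=True)
    cdf = np.cumsum(counts) / flat.size
    out = np.interp(flat, values, cdf)
    lo = cdf[0]
    out = (out - lo) / (1.0 - lo)
    return out.reshape(image.shape)


def _rescale_p99(image: np.ndarray) -> np.ndarray:
    p = np.percentile(image, 99)
    if p <= 0:
        p = image.max()
    if p <= 0:
        return np.zeros_like(image, dtype=np.float64)
    return np.clip(image / p, 0.0, 1.0)


def merge_channel_groups(
    stack: ImageStack, groups: Mapping[str, Sequence[str]]
) -> ImageStack:
    """Merge marker channels into one composite channel per group.

    Each member channel is first rescaled to its own 99th percentile and
    clipped to [0, 1]; the group composite is the per-pixel sum of the
    rescaled members, clipped to [0, 1].  Group order is preserved.
    """
    if not groups:
        raise ValueError("empty group list")
    planes = []
    entries = []
    for name, tags in groups.items():
        if not tags:
            raise ValueError(f"group {name!r} has no member channels")
        comp = np.sum([_rescale_p99(stack.get(t)) for t in tags], axis=0)
        planes.append(np.clip(comp, 0.0, 1.0))
        entries.append(PanelEntry(metal_tag=name, marker=name))
    return ImageStack(entries, np.stack(planes), roi_id=stack.roi_id)


def preprocess_stack(
    stack: ImageStack, config: PreprocessConfig | None = None
) -> ImageStack:
    """Hot-pixel removal then median filtering, applied channel-wise."""
    config = config or PreprocessConfig()
    planes = np.stack(
        [
            median_filter(
                remove_hot_pixels(p, config.hot_pixel_threshold), config.median_radius
            )
            for p in stack.pixels
        ]
    )
    return ImageStack(list(stack.channels), planes, roi_id=stack.roi_id)
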