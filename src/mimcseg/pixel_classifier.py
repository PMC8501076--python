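"""Per-pixel class probability maps from scribble-supervised classification.

Interactive pixel classification (nuclei / membrane / background for cell
segmentation; normal / tumour / structural for tissue domains) is recast here
as a scribble-supervised random forest: sparse labelled pixels train a
classifier on a bank of multi-scale image features (Gaussian-smoothed
intensity, gradient magnitude, Laplacian of Gaussian per channel and scale).
A two-stage "autocontext" variant appends first-stage predicted probabilities
to the feature bank before retraining, capturing spatial context without
interactive training.  Externally produced probability maps (multichannel
float TIFF in [0, 1]) can be loaded and used interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from .io_formats import ImageStack

__all__ = [
    "ProbabilityMaps",
    "extract_features",
    "train_pixel_model",
    "predict_probabilities",
    "train_and_predict",
]

DEFAULT_SCALES = (1.0, 2.0, 4.0)


@dataclass
class ProbabilityMaps:
    """Per-class probability images in [0, 1], one 2-D map per class.

    Invariant: the per-pixel sum over classes is 1 within 1e-6.
    """

    class_names: list[str]
    maps: np.ndarray  # (n_classes, H, W)

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3 or self.maps.shape[0] != len(self.class_names):
            raise ValueError("maps must be (n_classes, H, W) matching class_names")
        if self.maps.min() < -1e-9 or self.maps.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.maps.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("per-pixel class probabilities must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    def get(self, class_name: str) -> np.ndarray:
        try:
            return self.maps[self.class_names.index(class_name)]
        except ValueError:
            raise KeyError(f"class {class_name!r} not in {self.class_names}") from None

    def write(self, path) -> None:
        tifffile.imwrite(path, self.maps.astype(np.float32), photometric="minisblack")

    @classmethod
    def read(cls, path, class_names: list[str]) -> "ProbabilityMaps":
        arr = np.asarray(tifffile.imread(path), dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        # renormalise away float32 round-off
        arr = np.clip(arr, 0.0, 1.0)
        s = arr.sum(axis=0)
        s[s == 0] = 1.0
        return cls(class_names, arr / s)


def extract_features(
    image_stack: ImageStack | np.ndarray, scales=DEFAULT_SCALES
) -> np.ndarray:
    """Multi-scale feature bank: per channel and scale sigma, the
    Gaussian-smoothed intensity, gradient magnitude, and Laplacian of
    Gaussian.  Returns an array of shape ``(n_features, H, W)`` with
    ``n_features = channels * scales * 3``.
    """
    if isinstance(image_stack, ImageStack):
        planes = image_stack.pixels
    else:
        planes = np.asarray(image_stack, dtype=np.float64)
        if planes.ndim == 2:
            planes = planes[None]
    feats = []
    for plane in planes:
        for s in scales:
            smooth = ndi.gaussian_filter(plane, s) if s > 0 else plane.copy()
            feats.append(smooth)
            feats.append(ndi.gaussian_gradient_magnitude(plane, s) if s > 0 else np.zeros_like(plane))
            feats.append(ndi.gaussian_laplace(plane, s) if s > 0 else np.zeros_like(plane))
    return np.stack(feats)


@dataclass
class PixelModel:
    """Trained scribble classifier with its class roster."""

    forest: RandomForestClassifier
    class_names: list[str]
    autocontext: bool = False
    stage1: "PixelModel | None" = None


def _flatten(features: np.ndarray) -> np.ndarray:
    return features.reshape(features.shape[0], -1).T


def train_pixel_model(
    features: np.ndarray,
    scribbles: np.ndarray,
    class_names: list[str],
    seed: int = 0,
    n_trees: int = 100,
    autocontext: bool = False,
) -> PixelModel:
    """Train a random forest on scribble-labelled pixels.

    ``scribbles`` is an integer image: 0 = unlabelled, value ``k`` = class
    ``class_names[k-1]``.  Training is deterministic given ``seed``.  With
    ``autocontext`` a first forest's predicted probabilities are appended to
    the feature bank and a second forest is trained on the augmented stack.
    """
    scribbles = np.asarray(scribbles)
    labelled = scribbles > 0
    present = np.unique(scribbles[labelled])
    if present.size < 2:
        raise ValueError("scribbles must label at least two classes")
    if present.max() > len(class_names):
        raise ValueError(
            f"scribble class id {present.max()} exceeds the {len(class_names)} "
            "declared classes"
        )
    X = _flatten(features)[labelled.ravel()]
    y = scribbles[labelled]
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, min_samples_leaf=2
    )
    forest.fit(X, y)
    model = PixelModel(forest, list(class_names))
    if autocontext:
        stage1 = model
        prob1 = _predict_maps(stage1, features)
        aug = np.concatenate([features, prob1], axis=0)
        X2 = _flatten(aug)[labelled.ravel()]
        forest2 = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + 1, n_jobs=1, min_samples_leaf=2
        )
        forest2.fit(X2, y)
        model = PixelModel(forest2, list(class_names), autocontext=True, stage1=stage1)
    return model


def _predict_maps(model: PixelModel, features: np.ndarray) -> np.ndarray:
    shape = features.shape[1:]
    prob = model.forest.predict_proba(_flatten(features))
    # forest classes are 1-based scribble ids; scatter into full class roster
    full = np.zeros((len(model.class_names), prob.shape[0]), dtype=np.float64)
    for j, cls in enumerate(model.forest.classes_):
        full[int(cls) - 1] = prob[:, j]
    return full.reshape(len(model.class_names), *shape)


def predict_probabilities(model: PixelModel, features: np.ndarray) -> ProbabilityMaps:
    """Predict a normalised per-pixel class distribution."""
    if model.autocontext and model.stage1 is not None:
        prob1 = _predict_maps(model.stage1, features)
        features = np.concatenate([features, prob1], axis=0)
    maps = _predict_maps(model, features)
    s = maps.sum(axis=0)
    s[s == 0] = 1.0
    return ProbabilityMaps(list(model.class_names), maps / s)


def train_and_predict(
    image_stack: ImageStack | np.ndarray,
    scribbles: np.ndarray,
    class_names: list[str],
    scales=DEFAULT_SCALES,
    seed: int = 0,
    autocontext: bool = False,
) -> ProbabilityMaps:
    """Convenience wrapper: features -> train -> predict on the same image."""
    feats = extract_features(image_stack, scales)
    model = train_pixel_model(feats, scribbles, class_names, seed=seed, autocontext=autocontext)
    return predict_probabilities(model, feats)
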