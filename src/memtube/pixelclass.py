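"""Trainable 3-class pixel segmentation with shape-criteria reclassification.

A multi-scale feature bank (Gaussian smoothings, gradient magnitude,
Laplacian, Hessian eigenvalues) feeds a seeded random-forest pixel
classifier producing {background, tubule, vesicle} label maps. Connected
components are then measured and tubule-labeled objects failing any shape
criterion are reassigned to vesicle; the rule is one-directional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from sklearn.ensemble import RandomForestClassifier

from memtube.synthgen import FluorImage, LABEL_TUBULE, LABEL_VESICLE

__all__ = [
    "FeatureStack",
    "PixelClassifier",
    "LabelMap",
    "ObjectRecord",
    "ShapeCriteria",
    "DEFAULT_SCALES",
    "compute_features",
    "train_classifier",
    "predict_labels",
    "extract_objects",
    "reassign_by_shape",
]

DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.0, 4.0)

CLASS_NAMES = {0: "background", 1: "tubule", 2: "vesicle"}


@dataclass
class FeatureStack:
    """Per-pixel feature vectors, shape (H, W, n_features)."""

    values: np.ndarray
    scales: tuple[float, ...]
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return self.values.shape[-1]

    def as_matrix(self) -> np.ndarray:
        return self.values.reshape(-1, self.n_features)


@dataclass
class PixelClassifier:
    """Opaque trained model mapping feature vectors to {0, 1, 2}."""

    model: RandomForestClassifier
    scales: tuple[float, ...]
    seed: int
    training_ids: list[str] = field(default_factory=list)


@dataclass
class LabelMap:
    """Pixelwise 3-class segmentation with provenance."""

    labels: np.ndarray
    pixel_size_nm: float
    classifier_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if not np.isin(self.labels, (0, 1, 2)).all():
            raise ValueError("label values must be in {0, 1, 2}")


@dataclass
class ObjectRecord:
    """Geometry of one 8-connected foreground component."""

    component_id: int
    cls: str  # "tubule" | "vesicle"
    area_px: int
    area_nm2: float
    major_axis_nm: float
    minor_axis_nm: float
    elongation: float
    skeleton_length_nm: float
    mean_width_nm: float


@dataclass(frozen=True)
class ShapeCriteria:
    """Thresholds for reassigning misclassified tubules to vesicles.

    The source study's exact thresholds live in its deposited code, not its
    text; these defaults are declared substitutes and fully configurable.
    """

    min_tubule_elongation: float = 3.0
    min_tubule_area_px: int = 50
    max_tubule_mean_width_nm: float = 1000.0
    min_object_area_px: int = 10

    def __post_init__(self) -> None:
        if (
            self.min_tubule_elongation <= 0
            or self.min_tubule_area_px <= 0
            or self.max_tubule_mean_width_nm <= 0
            or self.min_object_area_px <= 0
        ):
            raise ValueError("all shape-criteria thresholds must be > 0")


# ---------------------------------------------------------------------------
# features


def compute_features(image: FluorImage, scales: tuple[float, ...] = DEFAULT_SCALES) -> FeatureStack:
    """Multi-scale feature bank. ``scales`` are Gaussian sigmas in pixels.

    All features are invariant under image mirroring and rotation by
    construction (smoothed intensity, gradient magnitude, Laplacian,
    Hessian eigenvalues), with reflection padding at borders.
    """
    if len(scales) == 0:
        raise ValueError("need at least one scale")
    img = np.asarray(image.pixels, dtype=float)
    feats = [img]
    names = ["raw"]
    for s in scales:
        sm = ndimage.gaussian_filter(img, sigma=s, mode="reflect")
        gy = ndimage.gaussian_filter(img, sigma=s, order=(1, 0), mode="reflect")
        gx = ndimage.gaussian_filter(img, sigma=s, order=(0, 1), mode="reflect")
        grad = np.hypot(gy, gx)
        lap = ndimage.gaussian_laplace(img, sigma=s, mode="reflect")
        h = hessian_matrix(img, sigma=s, mode="reflect", use_gaussian_derivatives=True)
        ev_hi, ev_lo = hessian_matrix_eigvals(h)
        feats += [sm, grad, lap, ev_hi, ev_lo]
        names += [f"{n}_s{s:g}" for n in ("gauss", "gradmag", "laplace", "hess_hi", "hess_lo")]
    stack = np.stack(feats, axis=-1)
    if not np.all(np.isfinite(stack)):
        raise ValueError("non-finite feature values")
    return FeatureStack(values=stack, scales=tuple(scales), feature_names=names)


# ---------------------------------------------------------------------------
# classifier


def train_classifier(
    images: list[FluorImage],
    truths: list[np.ndarray | LabelMap],
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
    max_samples_per_class: int = 4000,
    n_estimators: int = 80,
    training_ids: list[str] | None = None,
) -> PixelClassifier:
    """Train a seeded random-forest pixel classifier on labeled images.

    Per image, up to ``max_samples_per_class`` pixels per class are drawn
    (seeded) to keep training balanced and fast. All three classes must be
    present across the training labels.
    """
    if len(images) == 0 or len(images) != len(truths):
        raise ValueError("need equal, non-empty lists of images and label maps")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for img, truth in zip(images, truths):
        lab = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
        if lab.shape != img.pixels.shape:
            raise ValueError("label map shape does not match image")
        fs = compute_features(img, scales)
        flat = fs.as_matrix()
        lab_flat = lab.ravel()
        for cls in (0, 1, 2):
            idx = np.flatnonzero(lab_flat == cls)
            if idx.size == 0:
                continue
            if idx.size > max_samples_per_class:
                idx = rng.choice(idx, size=max_samples_per_class, replace=False)
            xs.append(flat[idx])
            ys.append(lab_flat[idx])
    x = np.concatenate(xs)
    y = np.concatenate(ys).astype(int)
    present = set(np.unique(y))
    missing = {0, 1, 2} - present
    if missing:
        raise ValueError(
            "training labels missing class(es): "
            + ", ".join(CLASS_NAMES[c] for c in sorted(missing))
        )
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        min_samples_leaf=2,
    )
    model.fit(x, y)
    return PixelClassifier(
        model=model, scales=tuple(scales), seed=seed, training_ids=list(training_ids or [])
    )


def predict_labels(model: PixelClassifier, image: FluorImage, image_id: str = "") -> LabelMap:
    """Apply a trained classifier to one image."""
    fs = compute_features(image, model.scales)
    if fs.n_features != model.model.n_features_in_:
        raise ValueError(
            f"feature mismatch: image yields {fs.n_features} features, "
            f"model expects {model.model.n_features_in_}"
        )
    pred = model.model.predict(fs.as_matrix()).reshape(image.pixels.shape)
    return LabelMap(
        labels=pred.astype(np.uint8),
        pixel_size_nm=image.pixel_size_nm,
        classifier_id=f"rf-seed{model.seed}",
        image_id=image_id,
    )


# ---------------------------------------------------------------------------
# object geometry


def _skeleton_length_px(mask: np.ndarray) -> float:
    """Approximate arclength of the morphological skeleton in pixels:
    orthogonal neighbor pairs count 1, diagonal pairs sqrt(2)."""
    sk = morphology.skeletonize(mask)
    orth = int((sk[:, 1:] & sk[:, :-1]).sum() + (sk[1:, :] & sk[:-1, :]).sum())
    diag = int((sk[1:, 1:] & sk[:-1, :-1]).sum() + (sk[1:, :-1] & sk[:-1, 1:]).sum())
    return max(orth + math.sqrt(2.0) * diag, 1.0)


def extract_objects(
    labels: LabelMap, pixel_size_nm: float | None = None, min_object_area_px: int = 10
) -> list[ObjectRecord]:
    """Measure every 8-connected foreground component of a label map.

    Component class is the majority pixel class within the component;
    components smaller than ``min_object_area_px`` are dropped as speckle.
    """
    px = pixel_size_nm if pixel_size_nm is not None else labels.pixel_size_nm
    fg = labels.labels > 0
    comp = measure.label(fg, connectivity=2)
    records: list[ObjectRecord] = []
    for rp in measure.regionprops(comp):
        if rp.area < min_object_area_px:
            continue
        mask = comp == rp.label
        vals = labels.labels[mask]
        n_tub = int((vals == LABEL_TUBULE).sum())
        n_ves = int((vals == LABEL_VESICLE).sum())
        cls = "tubule" if n_tub >= n_ves else "vesicle"
        major = max(rp.axis_major_length, 1.0) * px
        minor = max(rp.axis_minor_length, 1.0) * px
        skel_nm = _skeleton_length_px(mask) * px
        area_nm2 = rp.area * px**2
        records.append(
            ObjectRecord(
                component_id=int(rp.label),
                cls=cls,
                area_px=int(rp.area),
                area_nm2=area_nm2,
                major_axis_nm=major,
                minor_axis_nm=minor,
                elongation=max(major / minor, 1.0),
                skeleton_length_nm=skel_nm,
                mean_width_nm=area_nm2 / skel_nm,
            )
        )
    return records


def reassign_by_shape(
    objects: list[ObjectRecord], criteria: ShapeCriteria = ShapeCriteria()
) -> list[ObjectRecord]:
    """Reassign tubule-labeled objects that fail ANY criterion to vesicle.

    The rule is one-directional (vesicles are never promoted to tubules),
    hence idempotent; input order is preserved.
    """
    out: list[ObjectRecord] = []
    for obj in objects:
        if obj.cls == "tubule" and (
            obj.elongation < criteria.min_tubule_elongation
            or obj.area_px < criteria.min_tubule_area_px
            or obj.mean_width_nm > criteria.max_tubule_mean_width_nm
        ):
            out.append(replace(obj, cls="vesicle"))
        else:
            out.append(replace(obj))
    return out
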