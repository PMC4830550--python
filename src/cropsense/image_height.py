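"""Crop height from marker-bar photographs.

A 200 cm marker bar stands in the field; crops occlude it from the bottom
up, and a 15 cm reference band at its top is always visible. Pixels are
classified (random forest over multi-scale color/edge/texture/orientation
features) into background / marker bar / reference area / circle; the
binary masks are cleaned morphologically, clipped to the bounding box of
the participant-drawn circle, and the maximum per-column run of marker and
reference pixels gives their vertical extents. With the reference band's
known height the visible bar length follows, and crop height is 200 cm
minus the visible part.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from sklearn.ensemble import RandomForestClassifier

from .core_io import ValidationError

MARKER_TOTAL_CM = 200.0
REFERENCE_CM = 15.0

CLASS_NAMES = ("background", "marker", "reference", "circle")
N_CLASSES = 4
UNLABELED = -1

DEFAULT_SCALES = (1.0, 2.0, 4.0)
FEATURES_PER_SCALE = 6  # 3 color + edge + texture + orientation coherence


def pixel_features(image: np.ndarray,
                   scales: Sequence[float] = DEFAULT_SCALES) -> np.ndarray:
    """Per-pixel feature stack of shape (H, W, len(scales) * 6).

    Per scale sigma: Gaussian-smoothed R, G, B; gradient magnitude of the
    luminance (edge); local luminance variance (texture); structure-tensor
    coherence (orientation). Ordering is fixed: scales outer, the six
    features inner in the order just given.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValidationError("expected an H x W x 3 image")
    lum = img.mean(axis=2)
    feats = []
    for sigma in scales:
        for ch in range(3):
            feats.append(ndimage.gaussian_filter(img[:, :, ch], sigma))
        feats.append(ndimage.gaussian_gradient_magnitude(lum, sigma))
        mean = ndimage.gaussian_filter(lum, sigma)
        sq = ndimage.gaussian_filter(lum ** 2, sigma)
        feats.append(np.maximum(sq - mean ** 2, 0.0))
        gx = ndimage.gaussian_filter(lum, sigma, order=(0, 1))
        gy = ndimage.gaussian_filter(lum, sigma, order=(1, 0))
        jxx = ndimage.gaussian_filter(gx * gx, sigma)
        jxy = ndimage.gaussian_filter(gx * gy, sigma)
        jyy = ndimage.gaussian_filter(gy * gy, sigma)
        tr = jxx + jyy
        det_disc = np.sqrt(np.maximum((jxx - jyy) ** 2 + 4 * jxy ** 2, 0.0))
        coherence = np.where(tr > 1e-12, det_disc / np.maximum(tr, 1e-12), 0.0)
        feats.append(coherence)
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifier:
    """Random forest over :func:`pixel_features`, trained on sparse labels."""

    forest: RandomForestClassifier
    scales: tuple[float, ...] = DEFAULT_SCALES
    version: str = "1"

    def predict_proba_image(self, image: np.ndarray) -> np.ndarray:
        """H x W x 4 probability maps, renormalized to sum to one."""
        feats = pixel_features(image, self.scales)
        flat = feats.reshape(-1, feats.shape[-1])
        proba = self.forest.predict_proba(flat)
        maps = np.zeros((flat.shape[0], N_CLASSES))
        for col, cls in enumerate(self.forest.classes_):
            maps[:, int(cls)] = proba[:, col]
        total = maps.sum(axis=1, keepdims=True)
        maps = np.where(total > 0, maps / np.maximum(total, 1e-300), 0.25)
        return maps.reshape(image.shape[0], image.shape[1], N_CLASSES)

    def save(self, path) -> None:
        import joblib
        joblib.dump({"version": self.version, "scales": self.scales,
                     "forest": self.forest}, path)

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        import joblib
        blob = joblib.load(path)
        return cls(forest=blob["forest"], scales=tuple(blob["scales"]),
                   version=blob["version"])


def train_pixel_classifier(labeled: Sequence[tuple[np.ndarray, np.ndarray]],
                           n_trees: int = 50, seed: int = 0,
                           scales: Sequence[float] = DEFAULT_SCALES,
                           max_pixels_per_image: int = 20000) -> PixelClassifier:
    """Train the random-forest pixel classifier on sparsely labeled images.

    ``labeled`` pairs an image with a label mask holding class ids 0-3 on
    labeled pixels and -1 elsewhere. Every class must appear at least once
    across the training set. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for image, labels in labeled:
        labels = np.asarray(labels)
        sel = labels != UNLABELED
        if not sel.any():
            continue
        feats = pixel_features(image, scales)[sel]
        lab = labels[sel]
        if len(lab) > max_pixels_per_image:
            pick = rng.choice(len(lab), size=max_pixels_per_image, replace=False)
            feats, lab = feats[pick], lab[pick]
        xs.append(feats)
        ys.append(lab)
    if not xs:
        raise ValidationError("no labeled pixels provided")
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    present = set(np.unique(y).tolist())
    missing = [CLASS_NAMES[c] for c in range(N_CLASSES) if c not in present]
    if missing:
        raise ValidationError(f"no labeled pixels for class(es): {', '.join(missing)}")
    forest = RandomForestClassifier(n_estimators=n_trees,
                                    random_state=int(seed) % (2 ** 31),
                                    n_jobs=1)
    forest.fit(X, y)
    return PixelClassifier(forest=forest, scales=tuple(scales))


def segment(classifier: PixelClassifier, image: np.ndarray) -> np.ndarray:
    """Per-class probability maps (H x W x 4) for an image."""
    return classifier.predict_proba_image(image)


def binarize(maps: np.ndarray, cls: int, threshold: float = 0.5) -> np.ndarray:
    """Probability >= threshold -> True (ties at exactly 0.5 are included)."""
    return np.asarray(maps)[:, :, cls] >= threshold


def clean_mask(mask: np.ndarray, open_radius_px: int = 2,
               dilate_radius_px: int = 5, erode_back: bool = True) -> np.ndarray:
    """Morphological cleanup: opening (kill specks), dilation (connect
    nearby fragments), then keep only the largest 8-connected component.

    With ``erode_back`` the dilation is undone by an equal erosion after
    the component selection, so fragments get connected without inflating
    the component's extent (the extent ratio is what the height estimate
    rests on). Pixel-count ties between components are broken by the
    smallest (row, col) of the component's top-left bounding corner. An
    empty result is returned as-is; the caller decides whether that is a
    failure.
    """
    m = np.asarray(mask, dtype=bool)
    if open_radius_px > 0:
        m = morphology.opening(m, morphology.disk(open_radius_px))
    if dilate_radius_px > 0:
        m = morphology.dilation(m, morphology.disk(dilate_radius_px))
    if not m.any():
        return m
    labels = measure.label(m, connectivity=2)
    props = measure.regionprops(labels)
    best = min(props, key=lambda p: (-p.area, p.bbox[0], p.bbox[1]))
    m = labels == best.label
    if erode_back and dilate_radius_px > 0:
        m = morphology.erosion(m, morphology.disk(dilate_radius_px))
    return m


def circle_roi(circle_mask: np.ndarray) -> Optional[tuple[int, int, int, int]]:
    """Tight bounding box (row_min, row_max, col_min, col_max), inclusive,
    of the circle mask; None when the mask is empty."""
    m = np.asarray(circle_mask, dtype=bool)
    if not m.any():
        return None
    rows = np.nonzero(m.any(axis=1))[0]
    cols = np.nonzero(m.any(axis=0))[0]
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def clip_to_roi(mask: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = roi
    return np.asarray(mask, dtype=bool)[r0:r1 + 1, c0:c1 + 1]


def vertical_extent(mask: np.ndarray) -> int:
    """Largest per-column count of true pixels (the bar is ~vertical, so
    the best column's pixel count is its visible vertical extent)."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0 or not m.any():
        return 0
    return int(m.sum(axis=0).max())


@dataclass
class HeightEstimate:
    marker_extent_px: int = 0
    reference_extent_px: int = 0
    visible_marker_cm: Optional[float] = None
    crop_height_cm: Optional[float] = None
    status: str = "ok"
    clamped: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def crop_height_from_extents(marker_px: int, reference_px: int) -> HeightEstimate:
    """Scale the visible bar extent by the known 15 cm reference band and
    subtract from the 200 cm total: crop = 200 - 15 * marker_px / reference_px.

    A zero reference extent means no scale is available; a zero marker
    extent would imply a fully obscured 200 cm bar, implausible for crops
    below 2 m, so both are reported as failures rather than heights.
    """
    if reference_px <= 0:
        return HeightEstimate(marker_px, reference_px, status="failed_no_reference")
    if marker_px <= 0:
        return HeightEstimate(marker_px, reference_px, status="failed_no_marker")
    visible = REFERENCE_CM * marker_px / reference_px
    crop = MARKER_TOTAL_CM - visible
    clamped = not (0.0 <= crop <= MARKER_TOTAL_CM)
    crop = float(min(max(crop, 0.0), MARKER_TOTAL_CM))
    return HeightEstimate(marker_px, reference_px, visible_marker_cm=float(visible),
                          crop_height_cm=crop, status="ok", clamped=clamped)


def estimate_from_masks(marker_mask: np.ndarray, reference_mask: np.ndarray,
                        circle_mask: np.ndarray,
                        open_radius_px: int = 2, dilate_radius_px: int = 5,
                        clean: bool = True) -> HeightEstimate:
    """Measurement geometry given binary class masks (cleanup optional)."""
    # the reference band is the top 15 cm OF the bar, so the bar's visible
    # extent is measured on the union of the two classes
    bar_mask = np.asarray(marker_mask, dtype=bool) | np.asarray(reference_mask,
                                                                dtype=bool)
    if clean:
        bar_mask = clean_mask(bar_mask, open_radius_px, dilate_radius_px)
        reference_mask = clean_mask(reference_mask, open_radius_px, dilate_radius_px)
        circle_mask = clean_mask(circle_mask, open_radius_px, dilate_radius_px)
    roi = circle_roi(circle_mask)
    if roi is None:
        return HeightEstimate(status="failed_no_marker")
    marker_px = vertical_extent(clip_to_roi(bar_mask, roi))
    reference_px = vertical_extent(clip_to_roi(reference_mask, roi))
    return crop_height_from_extents(marker_px, reference_px)


def estimate_from_image(classifier: PixelClassifier, image: np.ndarray,
                        threshold: float = 0.5,
                        open_radius_px: int = 2, dilate_radius_px: int = 5,
                        dark_floor: float = 20.0) -> HeightEstimate:
    """Full per-image pipeline; failures come back as status codes so batch
    runs always complete."""
    img = np.asarray(image, dtype=float)
    if img.mean() < dark_floor:
        return HeightEstimate(status="failed_dark")
    try:
        maps = segment(classifier, img)
        marker = binarize(maps, 1, threshold)
        reference = binarize(maps, 2, threshold)
        circle = binarize(maps, 3, threshold)
        return estimate_from_masks(marker, reference, circle,
                                   open_radius_px, dilate_radius_px)
    except Exception:  # batch contract: never raise per-image
        return HeightEstimate(status="failed_no_marker")
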