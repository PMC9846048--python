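"""Modular-field segmentation from the GAD reference channel and ROI algebra.

Automates the manual FIJI workflow used for this kind of material: threshold
the reference channel to delineate GAD-positive modules, combine them into
one modular ROI, outline the total analysis region, derive the matrix ROI as
the exclusive-or of the two, and place a tissue-free background box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk, remove_small_objects

from .errors import BackgroundError, ConfigError, RoiClippedWarning, SegmentationWarning

__all__ = ["RoiSet", "segment_modules", "build_roi_set", "largest_empty_rectangle"]

Rectangle = Tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


@dataclass
class RoiSet:
    """The four analysis regions of one section.

    Invariants: ``module_mask`` is a subset of ``total_mask``;
    ``matrix_mask`` is their exclusive-or restricted to the total region
    (``total & ~module``); the background box is disjoint from the total
    region.
    """

    module_mask: np.ndarray
    total_mask: np.ndarray
    matrix_mask: np.ndarray
    background_mask: np.ndarray

    def validate(self) -> None:
        for name in ("module_mask", "total_mask", "matrix_mask", "background_mask"):
            arr = getattr(self, name)
            if arr.dtype != bool or arr.shape != self.total_mask.shape:
                raise ConfigError(f"{name} must be boolean with a common shape")
        if np.any(self.module_mask & ~self.total_mask):
            raise ConfigError("module_mask is not a subset of total_mask")
        if not np.array_equal(self.matrix_mask, self.total_mask & ~self.module_mask):
            raise ConfigError("matrix_mask != total_mask AND NOT module_mask")
        if np.any(self.background_mask & self.total_mask):
            raise ConfigError("background_mask intersects total_mask")

    @property
    def module_area(self) -> int:
        return int(self.module_mask.sum())

    @property
    def matrix_area(self) -> int:
        return int(self.matrix_mask.sum())

    @property
    def total_area(self) -> int:
        return int(self.total_mask.sum())

    @property
    def background_area(self) -> int:
        return int(self.background_mask.sum())


def _normalize(values: np.ndarray) -> Tuple[np.ndarray, float, float]:
    lo = float(values.min())
    hi = float(values.max())
    return (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values, float), lo, hi


def segment_modules(
    reference: np.ndarray,
    *,
    method: str = "otsu",
    quantile: float = 0.75,
    min_area: int = 50,
    closing_radius: int = 2,
    total_mask: Optional[np.ndarray] = None,
    plausibility: Tuple[float, float] = (0.0, 0.6),
) -> np.ndarray:
    """Label GAD-positive modules in the reference channel.

    The image is min-max normalised (making the result invariant under
    affine intensity rescaling), thresholded (Otsu by default, or a fixed
    quantile of the in-region intensities), morphologically closed, hole
    filled, filtered by ``min_area``, and labelled with 8-connectivity in
    row-major scan order.

    A foreground fraction of 0 or above the upper plausibility bound yields
    an all-zero label mask and a :class:`SegmentationWarning`, never a crash.
    """
    reference = np.asarray(reference)
    if reference.ndim != 2:
        raise ConfigError("reference must be a 2-D raster")
    if min_area <= 0:
        raise ConfigError("min_area must be positive")
    region = np.ones(reference.shape, bool) if total_mask is None else total_mask.astype(bool)

    values = reference[region].astype(np.float64)
    labels = np.zeros(reference.shape, dtype=np.int32)
    if values.size == 0 or values.min() == values.max():
        warnings.warn(
            "reference channel is constant over the analysis region; no modules",
            SegmentationWarning,
        )
        return labels

    norm_values, lo, hi = _normalize(values)
    norm_image = (reference.astype(np.float64) - lo) / (hi - lo)
    if method == "otsu":
        thr = float(threshold_otsu(norm_values))
    elif method == "quantile":
        thr = float(np.quantile(norm_values, quantile))
    else:
        raise ConfigError(f"unknown threshold method {method!r}")

    fg = (norm_image > thr) & region
    frac = fg.sum() / region.sum()
    lo_b, hi_b = plausibility
    if frac <= lo_b or frac > hi_b:
        warnings.warn(
            f"foreground fraction {frac:.3f} outside plausibility bounds "
            f"({lo_b}, {hi_b}]; returning an empty mask",
            SegmentationWarning,
        )
        return labels

    if closing_radius > 0:
        fg = closing(fg, disk(closing_radius)) & region
    fg = ndi.binary_fill_holes(fg)
    # keep components with area >= min_area (max_size removes areas <= it)
    fg = remove_small_objects(fg, max_size=min_area - 1)
    return cc_label(fg, connectivity=2).astype(np.int32)


def largest_empty_rectangle(free: np.ndarray) -> Tuple[int, Rectangle]:
    """Largest axis-aligned all-True rectangle, by the histogram-stack method.

    Returns ``(area, (row0, col0, row1, col1))`` with half-open bounds;
    area 0 if no free pixel exists.
    """
    h, w = free.shape
    heights = np.zeros(w, dtype=np.int64)
    best_area = 0
    best: Rectangle = (0, 0, 0, 0)
    for r in range(h):
        heights = (heights + 1) * free[r]
        stack: list = []
        for c in range(w + 1):
            cur = heights[c] if c < w else 0
            start = c
            while stack and stack[-1][1] >= cur:
                s, sh = stack.pop()
                area = int(sh) * (c - s)
                if area > best_area:
                    best_area = area
                    best = (r - int(sh) + 1, s, r + 1, c)
                start = s
            if not stack or cur > stack[-1][1]:
                stack.append((start, cur))
    return best_area, best


def build_roi_set(
    modules: np.ndarray,
    total: np.ndarray,
    background_box: Union[str, Rectangle] = "auto",
    *,
    min_background_area: int = 1024,
) -> RoiSet:
    """Assemble the ROI set from a module label mask and the total region.

    Module components extending outside ``total`` are clipped to it (with a
    :class:`RoiClippedWarning` naming them); the matrix is the exclusive-or
    of the modular and total ROIs. ``background_box="auto"`` selects the
    largest axis-aligned rectangle fully outside the total region, which
    must reach ``min_background_area``.
    """
    modules = np.asarray(modules)
    total = np.asarray(total, dtype=bool)
    if modules.shape != total.shape:
        raise ConfigError("modules and total must share a shape")

    outside = np.unique(modules[(modules > 0) & ~total])
    if outside.size:
        warnings.warn(
            f"module labels {outside.tolist()} extend outside the total region "
            "and were clipped",
            RoiClippedWarning,
        )
    module_mask = (modules > 0) & total
    matrix_mask = total & ~module_mask

    if background_box == "auto":
        area, (r0, c0, r1, c1) = largest_empty_rectangle(~total)
        if area < min_background_area:
            raise BackgroundError(
                f"largest tissue-free rectangle has area {area} px < required "
                f"{min_background_area}; supply background_box explicitly"
            )
    else:
        r0, c0, r1, c1 = background_box  # type: ignore[misc]
        if not (0 <= r0 < r1 <= total.shape[0] and 0 <= c0 < c1 <= total.shape[1]):
            raise ConfigError(f"background_box {background_box} outside the image")
        if np.any(total[r0:r1, c0:c1]):
            raise BackgroundError("supplied background_box intersects the total region")
        if (r1 - r0) * (c1 - c0) < min_background_area:
            raise BackgroundError(
                f"supplied background_box area {(r1 - r0) * (c1 - c0)} px < "
                f"required {min_background_area}"
            )
    background_mask = np.zeros_like(total)
    background_mask[r0:r1, c0:c1] = True

    rois = RoiSet(
        module_mask=module_mask,
        total_mask=total,
        matrix_mask=matrix_mask,
        background_mask=background_mask,
    )
    rois.validate()
    return rois
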