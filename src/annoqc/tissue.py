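"""Tissue segmentation for exhaustiveness denominators.

A binary tissue mask separates stained tissue from the near-white slide
background so that coverage metrics are computed over tissue only.  The
default method is Otsu thresholding on the HSV saturation channel of a
thumbnail (stained tissue is saturated, glass is not), followed by
morphological opening, small-object removal and hole filling.  Masks are
computed at a configurable downsample (default 32) of the base level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening, remove_small_holes, remove_small_objects

DEFAULT_DOWNSAMPLE = 32.0


@dataclass
class TissueParams:
    """Thresholding parameters for :func:`compute_tissue_mask`.

    ``saturation_floor`` guards Otsu against uniform images: pixels are
    tissue only if their saturation also exceeds this absolute floor.
    Areas are in mask pixels.
    """

    saturation_floor: float = 0.04
    min_object_area: int = 16
    max_hole_area: int = 64
    opening_radius: int = 1


@dataclass
class TissueMask:
    """Binary tissue raster at a known downsample of base resolution.

    ``mask[i, j]`` is True for tissue; mask pixel (0, 0) maps to base
    coordinate ``origin`` and one mask pixel spans ``downsample`` base px.
    """

    mask: np.ndarray
    downsample: float = DEFAULT_DOWNSAMPLE
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.downsample <= 0:
            raise ValueError("downsample must be positive")
        self.mask = np.asarray(self.mask, dtype=bool)

    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def tissue_area_px2(self) -> float:
        """Total tissue area in base-resolution px^2."""
        return float(np.count_nonzero(self.mask)) * self.downsample**2

    # -- I/O: single-channel PNG + sidecar JSON -----------------------
    def save(self, png_path) -> None:
        img = Image.fromarray(np.where(self.mask, 255, 0).astype(np.uint8))
        img.save(png_path)
        sidecar = str(png_path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(
                {"downsample": self.downsample, "origin": list(self.origin)}, fh
            )

    @classmethod
    def load(cls, png_path) -> "TissueMask":
        arr = np.asarray(Image.open(png_path).convert("L")) > 127
        sidecar = str(png_path) + ".json"
        try:
            with open(sidecar) as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"downsample": DEFAULT_DOWNSAMPLE, "origin": [0.0, 0.0]}
        return cls(
            mask=arr,
            downsample=float(meta["downsample"]),
            origin=tuple(meta["origin"]),
        )


def compute_tissue_mask(
    image: np.ndarray,
    params: Optional[TissueParams] = None,
    downsample: float = DEFAULT_DOWNSAMPLE,
    origin: tuple[float, float] = (0.0, 0.0),
) -> TissueMask:
    """Segment tissue from background in an RGB tile or thumbnail.

    Deterministic for fixed parameters.  Near-white / low-saturation
    pixels are background; specks below ``min_object_area`` are removed
    and holes below ``max_hole_area`` are filled.  An all-background
    image yields a valid all-False mask (callers may warn).
    """
    if params is None:
        params = TissueParams()
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image")
    if img.dtype != np.float64:
        img = img.astype(np.float64) / (255.0 if img.max() > 1.0 else 1.0)

    sat = rgb2hsv(img)[..., 1]
    if sat.max() <= params.saturation_floor:
        tissue = np.zeros(sat.shape, dtype=bool)
    elif sat.min() > params.saturation_floor and np.ptp(sat) < 1e-3:
        # uniform saturated image: Otsu is undefined, everything is tissue
        tissue = np.ones(sat.shape, dtype=bool)
    else:
        try:
            thr = threshold_otsu(sat)
        except ValueError:  # single-valued input
            thr = params.saturation_floor
        tissue = sat > max(thr, params.saturation_floor)
        if params.opening_radius > 0:
            tissue = opening(tissue, disk(params.opening_radius))
        if params.min_object_area > 0:
            tissue = remove_small_objects(tissue, max_size=params.min_object_area)
        if params.max_hole_area > 0:
            tissue = remove_small_holes(tissue, max_size=params.max_hole_area)
    return TissueMask(mask=tissue, downsample=downsample, origin=origin)


def tissue_area_in(
    mask: TissueMask, box: tuple[float, float, float, float]
) -> float:
    """Tissue area (base px^2) inside a base-resolution box.

    ``box`` is (xmin, ymin, xmax, ymax).  Counts tissue mask pixels whose
    centres fall in the box, scaled by downsample^2.  Raises if the box
    lies outside the mask extent.
    """
    xmin, ymin, xmax, ymax = box
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("box has non-positive extent")
    ox, oy = mask.origin
    h, w = mask.mask.shape
    # box in mask pixel coordinates
    c0 = (xmin - ox) / mask.downsample
    c1 = (xmax - ox) / mask.downsample
    r0 = (ymin - oy) / mask.downsample
    r1 = (ymax - oy) / mask.downsample
    if c1 <= 0 or r1 <= 0 or c0 >= w or r0 >= h:
        raise ValueError("box outside mask extent")
    cols = np.arange(w) + 0.5
    rows = np.arange(h) + 0.5
    col_sel = (cols >= c0) & (cols < c1)
    row_sel = (rows >= r0) & (rows < r1)
    sub = mask.mask[np.ix_(row_sel, col_sel)]
    return float(np.count_nonzero(sub)) * mask.downsample**2
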