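"""Seven-stage label-free segmentation of phase-contrast images.

The pipeline: (1) background adjustment, (2) texture enhancement,
(3) binarization, (4) small-object removal, (5) morphological closing,
(6) hole filling, (7) frame-touching object removal — followed by
connected-component labeling.  Touching cells are deliberately not split;
population statistics downstream absorb the resulting merges.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import Field, model_validator
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as _sk_closing
from skimage.morphology import disk
from skimage.segmentation import clear_border

from ._model import StrictModel, config_hash

logger = logging.getLogger(__name__)


class SegmentationConfig(StrictModel):
    """Tunable parameters of the segmentation pipeline.

    Defaults suit 4x phase contrast at ~2 µm/px; none is load-bearing —
    tests pin the configs they rely on.
    """

    background_kernel_px: int = Field(default=201, ge=3)
    texture_window_px: int = Field(default=9, ge=3)
    threshold_method: str = Field(default="otsu", pattern="^(otsu|fixed)$")
    threshold_value: float | None = None
    min_object_area_px: int = Field(default=100, ge=1)
    closing_radius_px: int = Field(default=2, ge=0)
    connectivity: int = Field(default=8)

    @model_validator(mode="after")
    def _check(self) -> "SegmentationConfig":
        if self.background_kernel_px % 2 == 0 or self.texture_window_px % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed thresholding requires threshold_value")
        return self

    @property
    def skimage_connectivity(self) -> int:
        return 2 if self.connectivity == 8 else 1


@dataclass
class LabeledMask:
    """Labeled single-cell regions with provenance."""

    labels: np.ndarray
    source_id: str = ""
    config_hash: str = ""

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def region_areas(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel())
        return {k: int(counts[k]) for k in range(1, len(counts)) if counts[k]}

    def qc_dict(self) -> dict:
        return {
            "source": self.source_id,
            "config_hash": self.config_hash,
            "n_regions": self.n_regions,
        }

    def write_qc(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.qc_dict(), indent=2))


def _dtype_range(image: np.ndarray) -> tuple[float, float]:
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return float(info.min), float(info.max)
    return -np.inf, np.inf


def adjust_background(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Remove low-frequency illumination.

    out = image − mean_filter(image, k) + global mean, clipped to the input
    dtype's range.  Returns float64.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    k = cfg.background_kernel_px
    if k > min(img.shape):
        raise ValueError(
            f"background kernel {k} exceeds image extent {min(img.shape)}"
        )
    f = img.astype(np.float64)
    smooth = ndi.uniform_filter(f, size=k, mode="reflect")
    out = f - smooth + f.mean()
    lo, hi = _dtype_range(img)
    return np.clip(out, lo, hi)


def enhance_texture(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Local-contrast map: windowed standard deviation, rescaled to [0, 1].

    Flat areas score 0; cell bodies and halo edges score high.  A constant
    image maps to all zeros.
    """
    f = np.asarray(image, dtype=np.float64)
    w = cfg.texture_window_px
    m1 = ndi.uniform_filter(f, size=w, mode="reflect")
    m2 = ndi.uniform_filter(f * f, size=w, mode="reflect")
    sd = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
    peak = sd.max()
    if peak <= 0:
        return np.zeros_like(sd)
    return sd / peak


def binarize(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Threshold to foreground = pixels above threshold (Otsu by default).

    Constant input under Otsu falls back to an all-background mask with a
    logged warning.
    """
    f = np.asarray(image, dtype=np.float64)
    if cfg.threshold_method == "fixed":
        thr = float(cfg.threshold_value)  # validated non-None
    else:
        if np.ptp(f) == 0:
            logger.warning("constant image: Otsu undefined, returning empty mask")
            return np.zeros(f.shape, dtype=bool)
        thr = float(threshold_otsu(f))
    return f > thr


def remove_small(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Delete components with area < min_object_area_px (boundary inclusive:
    components of exactly the minimum area are kept)."""
    m = np.ascontiguousarray(mask, dtype=bool)
    labeled = cc_label(m, connectivity=cfg.skimage_connectivity)
    if labeled.max() == 0:
        return m
    counts = np.bincount(labeled.ravel())
    keep = counts >= cfg.min_object_area_px
    keep[0] = False
    return keep[labeled]


def close_then_fill(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Morphological closing (disk footprint) then hole filling.

    Holes are background components not connected to the image border, so a
    "hole" escaping through a 1-px channel to the frame stays open.
    """
    m = np.asarray(mask, dtype=bool)
    if cfg.closing_radius_px > 0:
        m = _sk_closing(m, footprint=disk(cfg.closing_radius_px))
    return ndi.binary_fill_holes(m)


def remove_border_objects(mask: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Delete any component with at least one pixel on the image frame."""
    m = np.asarray(mask, dtype=bool)
    conn = (cfg.skimage_connectivity if cfg else 2)
    labeled = cc_label(m, connectivity=conn)
    return np.asarray(clear_border(labeled) > 0)


def segment(
    image: np.ndarray,
    cfg: SegmentationConfig | None = None,
    source_id: str = "",
) -> LabeledMask:
    """Run all seven stages and label the result.

    Deterministic for fixed (image, cfg).  Region labels are assigned in
    scan order by :func:`skimage.measure.label`.
    """
    cfg = cfg or SegmentationConfig()
    x = adjust_background(image, cfg)
    x = enhance_texture(x, cfg)
    m = binarize(x, cfg)
    m = remove_small(m, cfg)
    m = close_then_fill(m, cfg)
    m = remove_border_objects(m, cfg)
    labels = cc_label(m, connectivity=cfg.skimage_connectivity)
    return LabeledMask(
        labels=labels.astype(np.int32),
        source_id=source_id,
        config_hash=config_hash(cfg),
    )
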