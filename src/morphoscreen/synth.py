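"""Synthetic phase-contrast-like images of confluent elongated cells.

Cells are modeled as capsules (rectangles with semicircular caps),
optionally bent along a circular arc.  Rendering mimics the two artifacts
a label-free segmentation pipeline must cope with: a low-order additive
background gradient and a bright halo rim around each dark cell body, plus
i.i.d. Gaussian sensor noise.  Every image ships with a pixel-aligned
ground-truth instance mask and the sampled shape parameters.

Gray-level parameters (`background_level`, `cell_depth`, `halo_strength`,
`background_gradient_amplitude`, `noise_sd`) are expressed in the 16-bit
output scale (0–65535).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from pydantic import Field, model_validator
from skimage.measure import label as cc_label

from ._model import StrictModel, rng_from
from .morphometry import CellRecord, CellTable

logger = logging.getLogger(__name__)


class SyntheticSpec(StrictModel):
    """Generative parameters for one synthetic field of cells.

    Identical spec + seed yields bit-identical image and mask.
    """

    n_cells: int = Field(default=150, ge=0)
    length_mean: float = Field(default=80.0, gt=0, description="µm")
    length_sd: float = Field(default=20.0, ge=0, description="µm")
    width_mean: float = Field(default=16.0, gt=0, description="µm")
    width_sd: float = Field(default=3.0, ge=0, description="µm")
    orientation_kappa: float = Field(
        default=0.0,
        ge=0,
        description="von Mises concentration over [0, π); 0 = uniform",
    )
    curvature: float = Field(
        default=0.0, ge=0, description="arc bend angle (rad) of the spine"
    )
    overlap_fraction: float = Field(default=0.3, ge=0, lt=1)
    min_gap_px: float = Field(
        default=3.0,
        ge=0,
        description="extra pairwise clearance (px) at overlap_fraction=0",
    )
    border_margin_px: float = Field(
        default=0.0,
        description="keep centroids this far from the frame (may be negative)",
    )
    background_level: float = Field(default=20000.0, ge=0)
    cell_depth: float = Field(default=6000.0, ge=0)
    halo_strength: float = Field(default=4000.0, ge=0)
    halo_width_px: float = Field(default=2.0, ge=0)
    background_gradient_amplitude: float = Field(default=2500.0, ge=0)
    noise_sd: float = Field(default=1200.0, ge=0)
    pixel_size: float = Field(default=2.0, gt=0, description="µm/px")
    image_shape: tuple[int, int] = (1000, 1000)
    connectivity: int = Field(default=8)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        if self.length_mean < self.width_mean:
            raise ValueError("length_mean must be >= width_mean")
        if any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        return self


@dataclass(frozen=True)
class CellShape:
    """Sampled shape parameters of one capsule cell (lengths in µm)."""

    length_um: float
    width_um: float
    orientation_rad: float
    curvature: float = 0.0


@dataclass
class GroundTruth:
    """Instance mask plus the shape parameters of every rendered cell.

    ``instance_mask`` uses 0 for background and consecutive labels
    ``1..n``; label k corresponds to ``shapes[k-1]`` and
    ``centroids_px[k-1]``.  ``n_dropped`` counts cells that could not be
    placed (or were fully overwritten) and were discarded.
    """

    instance_mask: np.ndarray
    shapes: list[CellShape]
    centroids_px: list[tuple[float, float]] = field(default_factory=list)
    n_dropped: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.shapes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(1, len(self.shapes) + 1),
                "length_um": [s.length_um for s in self.shapes],
                "width_um": [s.width_um for s in self.shapes],
                "orientation_rad": [s.orientation_rad for s in self.shapes],
            }
        )


def sample_cell_shapes(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[CellShape]:
    """Draw ``spec.n_cells`` capsule parameter sets.

    Lengths and widths are normal draws truncated at > 0 (redrawn while
    non-positive); length >= width is enforced by swapping.  Orientation is
    uniform over [0, π) when ``orientation_kappa == 0`` and von Mises
    (folded to [0, π)) otherwise.
    """
    n = spec.n_cells
    if n == 0:
        return []

    def _trunc_pos(mean: float, sd: float, size: int) -> np.ndarray:
        vals = rng.normal(mean, sd, size)
        for _ in range(1000):
            bad = vals <= 0
            if not bad.any():
                break
            vals[bad] = rng.normal(mean, sd, int(bad.sum()))
        else:
            raise ValueError(
                f"could not draw positive values from N({mean}, {sd}²)"
            )
        return vals

    lengths = _trunc_pos(spec.length_mean, spec.length_sd, n)
    widths = _trunc_pos(spec.width_mean, spec.width_sd, n)
    swap = widths > lengths
    lengths[swap], widths[swap] = widths[swap], lengths[swap].copy()
    if spec.orientation_kappa == 0:
        thetas = rng.uniform(0.0, np.pi, n)
    else:
        thetas = np.mod(rng.vonmises(0.0, spec.orientation_kappa, n), np.pi)
    return [
        CellShape(float(l), float(w), float(t), spec.curvature)
        for l, w, t in zip(lengths, widths, thetas)
    ]


def _spine_points(shape: CellShape, pixel_size: float) -> np.ndarray:
    """Dense (row, col) offsets of the capsule spine, in pixels."""
    L = shape.length_um / pixel_size
    W = shape.width_um / pixel_size
    S = max(L - W, 0.0)  # spine (arc) length so total extent ~= L
    if S == 0:
        return np.zeros((1, 2))
    step = 0.4
    t = np.linspace(-0.5, 0.5, max(int(np.ceil(S / step)) + 1, 2))
    if shape.curvature <= 1e-9:
        xs = t * S
        ys = np.zeros_like(xs)
    else:
        # circular arc of arc-length S subtending `curvature` radians
        R = S / shape.curvature
        phi = t * shape.curvature
        xs = R * np.sin(phi)
        ys = R * (1.0 - np.cos(phi))
    c, s = np.cos(shape.orientation_rad), np.sin(shape.orientation_rad)
    # orientation measured in image plane: rows grow downward
    rows = xs * s + ys * c
    cols = xs * c - ys * s
    return np.column_stack([rows, cols])


def _rasterize(
    shape: CellShape,
    centroid: tuple[float, float],
    spec: SyntheticSpec,
) -> tuple[tuple[slice, slice], np.ndarray, np.ndarray] | None:
    """Rasterize one capsule; returns (window, body, halo) boolean tiles."""
    half_w = 0.5 * shape.width_um / spec.pixel_size
    spine = _spine_points(shape, spec.pixel_size)
    spine = spine + np.asarray(centroid)[None, :]
    pad = half_w + spec.halo_width_px + 1.0
    r0 = int(np.floor(spine[:, 0].min() - pad))
    r1 = int(np.ceil(spine[:, 0].max() + pad)) + 1
    c0 = int(np.floor(spine[:, 1].min() - pad))
    c1 = int(np.ceil(spine[:, 1].max() + pad)) + 1
    H, Wd = spec.image_shape
    r0, r1 = max(r0, 0), min(r1, H)
    c0, c1 = max(c0, 0), min(c1, Wd)
    if r0 >= r1 or c0 >= c1:
        return None
    rr, cc = np.meshgrid(
        np.arange(r0, r1, dtype=float),
        np.arange(c0, c1, dtype=float),
        indexing="ij",
    )
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    d2 = np.min(
        ((pts[:, None, :] - spine[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    d = np.sqrt(d2).reshape(rr.shape)
    body = d <= half_w
    halo = (d > half_w) & (d <= half_w + spec.halo_width_px)
    if not body.any():
        return None
    return (slice(r0, r1), slice(c0, c1)), body, halo


def render_image(
    shapes: Sequence[CellShape],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, GroundTruth]:
    """Place and render cells; return a uint16 image and its ground truth.

    Placement uses rejection sampling of centroids with a pairwise
    exclusion distance that shrinks as ``overlap_fraction`` grows; at
    ``overlap_fraction=0`` cells are guaranteed disjoint (and non-adjacent).
    Cells that cannot be placed within the retry cap are dropped with a
    warning.  Cells may extend past the frame (they are clipped), which
    deliberately exercises border-object removal downstream.
    """
    H, W = spec.image_shape
    f = spec.overlap_fraction

    placed: list[tuple[CellShape, tuple[float, float]]] = []
    centroids = np.empty((0, 2))
    radii = np.empty(0)
    n_dropped = 0
    m = spec.border_margin_px
    lo_r, hi_r = min(m, H - m), max(m, H - m)
    lo_c, hi_c = min(m, W - m), max(m, W - m)
    for shape in shapes:
        r_i = 0.5 * shape.length_um / spec.pixel_size
        ok = None
        for _ in range(200):
            cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            if len(centroids):
                dmin = (1.0 - f) * (
                    radii + r_i + 2.0 * spec.halo_width_px + spec.min_gap_px
                )
                if np.any(np.linalg.norm(centroids - cand, axis=1) < dmin):
                    continue
            ok = cand
            break
        if ok is None:
            n_dropped += 1
            continue
        placed.append((shape, (float(ok[0]), float(ok[1]))))
        centroids = np.vstack([centroids, ok])
        radii = np.append(radii, r_i)
    if n_dropped:
        logger.warning("dropped %d unplaceable cells", n_dropped)

    mask = np.zeros((H, W), dtype=np.int32)
    body_any = np.zeros((H, W), dtype=bool)
    halo_any = np.zeros((H, W), dtype=bool)
    kept: list[CellShape] = []
    kept_centroids: list[tuple[float, float]] = []
    for shape, cen in placed:
        tile = _rasterize(shape, cen, spec)
        if tile is None:
            n_dropped += 1
            continue
        win, body, halo = tile
        kept.append(shape)
        kept_centroids.append(cen)
        mask[win][body] = len(kept)
        body_any[win] |= body
        halo_any[win] |= halo

    mask, kept, kept_centroids, n_split = _enforce_connected_labels(
        mask, kept, kept_centroids, spec.connectivity
    )
    n_dropped += n_split

    img = np.full((H, W), spec.background_level, dtype=float)
    if spec.background_gradient_amplitude > 0:
        img += _background_gradient(
            (H, W), spec.background_gradient_amplitude, rng
        )
    else:
        # keep the RNG stream aligned regardless of amplitude
        rng.uniform(-1, 1, 3)
    img[halo_any & ~body_any] += spec.halo_strength
    img[body_any] = spec.background_level - spec.cell_depth
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(H, W))
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    gt = GroundTruth(
        instance_mask=mask,
        shapes=kept,
        centroids_px=kept_centroids,
        n_dropped=n_dropped,
    )
    return img, gt


def _background_gradient(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-order polynomial illumination field, peak-to-peak ≈ amplitude."""
    H, W = shape
    y = np.linspace(0, 1, H)[:, None]
    x = np.linspace(0, 1, W)[None, :]
    a, b, c = rng.uniform(-1, 1, 3)
    g = a * x + b * y + c * x * y
    ptp = np.ptp(g)
    if ptp < 1e-12:
        return np.zeros(shape)
    return (g - g.min()) / ptp * amplitude


def _enforce_connected_labels(
    mask: np.ndarray,
    shapes: list[CellShape],
    centroids: list[tuple[float, float]],
    connectivity: int,
) -> tuple[np.ndarray, list[CellShape], list[tuple[float, float]], int]:
    """Keep each label a single connected region with consecutive ids.

    Overdrawing can split an earlier cell; only its largest fragment is
    kept (smaller fragments become background within the overwriting cell's
    silhouette, which remains rendered dark).  Labels that lost all pixels
    are dropped and the remaining labels compacted to 1..n.
    """
    conn = 2 if connectivity == 8 else 1
    out = np.zeros_like(mask)
    new_shapes: list[CellShape] = []
    new_centroids: list[tuple[float, float]] = []
    n_lost = 0
    next_id = 1
    for k in range(1, len(shapes) + 1):
        sel = mask == k
        if not sel.any():
            n_lost += 1
            continue
        comp = cc_label(sel, connectivity=conn)
        if comp.max() > 1:
            sizes = np.bincount(comp.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            sel = comp == keep
        out[sel] = next_id
        new_shapes.append(shapes[k - 1])
        new_centroids.append(centroids[k - 1])
        next_id += 1
    if n_lost:
        logger.warning("dropped %d fully-overwritten cells", n_lost)
    return out, new_shapes, new_centroids, n_lost


def simulate_image(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Sample shapes and render one image from a spec (deterministic)."""
    rng = rng_from(spec.seed if seed is None else seed)
    shapes = sample_cell_shapes(spec, rng)
    return render_image(shapes, spec, rng)


# ---------------------------------------------------------------------------
# Analytic capsule descriptors (closed-form oracle + image-free cell pools)
# ---------------------------------------------------------------------------

def analytic_descriptors(shape: CellShape) -> dict[str, float]:
    """Closed-form descriptors of an ideal (unrasterized) capsule.

    For a straight capsule of total length L and width W:
    ``area = W(L−W) + π(W/2)²`` and ``perimeter = 2(L−W) + πW``.  Bending
    preserves arc length, so the same formulas are used for bent cells.
    """
    L, W = shape.length_um, shape.width_um
    area = W * (L - W) + np.pi * (W / 2.0) ** 2
    perim = 2.0 * (L - W) + np.pi * W
    comp = min(4.0 * np.pi * area / perim**2, 1.0)
    return {
        "area_um2": float(area),
        "perimeter_um": float(perim),
        "length_um": float(L),
        "width_um": float(W),
        "lw_ratio": float(L / W),
        "compactness": float(comp),
    }


def synthesize_cell_table(
    spec: SyntheticSpec,
    well_id: str = "synthetic",
    condition: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> CellTable:
    """Image-free cell pool: sampled shapes summarized analytically.

    Useful for exercising the profiling and classification stages at scale
    without rendering or segmenting images.
    """
    rng = rng_from(spec.seed) if rng is None else rng
    shapes = sample_cell_shapes(spec, rng)
    records = [
        CellRecord(
            cell_id=i + 1,
            well_id=well_id,
            condition=condition,
            **analytic_descriptors(s),
        )
        for i, s in enumerate(shapes)
    ]
    return CellTable.from_records(records, spec.pixel_size)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_outputs(
    out_dir: str | Path,
    stem: str,
    image: np.ndarray,
    gt: GroundTruth,
    png: bool = False,
) -> dict[str, str]:
    """Write image, label mask and shape CSV; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if png:
        import imageio.v3 as iio

        img8 = (image.astype(np.float64) / 257.0).round().astype(np.uint8)
        p = out / f"{stem}.png"
        iio.imwrite(p, img8)
    else:
        p = out / f"{stem}.tif"
        tifffile.imwrite(p, image)
    paths["image"] = str(p)
    pm = out / f"{stem}_mask.tif"
    tifffile.imwrite(pm, gt.instance_mask.astype(np.uint16))
    paths["mask"] = str(pm)
    pc = out / f"{stem}_shapes.csv"
    gt.to_frame().to_csv(pc, index=False)
    paths["shapes"] = str(pc)
    return paths
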