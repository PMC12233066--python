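"""Shared fixtures: synthetic renders (session-scoped, they are the slow
part) and object-level matching helpers used by several suites."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from morphoscreen.segment import SegmentationConfig, segment
from morphoscreen.synth import SyntheticSpec, simulate_image


@pytest.fixture(scope="session")
def seg_cfg() -> SegmentationConfig:
    """Pinned segmentation config used by the synthetic benchmarks."""
    return SegmentationConfig(
        background_kernel_px=151,
        texture_window_px=5,
        min_object_area_px=150,
        closing_radius_px=2,
    )


@pytest.fixture(scope="session")
def noiseless_spec() -> SyntheticSpec:
    """30 well-separated interior cells, no noise/gradient: count oracle."""
    return SyntheticSpec(
        n_cells=30,
        overlap_fraction=0.0,
        min_gap_px=14.0,
        border_margin_px=80.0,
        length_mean=100.0,
        length_sd=20.0,
        width_mean=28.0,
        width_sd=4.0,
        halo_width_px=1.0,
        noise_sd=0.0,
        background_gradient_amplitude=0.0,
        image_shape=(800, 800),
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_render(noiseless_spec):
    return simulate_image(noiseless_spec)


@pytest.fixture(scope="session")
def noisy_spec() -> SyntheticSpec:
    """Default noisy benchmark fixture: realistic noise, gradient, halo."""
    return SyntheticSpec(
        n_cells=80,
        overlap_fraction=0.1,
        min_gap_px=8.0,
        length_mean=100.0,
        length_sd=20.0,
        width_mean=28.0,
        width_sd=4.0,
        halo_width_px=1.0,
        noise_sd=900.0,
        background_gradient_amplitude=2500.0,
        halo_strength=4000.0,
        image_shape=(1000, 1000),
        seed=5,
    )


@pytest.fixture(scope="session")
def noisy_render(noisy_spec):
    return simulate_image(noisy_spec)


@pytest.fixture(scope="session")
def noisy_segmentation(noisy_render, seg_cfg):
    image, gt = noisy_render
    return gt, segment(image, seg_cfg)


def border_labels(mask: np.ndarray) -> set[int]:
    edge = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    return set(np.unique(edge)) - {0}


def dilated_border_labels(mask: np.ndarray, radius: int) -> set[int]:
    """Labels whose footprint dilated by `radius` px touches the frame."""
    out: set[int] = set()
    for lab in range(1, int(mask.max()) + 1):
        sel = ndi.binary_dilation(mask == lab, iterations=radius)
        if sel[0].any() or sel[-1].any() or sel[:, 0].any() or sel[:, -1].any():
            out.add(lab)
    return out


def object_f1(
    gt_mask: np.ndarray,
    det_mask: np.ndarray,
    iou_threshold: float = 0.5,
) -> tuple[float, int, int, int]:
    """Greedy one-to-one object matching at an IoU threshold.

    Ground-truth cells touching the frame are excluded: the pipeline
    removes frame-touching objects by design, so they are not detectable.
    Returns (f1, n_matched, n_gt, n_detected).
    """
    excluded = border_labels(gt_mask)
    gt_labels = [l for l in range(1, int(gt_mask.max()) + 1) if l not in excluded]
    det_labels = list(range(1, int(det_mask.max()) + 1))
    pairs: list[tuple[float, int, int]] = []
    for g in gt_labels:
        gsel = gt_mask == g
        for d in np.unique(det_mask[gsel]):
            if d == 0:
                continue
            dsel = det_mask == d
            inter = np.logical_and(gsel, dsel).sum()
            iou = inter / (gsel.sum() + dsel.sum() - inter)
            if iou >= iou_threshold:
                pairs.append((float(iou), g, int(d)))
    pairs.sort(reverse=True)
    used_g: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _, g, d in pairs:
        if g in used_g or d in used_d:
            continue
        used_g.add(g)
        used_d.add(d)
        tp += 1
    precision = tp / len(det_labels) if det_labels else 0.0
    recall = tp / len(gt_labels) if gt_labels else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return f1, tp, len(gt_labels), len(det_labels)
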