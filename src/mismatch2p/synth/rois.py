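"""Synthetic ROI label images with known morphology-filter ground truth.

Three shape families, each placed without overlap and with a deliberate
margin to the morphology thresholds (CI 0.14, area 150 px):

* discs — compact somatic/bouton-like blobs, CI ≈ 1 ≫ 0.14 → excluded
  by circularity regardless of area;
* elongated curves — thin axon-segment-like paths, ≥ 150 px with CI well
  below 0.14 → kept;
* specks — small fragments under 150 px → excluded by area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import draw, morphology


def _place(occupied: np.ndarray, shape_mask: np.ndarray, rng, max_tries: int = 200):
    """Random non-overlapping placement (1 px dilation margin) of a mask."""
    h, w = shape_mask.shape
    H, W = occupied.shape
    if h >= H or w >= W:
        raise ValueError("shape does not fit in image")
    grown = morphology.dilation(shape_mask, morphology.disk(1)).astype(bool)
    for _ in range(max_tries):
        r = rng.integers(0, H - h)
        c = rng.integers(0, W - w)
        region = occupied[r : r + h, c : c + w]
        if not np.any(region & grown):
            return r, c
    raise RuntimeError("could not place shape without overlap")


def _disc(rng) -> np.ndarray:
    radius = int(rng.integers(6, 14))
    mask = np.zeros((2 * radius + 3, 2 * radius + 3), dtype=bool)
    rr, cc = draw.disk((radius + 1, radius + 1), radius)
    mask[rr, cc] = True
    return mask


def _elongated(rng, min_area: int = 200) -> np.ndarray:
    """A thin meandering path ≥ min_area px, 2 px wide."""
    length = int(rng.integers(150, 260))
    pts_r, pts_c = [0.0], [0.0]
    angle = rng.uniform(0, 2 * np.pi)
    for _ in range(length):
        angle += rng.normal(0, 0.08)
        pts_r.append(pts_r[-1] + np.sin(angle))
        pts_c.append(pts_c[-1] + np.cos(angle))
    r = np.asarray(pts_r)
    c = np.asarray(pts_c)
    r -= r.min()
    c -= c.min()
    h, w = int(r.max()) + 4, int(c.max()) + 4
    mask = np.zeros((h, w), dtype=bool)
    for i in range(len(r) - 1):
        rr, cc = draw.line(int(r[i]) + 1, int(c[i]) + 1, int(r[i + 1]) + 1, int(c[i + 1]) + 1)
        mask[rr, cc] = True
    mask = morphology.dilation(mask, morphology.disk(1)).astype(bool)
    if mask.sum() < min_area:  # rare tight spiral: extend by another pass
        return _elongated(rng, min_area)
    return mask


def _speck(rng) -> np.ndarray:
    """A small elongated fragment well under the area threshold."""
    length = int(rng.integers(8, 30))
    mask = np.zeros((3, length + 2), dtype=bool)
    mask[1, 1 : length + 1] = True
    return mask


def generate_roi_label_image(
    n_discs: int,
    n_elongated: int,
    n_small: int,
    image_size: tuple = (400, 400),
    seed=0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A 16-bit label image plus its ground-truth table.

    Returns (label_image, truth) where truth has columns label,
    shape_kind ∈ {disc, elongated, speck}, expected_kept, and
    expected_reason for the intended morphology-filter outcome.
    """
    rng = np.random.default_rng(seed)
    H, W = image_size
    labels = np.zeros((H, W), dtype=np.uint16)
    occupied = np.zeros((H, W), dtype=bool)
    rows = []
    makers = (
        [("disc", _disc, False, "circularity")] * n_discs
        + [("elongated", _elongated, True, "")] * n_elongated
        + [("speck", _speck, False, "area")] * n_small
    )
    for label, (kind, maker, kept, reason) in enumerate(makers, start=1):
        mask = maker(rng)
        r, c = _place(occupied, mask, rng)
        h, w = mask.shape
        labels[r : r + h, c : c + w][mask] = label
        occupied[r : r + h, c : c + w] |= mask
        rows.append(
            {"label": label, "shape_kind": kind, "expected_kept": kept, "expected_reason": reason}
        )
    return labels, pd.DataFrame(rows)
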