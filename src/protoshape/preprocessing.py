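"""Mask cleanup and coupled-sample construction.

Raw RGB photographs plus raw segmentation masks are turned into clean
128x128 coupled samples through a fixed chain: morphological opening
(square kernel, k=5) -> retain the largest 8-connected component ->
zero the background -> isotropic crop/resize with a guaranteed 20-pixel
empty frame on the output canvas. A minimal pluggable segmenter
interface is provided; heavy external segmenters are an extension
point, not shipped logic.

Conventions: 0-based (row, col); mask value 1 = object; morphology pads
with background (0) outside the canvas; mask resampling is
nearest-neighbor so masks stay exactly binary, RGB is bilinear and is
re-zeroed outside the resized mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "EmptyMaskError", "CoupledSample", "open_mask", "largest_component",
    "remove_background", "crop_resize", "preprocess",
    "Segmenter", "BorderColorSegmenter",
]

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


class EmptyMaskError(ValueError):
    """Raised when a cleanup step leaves no foreground pixel."""


@dataclass
class CoupledSample:
    """Background-removed RGB raster paired with its binary mask.

    rgb is (S, S, 3) float in [0, 1] and zero wherever mask is zero;
    mask is (S, S) uint8 in {0, 1} with a single connected component
    whose bounding box respects the empty frame.
    """

    rgb: np.ndarray
    mask: np.ndarray
    class_label: int
    origin_id: str
    transform_tag: str = "original"

    def validate(self, frame: int = 20) -> None:
        s = self.mask.shape[0]
        if self.rgb.shape != (s, s, 3) or self.mask.shape != (s, s):
            raise ValueError("rgb/mask shape mismatch")
        if not np.all(np.isin(self.mask, (0, 1))):
            raise ValueError("mask must be binary")
        if np.any(self.rgb[self.mask == 0] != 0):
            raise ValueError("background not zeroed")
        n = ndimage.label(self.mask, structure=_STRUCT8)[1]
        if n != 1:
            raise ValueError(f"expected one component, found {n}")
        rows, cols = np.nonzero(self.mask)
        if rows.min() < frame or cols.min() < frame or \
                rows.max() >= s - frame or cols.max() >= s - frame:
            raise ValueError("object violates the empty frame")


# ------------------------------------------------------------------ operations

def _as_binary(mask) -> np.ndarray:
    m = np.asarray(mask)
    return (m > 0).astype(np.uint8)


def open_mask(mask, k: int = 5) -> np.ndarray:
    """Morphological opening: erosion then dilation with a k x k square."""
    if k < 1 or k % 2 == 0:
        raise ValueError("kernel side must be odd and >= 1")
    m = _as_binary(mask).astype(bool)
    struct = np.ones((k, k), dtype=bool)
    eroded = ndimage.binary_erosion(m, structure=struct, border_value=0)
    opened = ndimage.binary_dilation(eroded, structure=struct, border_value=0)
    if not opened.any():
        raise EmptyMaskError(f"opening with k={k} removed every pixel")
    return opened.astype(np.uint8)


def largest_component(mask) -> np.ndarray:
    """Keep only the largest 8-connected component.

    Ties are broken by the smallest top-left bounding-box corner in
    row-major order.
    """
    m = _as_binary(mask)
    if not m.any():
        raise EmptyMaskError("mask has no foreground")
    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n == 1:
        return m
    sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) > 1:
        boxes = ndimage.find_objects(labels)
        corners = [(boxes[c - 1][0].start, boxes[c - 1][1].start) for c in candidates]
        winner = candidates[int(np.lexsort((
            [c[1] for c in corners], [c[0] for c in corners]))[0])]
        logger.info("largest_component tie among %d blobs of %d px; "
                    "kept the row-major first", len(candidates), int(best_size))
    else:
        winner = candidates[0]
    return (labels == winner).astype(np.uint8)


def remove_background(rgb, mask) -> np.ndarray:
    """Zero every pixel outside the mask."""
    rgb = np.asarray(rgb, dtype=float)
    m = _as_binary(mask)
    if rgb.shape[:2] != m.shape:
        raise ValueError("rgb/mask shape mismatch")
    return rgb * m[..., None]


def crop_resize(rgb, mask, out_size: int = 128, frame: int = 20,
                class_label: int = -1, origin_id: str = "",
                transform_tag: str = "original") -> CoupledSample:
    """Tight-crop the object and rescale it isotropically onto the canvas.

    The bounding box's larger side is scaled to out_size - 2*frame and
    the object is centered, so no foreground pixel falls inside the
    `frame`-pixel margin of the output.
    """
    m = _as_binary(mask)
    if not m.any():
        raise EmptyMaskError("cannot crop an empty mask")
    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    h, w = r1 - r0, c1 - c0
    if max(h, w) < 2:
        raise ValueError("degenerate (single-pixel) bounding box")

    target = out_size - 2 * frame
    scale = target / max(h, w)
    nh = target if h >= w else max(1, round(h * scale))
    nw = target if w > h else max(1, round(w * scale))

    crop_rgb = np.asarray(rgb, dtype=float)[r0:r1, c0:c1]
    crop_m = m[r0:r1, c0:c1]
    rs_m = resize(crop_m.astype(float), (nh, nw), order=0,
                  anti_aliasing=False, preserve_range=True) >= 0.5
    rs_rgb = resize(crop_rgb, (nh, nw, 3), order=1,
                    anti_aliasing=False, preserve_range=True)

    out_rgb = np.zeros((out_size, out_size, 3))
    out_m = np.zeros((out_size, out_size), dtype=np.uint8)
    ro = (out_size - nh) // 2
    co = (out_size - nw) // 2
    out_m[ro:ro + nh, co:co + nw] = rs_m
    out_rgb[ro:ro + nh, co:co + nw] = rs_rgb
    out_rgb *= out_m[..., None]
    out_rgb = np.clip(out_rgb, 0.0, 1.0)
    return CoupledSample(out_rgb, out_m, class_label, origin_id, transform_tag)


def preprocess(rgb, raw_mask, class_label: int, origin_id: str,
               k: int = 5, out_size: int = 128, frame: int = 20) -> CoupledSample:
    """Full cleanup chain: open -> largest component -> zero bg -> crop/resize."""
    m = open_mask(raw_mask, k=k)
    m = largest_component(m)
    cleaned = remove_background(rgb, m)
    sample = crop_resize(cleaned, m, out_size=out_size, frame=frame,
                         class_label=class_label, origin_id=origin_id)
    logger.debug("preprocess %s: %d fg px", origin_id, int(sample.mask.sum()))
    return sample


# ------------------------------------------------------------------ raster I/O

def load_rgb(path) -> np.ndarray:
    """Read an 8-bit RGB PNG as float in [0, 1]."""
    from PIL import Image
    return np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0


def load_mask(path) -> np.ndarray:
    """Read a single-channel 0/255 PNG as a 0/1 mask."""
    from PIL import Image
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.uint8)


def save_rgb(path, rgb) -> None:
    from PIL import Image
    arr = (np.clip(np.asarray(rgb, dtype=float), 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def save_mask(path, mask) -> None:
    from PIL import Image
    Image.fromarray((_as_binary(mask) * 255), mode="L").save(path)


# ------------------------------------------------------------------- segmenter

class Segmenter:
    """Pluggable segmentation interface: segment(rgb) -> binary mask.

    An adapter wrapping an external promptable segmenter (e.g. FastSAM)
    conforms by implementing `segment`; none is shipped here.
    """

    def segment(self, rgb: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BorderColorSegmenter(Segmenter):
    """Default segmenter for synthetic scenes with homogeneous backgrounds.

    Estimates the background color as the median of the outermost border
    pixels and thresholds the per-pixel color distance, which makes it
    robust to global illumination shifts.
    """

    def __init__(self, tol: float = 0.08):
        self.tol = tol

    def segment(self, rgb: np.ndarray) -> np.ndarray:
        rgb = np.asarray(rgb, dtype=float)
        border = np.concatenate([rgb[0], rgb[-1], rgb[:, 0], rgb[:, -1]])
        bg = np.median(border, axis=0)
        dist = np.linalg.norm(rgb - bg, axis=-1)
        return (dist > self.tol).astype(np.uint8)
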