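"""Synthetic device-like image generator.

Emulates a small photographic corpus of single medical-style instruments
on homogeneous preparatory tables: 8 shape families with distinct
silhouettes, variable fill color, mild texture, three global illumination
modes, exact binary ground-truth masks, and multi-object table scenes.
Every generator is a pure function of (spec, seed), so all downstream
modules are testable without any external dataset.

Also provides labeled Gaussian embedding clusters with controllable
class separation, used as fixtures for the prototype classifier head and
the reliability score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = [
    "ShapeClassSpec", "SceneSpec", "PlacementError",
    "ILLUMINATION_MODES", "SILHOUETTES", "default_class_specs",
    "canonical_silhouette", "gen_object", "gen_dataset", "gen_scene",
    "gen_embedding_clusters", "write_manifest", "read_manifest",
]

# Global intensity transforms: per-channel multipliers applied to the
# whole raster (object and background alike); masks are never affected.
ILLUMINATION_MODES = {
    "neutral": (1.00, 1.00, 1.00),
    "cool": (0.85, 0.95, 1.10),
    "warm": (1.10, 1.00, 0.85),
}

# Homogeneous table backgrounds (small palette, one color per image/scene).
BACKGROUND_PALETTE = (
    (0.16, 0.16, 0.20),
    (0.82, 0.80, 0.75),
    (0.25, 0.32, 0.28),
    (0.55, 0.50, 0.45),
)


class PlacementError(RuntimeError):
    """Raised when scene objects cannot be placed without overlap."""


# ------------------------------------------------------------------ silhouettes
# Predicates over normalized coordinates (u, v) in [-1, 1]^2; each family
# is non-congruent to the others under rotation+flip at equal scale.

def _disc(u, v):
    return u * u + v * v <= 1.0


def _bar(u, v):
    return (np.abs(u) <= 1.0) & (np.abs(v) <= 0.25)


def _ell(u, v):
    return ((np.abs(u) <= 1.0) & (v >= 0.5) & (v <= 1.0)) | \
           ((u >= -1.0) & (u <= -0.5) & (np.abs(v) <= 1.0))


def _tee(u, v):
    return ((np.abs(u) <= 1.0) & (v >= 0.5) & (v <= 1.0)) | \
           ((np.abs(u) <= 0.25) & (np.abs(v) <= 1.0))


def _ring(u, v):
    r2 = u * u + v * v
    return (r2 <= 1.0) & (r2 >= 0.55 ** 2)


def _cross(u, v):
    return ((np.abs(u) <= 1.0) & (np.abs(v) <= 0.25)) | \
           ((np.abs(u) <= 0.25) & (np.abs(v) <= 1.0))


def _ellipse(u, v):
    return u * u + (v / 0.45) ** 2 <= 1.0


def _star(u, v):
    r = np.sqrt(u * u + v * v)
    th = np.arctan2(v, u)
    return r <= 0.55 + 0.45 * np.cos(5.0 * th)


SILHOUETTES = {
    "disc": _disc, "bar": _bar, "L": _ell, "T": _tee,
    "ring": _ring, "cross": _cross, "ellipse": _ellipse, "star": _star,
}


# Characteristic device colors (instruments keep a brand-like base color;
# per-sample jitter and illumination vary around it).
CLASS_COLORS = (
    (0.75, 0.72, 0.70), (0.25, 0.45, 0.80), (0.80, 0.30, 0.25),
    (0.85, 0.80, 0.35), (0.35, 0.70, 0.45), (0.70, 0.45, 0.75),
    (0.85, 0.55, 0.30), (0.45, 0.75, 0.80),
)


@dataclass(frozen=True)
class ShapeClassSpec:
    """One device class: silhouette family plus appearance variability."""

    class_id: int
    silhouette: str
    base_color: tuple[float, float, float] = (0.6, 0.6, 0.6)
    scale_range: tuple[float, float] = (0.45, 0.70)
    color_jitter: tuple[float, float] = (0.80, 1.20)
    illumination_modes: tuple[str, ...] = ("neutral", "cool", "warm")

    def __post_init__(self):
        if self.silhouette not in SILHOUETTES:
            raise ValueError(f"unknown silhouette {self.silhouette!r}")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("scale_range must lie in (0, 1]")


def default_class_specs(K: int = 8) -> list[ShapeClassSpec]:
    """The default K-class device roster (K <= 8 distinct silhouettes)."""
    names = list(SILHOUETTES)
    if K < 2 or K > len(names):
        raise ValueError(f"K must be in 2..{len(names)}")
    return [ShapeClassSpec(class_id=i, silhouette=names[i],
                           base_color=CLASS_COLORS[i]) for i in range(K)]


@dataclass(frozen=True)
class SceneSpec:
    """A multi-object preparatory-table scene."""

    n_objects: int = 8
    canvas_size: int = 384
    object_size: int = 96
    resolution_fraction: float = 1.0
    max_retries: int = 200

    def __post_init__(self):
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if not (0.0 < self.resolution_fraction <= 1.0):
            raise ValueError("resolution_fraction must be in (0, 1]")


# ------------------------------------------------------------------- rasterizer

def _rasterize(silhouette, canvas, center_rc, radius, theta, flip=False):
    rr, cc = np.mgrid[0:canvas, 0:canvas].astype(float)
    dr, dc = rr - center_rc[0], cc - center_rc[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = (dc * ct + dr * st) / radius
    v = (-dc * st + dr * ct) / radius
    if flip:
        u = -u
    return SILHOUETTES[silhouette](u, v)


def canonical_silhouette(spec: ShapeClassSpec, size: int = 128) -> np.ndarray:
    """Unrotated, centered, fixed-scale binary silhouette (for analysis)."""
    r = 0.40 * size
    return _rasterize(spec.silhouette, size, (size / 2, size / 2), r, 0.0).astype(np.uint8)


def gen_object(spec: ShapeClassSpec, light: str = "neutral", seed: int = 0,
               canvas_size: int = 128, background=None):
    """Render one object photo: raw RGB raster plus its exact binary mask.

    The mask is a hard 0/1 rasterization (no anti-aliasing); background
    pixels carry one constant palette color. Geometry and appearance are
    drawn from `seed` only, so two illumination modes of the same seed
    share a bit-identical mask.
    """
    if canvas_size < 32:
        raise ValueError("canvas must be at least 32x32")
    if light not in ILLUMINATION_MODES:
        raise ValueError(f"unknown illumination mode {light!r}")
    rng = np.random.default_rng(seed)

    scale = rng.uniform(*spec.scale_range)
    radius = scale * canvas_size / 2.0
    jitter = 0.05 * canvas_size
    if radius + jitter * np.sqrt(2) > canvas_size / 2.0:
        raise ValueError("scale too large for canvas")
    center = (canvas_size / 2.0 + rng.uniform(-jitter, jitter),
              canvas_size / 2.0 + rng.uniform(-jitter, jitter))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    mask = _rasterize(spec.silhouette, canvas_size, center, radius, theta)

    base = np.asarray(spec.base_color) * rng.uniform(*spec.color_jitter, size=3)
    texture = rng.normal(1.0, 0.06, size=(canvas_size, canvas_size))
    if background is None:
        background = BACKGROUND_PALETTE[rng.integers(len(BACKGROUND_PALETTE))]

    rgb = np.empty((canvas_size, canvas_size, 3))
    rgb[:] = np.asarray(background)
    obj = np.clip(base[None, :] * texture[mask][:, None], 0.0, 1.0)
    rgb[mask] = obj
    rgb = np.clip(rgb * np.asarray(ILLUMINATION_MODES[light]), 0.0, 1.0)
    return rgb, mask.astype(np.uint8)


# --------------------------------------------------------------------- dataset

def gen_dataset(K: int, n_per_class, seed: int = 0, canvas_size: int = 128,
                class_specs=None):
    """Generate coupled originals (clean RGB + mask) with a manifest.

    `n_per_class` may be an int (balanced) or a length-K sequence, which
    allows unbalanced corpora such as an 87-image 8-class set.  Each
    original is passed through the standard preprocessing chain so it
    satisfies the coupled-sample invariants.
    """
    from .preprocessing import preprocess

    if K < 2:
        raise ValueError("K must be >= 2")
    specs = class_specs if class_specs is not None else default_class_specs(K)
    counts = [int(n_per_class)] * K if np.isscalar(n_per_class) else list(n_per_class)
    if len(counts) != K:
        raise ValueError("per-class counts must have length K")

    rng = np.random.default_rng(seed)
    samples, rows = [], []
    for spec, n in zip(specs, counts):
        for i in range(n):
            obj_seed = int(rng.integers(2 ** 31))
            light = spec.illumination_modes[int(rng.integers(len(spec.illumination_modes)))]
            rgb, mask = gen_object(spec, light=light, seed=obj_seed,
                                   canvas_size=canvas_size)
            origin = f"c{spec.class_id}_o{i:03d}"
            sample = preprocess(rgb, mask, spec.class_id, origin)
            samples.append(sample)
            rows.append({"origin_id": origin, "class": spec.class_id,
                         "path_rgb": "", "path_mask": "", "split": "",
                         "transform_tag": "original"})
    manifest = pd.DataFrame(rows)
    return samples, manifest


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False,
                       dtype={"origin_id": str, "split": str,
                              "path_rgb": str, "path_mask": str,
                              "transform_tag": str})


# ----------------------------------------------------------------------- scenes

def downsample(raster, fraction: float, order: int = 1) -> np.ndarray:
    """Reduce a raster to `fraction` of its linear resolution."""
    h, w = raster.shape[:2]
    small = (max(1, round(h * fraction)), max(1, round(w * fraction)))
    return resize(raster, small + raster.shape[2:], order=order,
                  anti_aliasing=False, preserve_range=True)


def _degrade(raster, fraction, order):
    """Downsample to `fraction` linear resolution and back (blocky upscale)."""
    if fraction >= 1.0:
        return raster
    lo = downsample(raster, fraction, order=order)
    return resize(lo, raster.shape, order=0, anti_aliasing=False,
                  preserve_range=True)


def gen_scene(spec: SceneSpec, seed: int = 0, class_specs=None):
    """Compose a preparatory-table scene of non-overlapping objects.

    Returns (scene RGB, list of (full-canvas mask, class label, bbox)).
    Object appearance is optionally degraded to `resolution_fraction`
    before pasting, emulating small devices captured in a wide field of
    view; ground-truth masks follow the degraded rasters exactly.
    """
    rng = np.random.default_rng(seed)
    specs = class_specs if class_specs is not None else default_class_specs(8)
    background = BACKGROUND_PALETTE[rng.integers(len(BACKGROUND_PALETTE))]
    canvas = np.empty((spec.canvas_size, spec.canvas_size, 3))
    canvas[:] = np.asarray(background)

    s = spec.object_size
    if s > spec.canvas_size:
        raise PlacementError("object size exceeds scene canvas")

    # rejection-sample a non-overlapping layout; dense scenes fall back to
    # a shuffled grid, which succeeds whenever enough cells exist
    placed: list[tuple[int, int]] = []
    for idx in range(spec.n_objects):
        for _ in range(spec.max_retries + 1):
            r0 = int(rng.integers(0, spec.canvas_size - s + 1))
            c0 = int(rng.integers(0, spec.canvas_size - s + 1))
            if all(abs(r0 - r) >= s or abs(c0 - c) >= s for r, c in placed):
                placed.append((r0, c0))
                break
        else:
            break
    if len(placed) < spec.n_objects:
        n_cells = spec.canvas_size // s
        cells = [(r * s, c * s) for r in range(n_cells)
                 for c in range(n_cells)]
        if spec.n_objects > len(cells):
            raise PlacementError(
                f"cannot place {spec.n_objects} objects of size {s} on a "
                f"{spec.canvas_size} canvas after {spec.max_retries} retries")
        order = rng.permutation(len(cells))[:spec.n_objects]
        placed = [cells[i] for i in order]

    objects = []
    for idx, (r0, c0) in enumerate(placed):
        cls_spec = specs[idx % len(specs)]
        rgb, mask = gen_object(cls_spec, light="neutral",
                               seed=int(rng.integers(2 ** 31)),
                               canvas_size=s, background=background)
        rgb = _degrade(rgb, spec.resolution_fraction, order=1)
        mask = _degrade(mask.astype(float), spec.resolution_fraction,
                        order=0) >= 0.5
        canvas[r0:r0 + s, c0:c0 + s][mask] = rgb[mask]
        full_mask = np.zeros((spec.canvas_size, spec.canvas_size), dtype=np.uint8)
        full_mask[r0:r0 + s, c0:c0 + s] = mask
        objects.append((full_mask, cls_spec.class_id, (r0, c0, r0 + s, c0 + s)))
    return canvas, objects


# ----------------------------------------------------------- embedding clusters

def gen_embedding_clusters(K: int, H: int, dim: int, separation: float,
                           seed: int = 0):
    """Labeled spherical Gaussian clusters with controlled separability.

    `separation` is the minimum pairwise centroid distance in units of
    the within-class spread (identity covariance). Returns (X, y) with
    K*H rows in class-major order.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    centroids = rng.normal(size=(K, dim))
    if K > 1 and separation > 0:
        d = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
        d_min = d[~np.eye(K, dtype=bool)].min()
        centroids *= separation / d_min
    else:
        centroids *= 0.0 if separation == 0 else 1.0
    y = np.repeat(np.arange(K), H)
    X = centroids[y] + rng.normal(size=(K * H, dim))
    return X, y
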