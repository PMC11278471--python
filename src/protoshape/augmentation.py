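"""Flip/rotation augmentation (x80) and leakage-safe fold assignment.

Each coupled original yields 80 derivatives: the 4-element flip group
{identity, horizontal, vertical, both} crossed with 20 rotations in 18
degree steps about the mask's center of mass. Fold assignment for
cross-validation happens at the origin-photo level and is class
stratified, so no augmented derivative of a training original can leak
into validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

from .preprocessing import CoupledSample, EmptyMaskError

__all__ = [
    "FLIP_TAGS", "AugmentedSet", "FoldAssignment",
    "flips", "rotations", "augment", "iter_augmented", "augment_dataset",
    "assign_folds", "apply_transform",
]

logger = logging.getLogger(__name__)

FLIP_TAGS = ("f0", "fh", "fv", "fhv")


def _flip_arrays(rgb, mask, tag):
    if tag == "f0":
        return rgb, mask
    if tag == "fh":
        return rgb[:, ::-1], mask[:, ::-1]
    if tag == "fv":
        return rgb[::-1], mask[::-1]
    if tag == "fhv":
        return rgb[::-1, ::-1], mask[::-1, ::-1]
    raise ValueError(f"unknown flip tag {tag!r}")


def _compose_tag(base: str, new: str) -> str:
    return new if base == "original" else f"{base}|{new}"


def flips(sample: CoupledSample) -> list[CoupledSample]:
    """The 4-element flip orbit: identity, horizontal, vertical, both."""
    out = []
    for tag in FLIP_TAGS:
        rgb, mask = _flip_arrays(sample.rgb, sample.mask, tag)
        out.append(CoupledSample(np.ascontiguousarray(rgb),
                                 np.ascontiguousarray(mask),
                                 sample.class_label, sample.origin_id,
                                 _compose_tag(sample.transform_tag, tag)))
    return out


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Center of mass of the foreground, continuous (row, col)."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("centroid of an empty mask")
    return float(rows.mean()), float(cols.mean())


def _rotate_once(sample: CoupledSample, angle_deg: float, tag: str) -> CoupledSample:
    cr, cc = mask_centroid(sample.mask)
    # skimage's center is (col, row); positive angle = counterclockwise
    mask = _sk_rotate(sample.mask.astype(float), angle_deg, center=(cc, cr),
                      order=0, preserve_range=True, cval=0.0) >= 0.5
    if not mask.any():
        raise EmptyMaskError(f"rotation by {angle_deg} deg left no foreground")
    rgb = _sk_rotate(sample.rgb, angle_deg, center=(cc, cr), order=1,
                     preserve_range=True, cval=0.0)
    rgb = np.clip(rgb * mask[..., None], 0.0, 1.0)
    clipped = 1.0 - mask.sum() / max(sample.mask.sum(), 1)
    if clipped > 0.05:
        logger.info("rotation %s of %s clipped %.1f%% of the object",
                    tag, sample.origin_id, 100 * clipped)
    return CoupledSample(rgb, mask.astype(np.uint8), sample.class_label,
                         sample.origin_id,
                         _compose_tag(sample.transform_tag, tag))


def rotations(sample: CoupledSample, n: int = 20, step: float = 18.0) -> list[CoupledSample]:
    """n rotations by i*step degrees (i = 0..n-1) about the mask centroid.

    i=0 is the untouched identity; masks rotate nearest-neighbor, RGB
    bilinear with zero fill and re-zeroing outside the rotated mask.
    """
    out = []
    for i in range(n):
        tag = f"r{i:02d}"
        if i == 0:
            out.append(CoupledSample(sample.rgb.copy(), sample.mask.copy(),
                                     sample.class_label, sample.origin_id,
                                     _compose_tag(sample.transform_tag, tag)))
        else:
            out.append(_rotate_once(sample, i * step, tag))
    return out


def apply_transform(sample: CoupledSample, flip_tag: str, rot_index: int,
                    n_rot: int = 20, step: float = 18.0) -> CoupledSample:
    """Apply one of the 80 flip x rotation transforms on demand."""
    rgb, mask = _flip_arrays(sample.rgb, sample.mask, flip_tag)
    flipped = CoupledSample(np.ascontiguousarray(rgb), np.ascontiguousarray(mask),
                            sample.class_label, sample.origin_id,
                            _compose_tag(sample.transform_tag, flip_tag))
    if rot_index == 0:
        flipped.transform_tag = _compose_tag(flipped.transform_tag, "r00")
        return flipped
    if not 0 <= rot_index < n_rot:
        raise ValueError("rotation index out of range")
    return _rotate_once(flipped, rot_index * step, f"r{rot_index:02d}")


def augment(sample: CoupledSample, n_rot: int = 20, step: float = 18.0) -> list[CoupledSample]:
    """All flip x rotation derivatives of one original (default 80)."""
    out = []
    for f in flips(sample):
        out.extend(rotations(f, n=n_rot, step=step))
    return out


def iter_augmented(samples, n_rot: int = 20, step: float = 18.0):
    """Lazily yield every augmented derivative of an original corpus."""
    for s in samples:
        yield from augment(s, n_rot=n_rot, step=step)


@dataclass
class AugmentedSet:
    """Materialized augmented corpus with origin provenance."""

    samples: list[CoupledSample]
    provenance: dict[str, list[int]] = field(default_factory=dict)


def augment_dataset(samples, n_rot: int = 20, step: float = 18.0) -> AugmentedSet:
    out, prov = [], {}
    for s in samples:
        derived = augment(s, n_rot=n_rot, step=step)
        prov[s.origin_id] = list(range(len(out), len(out) + len(derived)))
        out.extend(derived)
    return AugmentedSet(out, prov)


# -------------------------------------------------------------------- folding

@dataclass
class FoldAssignment:
    """Origin-level, class-stratified fold map for F-fold cross-validation."""

    fold_of: dict[str, int]
    n_folds: int
    balance: pd.DataFrame  # class x fold origin counts

    def val_origins(self, fold: int) -> set[str]:
        return {o for o, f in self.fold_of.items() if f == fold}

    def train_origins(self, fold: int) -> set[str]:
        return {o for o, f in self.fold_of.items() if f != fold}

    def audit(self) -> None:
        """Assert zero origin leakage between every train/val pair."""
        for f in range(self.n_folds):
            overlap = self.train_origins(f) & self.val_origins(f)
            if overlap:  # pragma: no cover - impossible by construction
                raise AssertionError(f"origin leakage in fold {f}: {overlap}")


def assign_folds(originals, F: int = 5, seed: int = 0) -> FoldAssignment:
    """Assign origin photos to F folds, stratified by class.

    `originals` is an iterable of CoupledSamples or (origin_id, class)
    pairs. Per-class fold counts differ by at most one. The assignment
    depends only on the set of origins and the seed, not on input order.
    """
    pairs = []
    for o in originals:
        if isinstance(o, CoupledSample):
            pairs.append((o.origin_id, o.class_label))
        else:
            pairs.append((str(o[0]), int(o[1])))
    by_class: dict[int, set[str]] = {}
    for origin, cls in pairs:
        by_class.setdefault(cls, set()).add(origin)

    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    counts = {}
    for cls in sorted(by_class):
        origins = sorted(by_class[cls])
        if len(origins) < F:
            logger.warning("class %s has %d originals < %d folds; some "
                           "validation folds will hold no item of it",
                           cls, len(origins), F)
        order = rng.permutation(len(origins))
        row = np.zeros(F, dtype=int)
        for rank, idx in enumerate(order):
            fold = rank % F
            fold_of[origins[idx]] = fold
            row[fold] += 1
        counts[cls] = row
    balance = pd.DataFrame(counts).T
    balance.index.name = "class"
    balance.columns = [f"fold{f}" for f in range(F)]
    assignment = FoldAssignment(fold_of, F, balance)
    assignment.audit()
    return assignment
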