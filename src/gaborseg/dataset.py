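"""Balanced pixel sampling and train/validation/test splitting.

The learning set is a class-balanced collection of vessel and non-vessel
pixels pooled across images (non-vessel pixels only from inside the field
of view), split 65:10:25 into train/validation/test with stratification by
class. Sampling and splitting are deterministic given a seed and are keyed
on sorted (image_id, row, col) order, so results do not depend on input
file ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import PixelFeatureMatrix

__all__ = ["LabeledDataset", "sample_pixels", "split_dataset", "DEFAULT_RATIOS"]

DEFAULT_RATIOS = (0.65, 0.10, 0.25)
SPLIT_NAMES = ("train", "val", "test")


@dataclass
class LabeledDataset:
    """Feature matrix + binary labels (1 = vessel) + split assignment."""

    features: PixelFeatureMatrix
    labels: np.ndarray
    split: np.ndarray | None = None   # values in {"train","val","test"}
    seed: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != self.features.n:
            raise ValueError("labels length does not match feature matrix")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)
            if self.split.shape[0] != self.features.n:
                raise ValueError("split length does not match feature matrix")

    @property
    def n(self) -> int:
        return self.features.n

    def partition(self, name: str) -> "LabeledDataset":
        if self.split is None:
            raise ValueError("dataset has not been split")
        if name not in SPLIT_NAMES:
            raise ValueError(f"unknown partition {name!r}")
        idx = np.flatnonzero(self.split == name)
        return self.take(idx)

    def take(self, idx: np.ndarray) -> "LabeledDataset":
        from .features import PixelFeatureMatrix as FM

        fm = FM(
            features=self.features.features[idx],
            coords=self.features.coords[idx],
            image_ids=self.features.image_ids[idx],
            layout=self.features.layout,
            standardization=self.features.standardization,
        )
        return LabeledDataset(
            features=fm, labels=self.labels[idx],
            split=None if self.split is None else self.split[idx],
            seed=self.seed,
        )


def sample_pixels(images, n_vessel: int, n_nonvessel: int, seed: int):
    """Draw class-balanced pixel coordinates pooled across images.

    ``images`` is a list of ``(FundusImage, VesselMask)`` pairs. Sampling is
    uniform without replacement within each class; non-vessel candidates are
    restricted to the field of view. Returns a list of
    ``(image_id, row, col, label)`` tuples, vessel rows first.
    """
    vessel_keys, nonvessel_keys = [], []
    for img, truth in images:
        if truth.shape != img.shape:
            raise ValueError(
                f"truth mask shape {truth.shape} does not match image {img.shape}"
            )
        fov = img.fov_mask
        v = truth.mask & fov
        nv = ~truth.mask & fov
        for r, c in zip(*np.nonzero(v)):
            vessel_keys.append((img.id, int(r), int(c)))
        for r, c in zip(*np.nonzero(nv)):
            nonvessel_keys.append((img.id, int(r), int(c)))

    if n_vessel > len(vessel_keys):
        raise ValueError(
            f"requested {n_vessel} vessel pixels but only {len(vessel_keys)} available"
        )
    if n_nonvessel > len(nonvessel_keys):
        raise ValueError(
            f"requested {n_nonvessel} non-vessel pixels but only "
            f"{len(nonvessel_keys)} available"
        )

    rng = np.random.default_rng(seed)
    out = []
    for keys, n, label in ((vessel_keys, n_vessel, 1), (nonvessel_keys, n_nonvessel, 0)):
        keys = sorted(keys)  # file-order independence
        chosen = rng.choice(len(keys), size=n, replace=False)
        out.extend(keys[i] + (label,) for i in sorted(chosen))
    return out


def _largest_remainder(n: int, ratios) -> list[int]:
    """Apportion n into parts proportional to ratios, largest remainder rule."""
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # biggest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(ds: LabeledDataset, ratios=DEFAULT_RATIOS, seed: int = 0) -> LabeledDataset:
    """Assign each row to train/val/test, stratified by class.

    Partition sizes follow largest-remainder rounding per class, so each
    split fraction is exact to within one sample per class. Assignment is
    deterministic given the seed and independent of row order: rows are
    ranked by sorted (image_id, row, col) key before shuffling.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be positive and sum to 1, got {ratios}")

    keys = [
        (str(i), int(r), int(c))
        for i, (r, c) in zip(ds.features.image_ids, ds.features.coords)
    ]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (image_id, row, col) keys; split would be ambiguous")
    order = np.array(sorted(range(len(keys)), key=keys.__getitem__))

    rng = np.random.default_rng(seed)
    split = np.empty(ds.n, dtype=object)
    for label in np.unique(ds.labels):
        cls_rows = order[ds.labels[order] == label]   # canonical order within class
        if cls_rows.size == 0:
            continue
        sizes = _largest_remainder(cls_rows.size, ratios)
        if any(s == 0 for s in sizes):
            raise ValueError(
                f"class {label}: a partition would be empty with n={cls_rows.size} "
                f"and ratios {ratios}"
            )
        perm = rng.permutation(cls_rows.size)
        shuffled = cls_rows[perm]
        start = 0
        for name, size in zip(SPLIT_NAMES, sizes):
            split[shuffled[start:start + size]] = name
            start += size
    return LabeledDataset(features=ds.features, labels=ds.labels, split=split, seed=seed)
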