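"""Image loading, proportional rescaling, and hold-out / k-fold partitioning.

Boards arrive at arbitrary rectangular sizes.  Preprocessing only rescales
each image *in equal proportion* (default to 1/5 linear size); it never crops,
pads or squares — preserving the full board is the point of the size-agnostic
extractor downstream.

The split planner reproduces the published protocol: a stratified 8:2
hold-out (test counts per class are the *ceiling* of the test fraction — the
only rounding consistent with the published per-class test counts), then the
per-class training remainder spread over k folds whose sizes differ by at
most one, any remainder going to the highest-numbered folds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "Sample",
    "SplitPlan",
    "load_manifest",
    "load_image",
    "proportional_rescale",
    "holdout_counts",
    "make_split",
]


@dataclass(frozen=True)
class Sample:
    path: Path
    label: str
    size: tuple[int, int]  # (height_px, width_px)


def load_manifest(manifest_path) -> pd.DataFrame:
    """Read a ``path,label,height,width`` manifest; paths resolve relative to
    the manifest's directory."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {manifest_path} must have columns {sorted(required)}")
    df = df.copy()
    df["path"] = [str(manifest_path.parent / p) for p in df["path"]]
    return df


def load_image(path) -> np.ndarray:
    """Load an image file as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def proportional_rescale(image: np.ndarray, factor: float = 0.2) -> np.ndarray:
    """Rescale an (H, W, 3) image by a single linear factor on both axes.

    The output is round(factor*H) x round(factor*W): the aspect ratio is
    preserved to rounding and no cropping or padding ever occurs.  Default
    factor 0.2 reduces each side to one fifth.
    """
    if not 0 < factor <= 1:
        raise ValueError(f"rescale factor must lie in (0, 1], got {factor}")
    img = np.asarray(image)
    h, w = img.shape[:2]
    if factor == 1.0:
        return img.copy()
    nh, nw = round(factor * h), round(factor * w)
    if nh < 1 or nw < 1:
        raise ValueError(
            f"rescaling {h}x{w} by {factor} would produce an empty {nh}x{nw} image"
        )
    return np.asarray(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))


def holdout_counts(n_class: int, test_fraction: float = 0.2) -> tuple[int, int]:
    """Per-class (n_test, n_train) under the 8:2 hold-out.

    Test counts round *up*: n_test = ceil(test_fraction * n_class).
    """
    if n_class < 1:
        raise ValueError(f"class size must be >= 1, got {n_class}")
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    n_test = math.ceil(test_fraction * n_class)
    return n_test, n_class - n_test


@dataclass(frozen=True)
class SplitPlan:
    """Deterministic partition: per-class test indices plus a fold id (1..k)
    for every training sample.  Indices refer to manifest row order (0-based);
    fold ids are 1-based, mirroring published fold tables."""

    test_indices: dict[str, tuple[int, ...]]
    fold_assignments: dict[int, int]
    k: int
    seed: int

    @property
    def all_test_indices(self) -> set[int]:
        return {i for idxs in self.test_indices.values() for i in idxs}

    def fold_indices(self, fold: int) -> list[int]:
        if not 1 <= fold <= self.k:
            raise ValueError(f"fold must lie in 1..{self.k}, got {fold}")
        return sorted(i for i, f in self.fold_assignments.items() if f == fold)

    def train_indices(self, exclude_fold: int | None = None) -> list[int]:
        """All training indices, optionally excluding one held-out fold."""
        return sorted(
            i for i, f in self.fold_assignments.items()
            if exclude_fold is None or f != exclude_fold
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "seed": self.seed,
                "test": {lab: list(v) for lab, v in self.test_indices.items()},
                "folds": {str(i): f for i, f in sorted(self.fold_assignments.items())},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            test_indices={lab: tuple(v) for lab, v in d["test"].items()},
            fold_assignments={int(i): int(f) for i, f in d["folds"].items()},
            k=int(d["k"]),
            seed=int(d["seed"]),
        )


def fold_sizes(n_train: int, k: int) -> list[int]:
    """Fold sizes for one class: differ by <= 1, remainder in the highest folds."""
    base, rem = divmod(n_train, k)
    return [base + (1 if fold > k - rem else 0) for fold in range(1, k + 1)]


def make_split(
    manifest: pd.DataFrame, k: int = 4, test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Stratified hold-out + k-fold plan, a pure function of its arguments.

    Per class: shuffle that class's manifest rows with the seed, set aside
    ceil(test_fraction * n) as test, then deal the remainder into k folds of
    near-equal size (larger folds get the highest ids).
    """
    if k < 2:
        raise ValueError(f"cross-validation needs k >= 2 folds, got k={k}")
    labels = manifest["label"].tolist()
    rng = np.random.default_rng(seed)
    test_indices: dict[str, tuple[int, ...]] = {}
    fold_assignments: dict[int, int] = {}
    for label in sorted(set(labels)):
        cls_idx = np.array([i for i, lab in enumerate(labels) if lab == label])
        n_test, n_train = holdout_counts(len(cls_idx), test_fraction)
        if n_train < k:
            raise ValueError(
                f"class {label!r} has only {n_train} training samples for k={k} folds"
            )
        perm = rng.permutation(len(cls_idx))
        shuffled = cls_idx[perm]
        test_indices[label] = tuple(int(i) for i in sorted(shuffled[:n_test]))
        train = shuffled[n_test:]
        pos = 0
        for fold, size in enumerate(fold_sizes(n_train, k), start=1):
            for i in train[pos : pos + size]:
                fold_assignments[int(i)] = fold
            pos += size
    return SplitPlan(test_indices, fold_assignments, k=k, seed=seed)
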