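"""Pseudo-color fusion of paired grayscale images, input-size handling and
the stratified train/validation/test split.

The fusion convention places the first (T1-role) image in the blue
channel and the second (T2-role) image in the green channel; the red
channel is identically zero.  Channel order in memory is (R, G, B).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .synthetic import GrayscalePairCase

__all__ = [
    "PseudoColorImage",
    "SplitResult",
    "fuse_pseudo_color",
    "resize_to_input",
    "center_crop",
    "stratified_split",
    "split_assignment",
    "read_manifest",
    "write_splits",
    "read_splits",
    "TEXTURE_CLASS",
]

TEXTURE_CLASS = 2


@dataclass(frozen=True)
class PseudoColorImage:
    """H x W x 3 image in [0, 1], channels (R, G, B); label 0/1 for cohort
    cases, 2 for auxiliary texture images."""

    pixels: np.ndarray
    case_id: str
    label: int

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")


@dataclass(frozen=True)
class SplitResult:
    train: list[str]
    val: list[str]
    test: list[str]
    fractions: tuple[float, float, float]
    seed: int

    def assignment(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name in ("train", "val", "test"):
            for cid in getattr(self, name):
                out[cid] = name
        return out


def fuse_pseudo_color(case: GrayscalePairCase) -> PseudoColorImage:
    """Fuse a paired case into an RGB image: B = img_a (T1 role),
    G = img_b (T2 role), R = 0."""
    if case.img_a.shape != case.img_b.shape:
        raise ValueError("paired images must share a shape")
    h, w = case.img_a.shape
    px = np.zeros((h, w, 3), dtype=np.float64)
    px[:, :, 1] = case.img_b
    px[:, :, 2] = case.img_a
    return PseudoColorImage(px, case.case_id, case.label)


def resize_to_input(image: np.ndarray, size: int = 100) -> np.ndarray:
    """Resize to ``size x size`` (bilinear, anti-aliased on downscale).

    A same-size input is returned unchanged (copy); grayscale and
    3-channel inputs are both accepted.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    if (h, w) == (size, size):
        return image.copy()
    out_shape = (size, size) + image.shape[2:]
    anti_alias = size < max(h, w)
    return _sk_resize(image, out_shape, order=1, anti_aliasing=anti_alias,
                      mode="reflect", preserve_range=True)


def center_crop(image: np.ndarray, size: int) -> np.ndarray:
    """Centred ``size x size`` window; offsets are floor((dim - size) / 2).
    No interpolation — the caller must resize first if the image is small."""
    if size <= 0:
        raise ValueError("size must be positive")
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop size {size}; resize first")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return image[r0:r0 + size, c0:c0 + size, ...].copy()


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    # hand out remainders to the largest fractional parts; ties go to the
    # earlier split (train first)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(cases: list[GrayscalePairCase],
                     fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0,
                     explicit_counts: dict[int, tuple[int, int, int]] | None = None
                     ) -> SplitResult:
    """Per-label split into train/val/test.

    Counts per label follow largest-remainder rounding of ``fractions``
    unless ``explicit_counts`` maps label -> (n_train, n_val, n_test), in
    which case they are matched exactly (and must sum to the label
    totals).  The partition is disjoint, exhaustive and seed-reproducible.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[str]] = {}
    for case in cases:
        by_label.setdefault(case.label, []).append(case.case_id)

    parts: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    for label in sorted(by_label):
        ids = sorted(by_label[label])
        rng.shuffle(ids)
        if explicit_counts is not None:
            counts = explicit_counts.get(label)
            if counts is None or sum(counts) != len(ids):
                raise ValueError(
                    f"explicit_counts for label {label} must sum to {len(ids)}")
        else:
            counts = _largest_remainder(len(ids), fractions)
        i = 0
        for name, n in zip(("train", "val", "test"), counts):
            parts[name].extend(ids[i:i + n])
            i += n
    return SplitResult(parts["train"], parts["val"], parts["test"],
                       tuple(fractions), seed)


def split_assignment(split: SplitResult) -> dict[str, str]:
    return split.assignment()


def read_manifest(path: str, reader=None) -> list[GrayscalePairCase]:
    """Load a cohort from ``manifest.csv`` (case_id, img_a, img_b, label).

    Image paths are resolved relative to the manifest's directory.  The
    default reader handles PNG/TIFF via imageio and rescales 8-/16-bit
    data to [0, 1]; pass ``reader`` (path -> 2-D float array) to plug in
    another format such as DICOM.
    """
    if reader is None:
        import imageio.v3 as iio

        def reader(p: str) -> np.ndarray:
            arr = np.asarray(iio.imread(p), dtype=np.float64)
            if arr.ndim == 3:
                arr = arr.mean(axis=2)
            peak = 255.0 if arr.max() <= 255 else 65535.0
            return arr / peak

    root = os.path.dirname(os.path.abspath(path))
    frame = pd.read_csv(path)
    cases = []
    for row in frame.itertuples(index=False):
        cases.append(GrayscalePairCase(
            str(row.case_id),
            reader(os.path.join(root, row.img_a)),
            reader(os.path.join(root, row.img_b)),
            int(row.label),
        ))
    return cases


def write_splits(split: SplitResult, path: str) -> None:
    rows = [{"case_id": cid, "split": name}
            for name in ("train", "val", "test") for cid in getattr(split, name)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_splits(path: str) -> dict[str, str]:
    frame = pd.read_csv(path)
    return dict(zip(frame["case_id"].astype(str), frame["split"]))
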