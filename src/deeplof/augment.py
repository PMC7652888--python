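"""Training-time augmentation: flips, free rotation, random erasing and
mixup, composed per item each epoch.

Order of application is flip -> rotate -> erase, then mixup pairs items
within the epoch stream.  All outputs stay in [0, 1] and soft labels stay
on the probability simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import rotate as _nd_rotate

__all__ = [
    "AugmentConfig",
    "SoftLabeledImage",
    "random_flip_rotate",
    "random_erasing",
    "mixup",
    "augment_epoch",
    "one_hot",
]


@dataclass(frozen=True)
class AugmentConfig:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rotation_range: float = 180.0  # degrees; angle ~ U(-range, +range)
    erase_prob: float = 0.5
    erase_area_range: tuple[float, float] = (0.02, 0.33)  # fraction of image area
    erase_aspect_range: tuple[float, float] = (0.3, 3.3)
    mixup_alpha: float = 0.2  # Beta(alpha, alpha) shape for the mixing weight
    mixup_enabled: bool = True
    mixup_scope: str = "all"  # "all" or "cohort_only"
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_hflip, self.p_vflip, self.erase_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.erase_area_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("erase_area_range must lie inside (0, 1)")
        if self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be positive")
        if self.mixup_scope not in ("all", "cohort_only"):
            raise ValueError("mixup_scope must be 'all' or 'cohort_only'")


@dataclass(frozen=True)
class SoftLabeledImage:
    pixels: np.ndarray  # H x W x 3
    label_weights: np.ndarray  # length-C simplex vector

    def __post_init__(self):
        w = self.label_weights
        if np.any(w < -1e-12) or abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError("label_weights must be a probability simplex vector")


def one_hot(label: int, n_classes: int = 3) -> np.ndarray:
    v = np.zeros(n_classes)
    v[label] = 1.0
    return v


def random_flip_rotate(image: np.ndarray, config: AugmentConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Flip with the configured probabilities, then rotate by a uniform
    angle in ±rotation_range (bilinear, corners filled with zero)."""
    out = image
    if rng.random() < config.p_hflip:
        out = np.flip(out, axis=1)
    if rng.random() < config.p_vflip:
        out = np.flip(out, axis=0)
    if config.rotation_range > 0:
        angle = rng.uniform(-config.rotation_range, config.rotation_range)
        out = _nd_rotate(out, angle, axes=(1, 0), reshape=False, order=1,
                         mode="constant", cval=0.0)
    return np.clip(np.ascontiguousarray(out), 0.0, 1.0)


def random_erasing(image: np.ndarray, config: AugmentConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """With probability ``erase_prob`` overwrite one random rectangle with
    uniform noise; rectangle area and aspect ratio are drawn from the
    configured ranges (aspect log-uniform, as in the original recipe)."""
    if rng.random() >= config.erase_prob:
        return image
    h, w = image.shape[:2]
    area = h * w
    for _ in range(20):
        target = rng.uniform(*config.erase_area_range) * area
        log_lo, log_hi = np.log(config.erase_aspect_range)
        aspect = np.exp(rng.uniform(log_lo, log_hi))
        eh = int(round(np.sqrt(target * aspect)))
        ew = int(round(np.sqrt(target / aspect)))
        if 0 < eh <= h and 0 < ew <= w:
            r0 = int(rng.integers(0, h - eh + 1))
            c0 = int(rng.integers(0, w - ew + 1))
            out = image.copy()
            out[r0:r0 + eh, c0:c0 + ew, ...] = rng.uniform(
                0.0, 1.0, out[r0:r0 + eh, c0:c0 + ew, ...].shape)
            return out
    return image


def mixup(a: SoftLabeledImage, b: SoftLabeledImage, lam: float | None = None,
          alpha: float = 0.2, rng: np.random.Generator | None = None) -> SoftLabeledImage:
    """Convex combination of two items: pixels and labels are both mixed
    with the same weight ``lam``; if ``lam`` is None it is drawn from
    Beta(alpha, alpha)."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("mixup requires images of identical shape")
    if a.label_weights.shape != b.label_weights.shape:
        raise ValueError("mixup requires labels of identical length")
    if lam is None:
        rng = rng or np.random.default_rng(0)
        lam = float(rng.beta(alpha, alpha))
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    return SoftLabeledImage(
        lam * a.pixels + (1.0 - lam) * b.pixels,
        lam * a.label_weights + (1.0 - lam) * b.label_weights,
    )


def augment_epoch(items: list[SoftLabeledImage], config: AugmentConfig,
                  seed: int) -> list[SoftLabeledImage]:
    """One epoch's augmentation pass: flip/rotate then erase per item,
    then mixup with a random partner.  Deterministic given ``seed``;
    output length equals input length.

    With ``mixup_scope='cohort_only'`` each item is only mixed with a
    partner whose label mass on the auxiliary class (index 2, when
    present) matches its own, keeping texture and cohort streams apart.
    """
    if not items:
        raise ValueError("augment_epoch requires a nonempty stream")
    rng = np.random.default_rng(seed)
    staged = [
        SoftLabeledImage(
            random_erasing(random_flip_rotate(it.pixels, config, rng), config, rng),
            it.label_weights.copy(),
        )
        for it in items
    ]
    if not config.mixup_enabled:
        return staged

    def is_texture(it: SoftLabeledImage) -> bool:
        return it.label_weights.shape[0] > 2 and it.label_weights[2] > 0.5

    partners = rng.permutation(len(staged))
    out = []
    for i, item in enumerate(staged):
        j = int(partners[i])
        if config.mixup_scope == "cohort_only" and is_texture(staged[j]) != is_texture(item):
            j = i
        lam = float(rng.beta(config.mixup_alpha, config.mixup_alpha))
        out.append(mixup(item, staged[j], lam=lam))
    return out
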