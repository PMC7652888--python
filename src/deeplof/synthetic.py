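"""Synthetic paired-image cohorts with a numerous, compact "normal" class
and a rare, diverse "abnormal" class, plus a procedural texture library.

The generator emulates the statistical shape of a small, imbalanced
tumour-imaging cohort: benign-like cases are drawn from a handful of
smooth blob/Gabor archetypes with additive noise (low between-case
variance), malignant-like cases from a larger archetype pool with
per-case random geometry (high between-case variance), and each case
carries two correlated grayscale renderings of the same underlying
tissue field, standing in for two MR contrasts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrayscalePairCase",
    "TextureImage",
    "CohortSpec",
    "generate_cohort",
    "generate_texture_library",
    "tabulate_composition",
    "write_cohort",
    "PAROTID_TABLE",
    "reference_cohort_assignment",
]

NORMAL, ABNORMAL = 0, 1

#: Published reference composition of a 245-case parotid-tumour cohort:
#: per-subtype (label, train, validation, test) counts.  Benign 190
#: (116/38/36), malignant 55 (35/10/10); split totals 151/48/46.
PAROTID_TABLE: dict[str, tuple[int, int, int, int]] = {
    "pleomorphic_adenoma": (NORMAL, 81, 25, 26),
    "warthin_tumor": (NORMAL, 18, 6, 5),
    "other_benign": (NORMAL, 17, 7, 5),
    "mucoepidermoid_carcinoma": (ABNORMAL, 13, 3, 3),
    "acinic_cell_carcinoma": (ABNORMAL, 5, 2, 1),
    "malignant_lymphoma": (ABNORMAL, 5, 1, 1),
    "other_malignant": (ABNORMAL, 12, 4, 5),
}


@dataclass(frozen=True)
class GrayscalePairCase:
    """One case: two registered grayscale images plus a binary label."""

    case_id: str
    img_a: np.ndarray  # T1 role, 2-D, values in [0, 1]
    img_b: np.ndarray  # T2 role, same shape
    label: int  # 0 = normal, 1 = abnormal

    def __post_init__(self):
        if self.img_a.shape != self.img_b.shape or self.img_a.ndim != 2:
            raise ValueError("img_a and img_b must be 2-D arrays of identical shape")
        if self.label not in (NORMAL, ABNORMAL):
            raise ValueError("label must be 0 (normal) or 1 (abnormal)")


@dataclass(frozen=True)
class TextureImage:
    image: np.ndarray  # 2-D, values in [0, 1]
    source_id: str


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters; the defaults mirror the reference cohort's
    size and imbalance (190 normal / 55 abnormal, 22.4% prevalence)."""

    n_normal: int = 190
    n_abnormal: int = 55
    n_textures: int = 61
    image_size: int = 100
    n_archetypes_normal: int = 3
    n_archetypes_abnormal: int = 12
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_normal, self.n_abnormal, self.n_textures) < 0:
            raise ValueError("counts must be non-negative")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8 pixels")
        if self.n_archetypes_abnormal < self.n_archetypes_normal:
            raise ValueError("abnormal archetype pool must be at least as large as the normal pool")


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = np.linspace(-1.0, 1.0, size)
    return np.meshgrid(c, c, indexing="ij")


def _gabor_blob(size: int, cx: float, cy: float, sigma: float, freq: float,
                theta: float, phase: float) -> np.ndarray:
    """Gaussian envelope modulated by an oriented sinusoid, in [0, 1]."""
    yy, xx = _grid(size)
    env = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2)))
    carrier = 0.5 + 0.5 * np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
    return env * (0.4 + 0.6 * carrier)


def _normal_field(rng: np.random.Generator, size: int) -> np.ndarray:
    """Compact archetype: centred round lesion, narrow parameter range."""
    return _gabor_blob(
        size,
        cx=rng.uniform(-0.06, 0.06),
        cy=rng.uniform(-0.06, 0.06),
        sigma=rng.uniform(0.38, 0.45),
        freq=rng.uniform(1.2, 1.8),
        theta=rng.uniform(0, np.pi),
        phase=rng.uniform(0, 2 * np.pi),
    )


def _abnormal_field(rng: np.random.Generator, size: int) -> np.ndarray:
    """Diverse archetype: several blobs with random geometry and texture."""
    n_blobs = rng.integers(2, 6)
    out = np.zeros((size, size))
    for _ in range(n_blobs):
        out += _gabor_blob(
            size,
            cx=rng.uniform(-0.6, 0.6),
            cy=rng.uniform(-0.6, 0.6),
            sigma=rng.uniform(0.10, 0.35),
            freq=rng.uniform(0.8, 6.0),
            theta=rng.uniform(0, np.pi),
            phase=rng.uniform(0, 2 * np.pi),
        )
    peak = out.max()
    return out / peak if peak > 0 else out


def _render_pair(field: np.ndarray, rng: np.random.Generator,
                 noise_sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Two contrast renderings of one tissue field: the second contrast is
    an (inverted) gamma-mapped view, emulating a T1/T2-style difference."""
    gamma_a = rng.uniform(0.8, 1.25)
    gamma_b = rng.uniform(0.8, 1.25)
    a = np.clip(field ** gamma_a + rng.normal(0.0, noise_sd, field.shape), 0.0, 1.0)
    b = np.clip((1.0 - field) ** gamma_b + rng.normal(0.0, noise_sd, field.shape), 0.0, 1.0)
    return a, b


def generate_cohort(spec: CohortSpec) -> list[GrayscalePairCase]:
    """Generate ``n_normal + n_abnormal`` paired-image cases.

    Normal cases reuse a fixed set of ``n_archetypes_normal`` precomputed
    fields (low between-case variance); abnormal cases redraw random
    geometry from one of ``n_archetypes_abnormal`` parameter seeds per
    case (high between-case variance).  Identical specs give bitwise-
    identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size

    normal_fields = [_normal_field(rng, size) for _ in range(spec.n_archetypes_normal)]
    abnormal_seeds = rng.integers(0, 2 ** 31 - 1, size=max(spec.n_archetypes_abnormal, 1))

    cases: list[GrayscalePairCase] = []
    for i in range(spec.n_normal):
        fld = normal_fields[rng.integers(len(normal_fields))] if normal_fields else np.zeros((size, size))
        gain = rng.uniform(0.92, 1.0)
        a, b = _render_pair(np.clip(fld * gain, 0, 1), rng, spec.noise_sd)
        cases.append(GrayscalePairCase(f"n{i:04d}", a, b, NORMAL))
    for i in range(spec.n_abnormal):
        arch = int(abnormal_seeds[rng.integers(len(abnormal_seeds))])
        # per-case geometry: archetype seed is mixed with a fresh case draw
        case_rng = np.random.default_rng((arch + int(rng.integers(0, 2 ** 31 - 1))) % (2 ** 31))
        fld = _abnormal_field(case_rng, size)
        a, b = _render_pair(fld, rng, spec.noise_sd)
        cases.append(GrayscalePairCase(f"a{i:04d}", a, b, ABNORMAL))
    return cases


def generate_texture_library(n: int, size: int = 128, seed: int = 0) -> list[TextureImage]:
    """Procedural texture images: oriented gratings, band-filtered noise
    and their products — deliberately unlike the cohort's blob archetypes."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if size < 8:
        raise ValueError("size must be at least 8 pixels")
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    yy, xx = _grid(size)
    textures: list[TextureImage] = []
    for i in range(n):
        kind = i % 3
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(2.0, 14.0)
        grating = 0.5 + 0.5 * np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta))
                                     + rng.uniform(0, 2 * np.pi))
        noise = gaussian_filter(rng.standard_normal((size, size)), sigma=rng.uniform(0.8, 4.0))
        lo, hi = noise.min(), noise.max()
        noise = (noise - lo) / (hi - lo) if hi > lo else np.zeros_like(noise)
        if kind == 0:
            img = grating
        elif kind == 1:
            img = noise
        else:
            img = grating * noise
        textures.append(TextureImage(np.clip(img, 0.0, 1.0), f"tex{i:04d}"))
    return textures


def tabulate_composition(cases, split_assignment: dict[str, str]) -> pd.DataFrame:
    """Cross-tabulate label x split with margin totals.

    ``cases`` is any iterable of objects with ``case_id`` and ``label``
    attributes.  Every case must be assigned to exactly one of
    train/val/test; an unassigned case raises ``ValueError``.
    """
    splits = ("train", "val", "test")
    counts = {lbl: {s: 0 for s in splits} for lbl in ("normal", "abnormal")}
    for case in cases:
        try:
            split = split_assignment[case.case_id]
        except KeyError:
            raise ValueError(f"case {case.case_id!r} has no split assignment") from None
        if split not in splits:
            raise ValueError(f"unknown split {split!r} for case {case.case_id!r}")
        counts["abnormal" if case.label == ABNORMAL else "normal"][split] += 1
    table = pd.DataFrame(counts).T.loc[["normal", "abnormal"], list(splits)]
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def reference_cohort_assignment() -> tuple[list[GrayscalePairCase], dict[str, str]]:
    """Dummy cases and split assignment reproducing the reference cohort's
    published composition table (labels and split counts only; the images
    are placeholders)."""
    blank = np.zeros((8, 8))
    cases, assignment = [], {}
    for subtype, (label, n_train, n_val, n_test) in PAROTID_TABLE.items():
        for split, n in zip(("train", "val", "test"), (n_train, n_val, n_test)):
            for i in range(n):
                cid = f"{subtype}_{split}_{i:03d}"
                cases.append(GrayscalePairCase(cid, blank, blank, label))
                assignment[cid] = split
    return cases, assignment


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def write_cohort(cases: list[GrayscalePairCase], textures: list[TextureImage],
                 outdir: str) -> str:
    """Write a cohort as 8-bit PNGs plus ``manifest.csv`` and a
    ``textures/`` directory; returns the manifest path."""
    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for case in cases:
        pa, pb = f"{case.case_id}_a.png", f"{case.case_id}_b.png"
        iio.imwrite(os.path.join(outdir, pa), _to_uint8(case.img_a))
        iio.imwrite(os.path.join(outdir, pb), _to_uint8(case.img_b))
        rows.append({"case_id": case.case_id, "img_a": pa, "img_b": pb, "label": case.label})
    texdir = os.path.join(outdir, "textures")
    os.makedirs(texdir, exist_ok=True)
    for tex in textures:
        iio.imwrite(os.path.join(texdir, f"{tex.source_id}.png"), _to_uint8(tex.image))
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
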