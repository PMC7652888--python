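"""End-to-end experiment orchestration and the ablation ladder.

Four arms reproduce the ablation over one backbone:

* ``conventional`` — two-class softmax classifier, no auxiliary
  textures, no norm constraint; score = p(abnormal).
* ``texture`` — three-class softmax with the auxiliary texture class;
  binary score = p1 / (p0 + p1).
* ``texture_l2`` — same, with the L2-constrained softmax head.
* ``texture_l2_lof`` — L2-head feature descriptors of the normal
  training cases form a LOF reference set; the test set is scored by
  LOF.

Each arm trains on the training split, model-selects on validation loss
and is evaluated on the test split only.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import anomaly
from .augment import AugmentConfig
from .evaluation import EvalReport, ScoredLabelSet, build_report
from .imaging import (PseudoColorImage, SplitResult, TEXTURE_CLASS, center_crop,
                      fuse_pseudo_color, resize_to_input, stratified_split)
from .network import (DCNNModel, L2HeadConfig, TrainingConfig, binary_score,
                      build_model, extract_features, predict_softmax, train)
from .synthetic import (CohortSpec, GrayscalePairCase, TextureImage,
                        generate_cohort, generate_texture_library)

__all__ = [
    "ARMS",
    "LOFConfig",
    "ExperimentConfig",
    "AblationReport",
    "prepare_inputs",
    "run_arm",
    "run_experiment",
    "default_benchmark_config",
]

ARMS = ("conventional", "texture", "texture_l2", "texture_l2_lof")
_METRICS = ("roc_auc", "pr_auc", "sensitivity", "specificity")


@dataclass(frozen=True)
class LOFConfig:
    k: int = 5
    metric: str = "squared_euclidean"
    variant: str = "reachability"
    fit_scope: str = "normal_only"
    include_textures: bool = False


@dataclass
class ExperimentConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    manifest: str | None = None  # user-supplied cohort; overrides `cohort`
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    explicit_counts: dict[int, tuple[int, int, int]] | None = None
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    head: L2HeadConfig = field(default_factory=L2HeadConfig)
    lof: LOFConfig = field(default_factory=LOFConfig)
    arms: tuple[str, ...] = ARMS
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_bootstrap: int = 1000

    def __post_init__(self):
        if not self.arms:
            raise ValueError("at least one ablation arm is required")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arms: {sorted(unknown)}")

    # -- YAML round-trip ----------------------------------------------------
    def to_yaml(self, path: str | None = None) -> str:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        text = yaml.safe_dump(plain(dataclasses.asdict(self)), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        def tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x

        kwargs = dict(raw)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        if "augment" in kwargs and isinstance(kwargs["augment"], dict):
            aug = dict(kwargs["augment"])
            for key in ("erase_area_range", "erase_aspect_range"):
                if key in aug:
                    aug[key] = tup(aug[key])
            kwargs["augment"] = AugmentConfig(**aug)
        if "training" in kwargs and isinstance(kwargs["training"], dict):
            kwargs["training"] = TrainingConfig(**kwargs["training"])
        if "head" in kwargs and isinstance(kwargs["head"], dict):
            kwargs["head"] = L2HeadConfig(**kwargs["head"])
        if "lof" in kwargs and isinstance(kwargs["lof"], dict):
            kwargs["lof"] = LOFConfig(**kwargs["lof"])
        if "explicit_counts" in kwargs and kwargs["explicit_counts"]:
            kwargs["explicit_counts"] = {int(k): tuple(v)
                                         for k, v in kwargs["explicit_counts"].items()}
        for key in ("split_fractions", "arms", "seeds"):
            if key in kwargs:
                kwargs[key] = tup(kwargs[key])
        return cls(**kwargs)


def _texture_to_pseudo_color(tex: TextureImage, size: int) -> PseudoColorImage:
    """Auxiliary textures enter the network in the same channel layout as
    cohort images (R = 0): the texture fills B and G."""
    img = tex.image
    if min(img.shape[:2]) < size:
        img = resize_to_input(img, size)
    img = center_crop(img, size)
    case = GrayscalePairCase(tex.source_id, img, img, 0)
    fused = fuse_pseudo_color(case)
    return PseudoColorImage(fused.pixels, tex.source_id, TEXTURE_CLASS)


def prepare_inputs(config: ExperimentConfig, seed: int
                   ) -> tuple[dict[str, list[PseudoColorImage]], list[PseudoColorImage]]:
    """Generate (or load) the cohort, fuse pseudo-color inputs, resize to
    the network input size and apply the stratified split."""
    size = config.training.input_size
    if config.manifest is not None:
        from .imaging import read_manifest
        cases = read_manifest(config.manifest)
        textures = []
    else:
        spec = dataclasses.replace(config.cohort, seed=seed)
        cases = generate_cohort(spec)
        textures = generate_texture_library(spec.n_textures, size=max(size, 128),
                                            seed=seed + 1)
    split = stratified_split(cases, config.split_fractions, seed=seed,
                             explicit_counts=config.explicit_counts)
    fused = {}
    for case in cases:
        img = fuse_pseudo_color(case)
        fused[case.case_id] = PseudoColorImage(resize_to_input(img.pixels, size),
                                               case.case_id, case.label)
    splits = {name: [fused[cid] for cid in getattr(split, name)]
              for name in ("train", "val", "test")}
    tex_images = [_texture_to_pseudo_color(t, size) for t in textures]
    return splits, tex_images


def run_arm(arm: str, splits: dict[str, list[PseudoColorImage]],
            textures: list[PseudoColorImage], config: ExperimentConfig,
            seed: int) -> EvalReport:
    """Train and evaluate one ablation arm; returns the test-set report."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    for name in ("train", "val", "test"):
        if not splits.get(name):
            raise ValueError(f"missing {name} split")

    if arm == "conventional":
        head = L2HeadConfig(alpha=config.head.alpha, n_classes=2, constrained=False)
        arm_textures: list[PseudoColorImage] = []
    elif arm == "texture":
        head = L2HeadConfig(alpha=config.head.alpha, n_classes=3, constrained=False)
        arm_textures = textures
    else:
        head = dataclasses.replace(config.head, n_classes=3, constrained=True)
        arm_textures = textures

    tcfg = dataclasses.replace(config.training, seed=seed)
    model = build_model(tcfg, head)
    aug = dataclasses.replace(config.augment, seed=seed)
    trained = train(model, splits["train"], splits["val"], arm_textures, aug, tcfg)

    test = splits["test"]
    labels = np.array([c.label for c in test])
    ids = tuple(c.case_id for c in test)
    if arm == "texture_l2_lof":
        train_desc = extract_features(trained, splits["train"])
        lof_model = anomaly.fit(train_desc, k=config.lof.k, metric=config.lof.metric,
                                variant=config.lof.variant, fit_scope=config.lof.fit_scope,
                                include_textures=config.lof.include_textures)
        test_desc = extract_features(trained, test)
        scores = np.array([s.lof for s in anomaly.score(lof_model, test_desc)])
    else:
        probs = predict_softmax(trained, test)
        scores = binary_score(probs)
    scored = ScoredLabelSet(scores, labels, ids)
    return build_report(scored, n_boot=config.n_bootstrap, seed=seed)


@dataclass
class AblationReport:
    """Per-arm, per-seed evaluation reports plus per-arm medians."""

    reports: dict[str, dict[int, EvalReport]]
    medians: dict[str, dict[str, float]]
    config_yaml: str

    def to_dict(self) -> dict:
        return {
            "reports": {arm: {str(seed): r.to_dict() for seed, r in by_seed.items()}
                        for arm, by_seed in self.reports.items()},
            "medians": self.medians,
            "config_yaml": self.config_yaml,
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_experiment(config: ExperimentConfig, outdir: str | None = None,
                   progress=None) -> AblationReport:
    """Run every requested arm over every seed and aggregate medians.

    When ``outdir`` is given, each per-arm/per-seed report is persisted as
    it completes (partial results survive a failure), followed by the
    aggregate ``report.json`` and the config snapshot.
    """
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        config.to_yaml(os.path.join(outdir, "experiment.yaml"))
    reports: dict[str, dict[int, EvalReport]] = {arm: {} for arm in config.arms}
    for seed in config.seeds:
        splits, textures = prepare_inputs(config, seed)
        for arm in config.arms:
            report = run_arm(arm, splits, textures, config, seed)
            reports[arm][seed] = report
            if progress is not None:
                progress(arm, seed, report)
            if outdir is not None:
                report.to_json(os.path.join(outdir, f"report_{arm}_seed{seed}.json"))
    medians = {
        arm: {m: float(np.median([getattr(r, m) for r in by_seed.values()]))
              for m in _METRICS}
        for arm, by_seed in reports.items()
    }
    out = AblationReport(reports, medians, config.to_yaml())
    if outdir is not None:
        out.to_json(os.path.join(outdir, "report.json"))
    return out


def default_benchmark_config() -> ExperimentConfig:
    """Scaled-down end-to-end benchmark on the synthetic cohort.

    Mirrors the reference cohort's size and imbalance (190 normal / 55
    abnormal at 100 x 100) with the small CPU backbone: 15 epochs of
    Adam at 1e-3 (a from-scratch rate; the reference 1e-5 is a
    fine-tuning rate for a pretrained backbone) and two arms at the ends
    of the ablation ladder.
    """
    return ExperimentConfig(
        cohort=CohortSpec(),
        training=TrainingConfig(learning_rate=1e-3, max_epochs=15,
                                early_stop_patience=15, backbone="tiny_cnn"),
        arms=("conventional", "texture_l2_lof"),
        seeds=(0, 1, 2, 3, 4),
        n_bootstrap=500,
    )
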