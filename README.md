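# deeplof

Anomaly detection on deep features for small, imbalanced paired-image
cohorts — e.g. discriminating rare malignant tumours from common benign
ones on cropped MR images when only a few hundred cases exist.

Rare-disease imaging datasets break the usual two-class deep-learning
recipe twice over: the abnormal class is both scarce and internally
heterogeneous, so a softmax classifier starves and overfits. `deeplof`
implements a two-stage alternative:

1. **Feature learning.** A convolutional network is trained as a
   *three*-class classifier — normal (0), abnormal (1) and an auxiliary
   non-medical texture class (2) that regularizes feature extraction —
   with the **L2-constrained softmax loss**

   minimize −(1/M) Σᵢ log softmax(Wᵀ f(xᵢ) + b)[yᵢ]   subject to ‖f(xᵢ)‖₂ = α,

   which places every feature descriptor f(xᵢ) on a hypersphere of
   radius α (default α = 80) so that classes separate by direction
   (cosine similarity) rather than magnitude. Inputs are pseudo-color
   fusions of two registered grayscale contrasts (blue = T1-role,
   green = T2-role, red empty), resized to 100 × 100.

2. **Anomaly scoring.** The penultimate-layer descriptors of the
   *normal* training cases form a reference set for the **Local Outlier
   Factor**: with N_k(p) the k-distance neighborhood and lrd(p) the
   local (reachability) density,

   LOF(p) = ( Σ_{q∈N_k(p)} lrd(q)/lrd(p) ) / |N_k(p)|,

   computed by brute-force search with squared-Euclidean distance and
   k = 5. LOF ≈ 1 inside the normal cloud and grows for outliers; a
   Youden-index threshold turns scores into normal/abnormal calls.

Evaluation follows the standard protocol for this setting: ROC-AUC and
PR-AUC (average precision), sensitivity/specificity at the Youden point,
bootstrap 95% CIs and the DeLong CI for ROC-AUC, plus a four-arm
ablation ladder (conventional softmax → + textures → + L2 loss →
+ LOF).

Because real cohorts of this kind are private, the package ships a
first-class synthetic-data module that emulates their statistical
structure — a numerous, low-diversity normal class, a rare,
high-diversity abnormal class, two correlated contrasts per case, and a
procedural texture library — at configurable counts and imbalance. The
neural-network stage (conv/pool/dense layers, the L2-constraint layer,
reverse-mode gradients, Adam) is implemented in numpy and validated
against finite differences; it trains the default small backbone on a
CPU in seconds per epoch.

## Worked example

```python
import numpy as np
from deeplof import (CohortSpec, ExperimentConfig, TrainingConfig,
                     prepare_inputs, run_arm)

cfg = ExperimentConfig(
    cohort=CohortSpec(n_normal=40, n_abnormal=14, n_textures=10, image_size=48),
    training=TrainingConfig(learning_rate=1e-3, max_epochs=6,
                            early_stop_patience=6, input_size=48),
    arms=("conventional", "texture_l2_lof"), seeds=(0,), n_bootstrap=200)

splits, textures = prepare_inputs(cfg, seed=0)
for arm in cfg.arms:
    r = run_arm(arm, splits, textures, cfg, seed=0)
    print(f"{arm:16s} ROC-AUC {r.roc_auc:.3f}  PR-AUC {r.pr_auc:.3f} "
          f"sens {r.sensitivity:.2f}  spec {r.specificity:.2f}")
```

prints

```
conventional     ROC-AUC 0.250  PR-AUC 0.269 sens 0.33  spec 0.75
texture_l2_lof   ROC-AUC 1.000  PR-AUC 1.000 sens 1.00  spec 1.00
```

On this 54-case cohort the conventional two-class softmax cannot learn
the rare class (ROC-AUC below chance on the 11-case test set), while
LOF scoring of the L2-constrained descriptors separates the test set
perfectly — the ordering the method is designed to produce. The worked
LOF arithmetic is easy to check by hand: for references {0, 10, 20, 30,
40} on a line with k = 2 and squared distances, an interior point scores
LOF(20) = 1.0 and a far query LOF(100) = 29.75.

A shell workflow is available through the `deeplof` CLI
(`generate`, `split`, `train`, `extract`, `score`, `evaluate`,
`experiment`); see `--help` on each subcommand.

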