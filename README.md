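# maft — multi-modal adaptive-fusion transformer for depression-level estimation

`maft` estimates a subject's PHQ-8 depression score (an integer in
[0, 24]) from frame-level audiovisual feature streams of the kind
exported by openSMILE and openFace: per subject, one numeric matrix
`t × d` per feature type (MFCC, eGeMAPS, facial action units, deep
representations, ...), with `t` ranging from hundreds to tens of
thousands of frames.  It is aimed at affective-computing researchers who
work with AVEC-style interview corpora and want a reproducible
train-and-fuse pipeline with a synthetic stand-in cohort for testing.

## Method

For every feature type an independent **transformer encoder** is trained
to regress the PHQ-8 score:

- long sequences are shortened to a budget of `N` frames by **segment
  sampling**: the sequence is split evenly into `s` segments and a run of
  `L = N/s` successive frames is drawn at random from each (`N = 2048`
  for low/middle-level features, `720` for high-level, by default);
- the encoder is the classic post-norm stack — sinusoidal positional
  encoding, `N_enc` layers of scaled dot-product self-attention
  `Z = softmax(QKᵀ/√d_k)V` plus a two-layer feed-forward block, each with
  residual connection and layer normalization — followed by temporal
  averaging and an embedding FC block (ReLU → dropout → linear);
- two task heads share the embedding: a **regression head** trained with
  the concordance-correlation loss `L_re = 1 − CCC(ŷ, y)`, where
  `CCC = 2·S_ŷy / (S_ŷ² + S_y² + (ȳ̂ − ȳ)²)` (Lin's coefficient,
  population moments), and an auxiliary **5-class severity head**
  (minimal / mild / moderate / moderately severe / severe, cut-points at
  0, 5, 10, 15, 20) trained with cross-entropy `L_cl`; the joint loss is
  `Loss = a·L_re + b·L_cl` with `(a, b) = (0.9, 0.1)` for multi-task and
  `(1.0, 0.0)` for single-task training.

Per-feature dev-set predictions are then combined by **adaptive late
fusion**: each feature's predictions are weighted by its validation CCC,

    w_m = CCC_m / Σ_m CCC_m ,   ŷ_fused = Σ_m w_m · ŷ_m ,

(negative CCCs clamped to zero), optionally restricted to the top-M
features by CCC.  Plain averaged fusion is provided as the baseline.

Because clinical interview corpora are access-restricted, the package
ships a synthetic cohort generator: AR(1) feature streams whose means
shift linearly with a latent severity drawn from a skewed-low score
distribution, with a per-feature signal strength (including pure-noise
streams) — enough structure to exercise and validate every stage.

## Worked example

Train all three default synthetic feature streams at toy scale (2 encoder
layers, 64-frame budget, 200 epochs; ~15 s) and fuse:

```python
import numpy as np
from maft import (CohortSpec, EncoderConfig, LossWeights, SamplingSpec,
                  TrainConfig, adaptive_fusion, averaged_fusion, ccc,
                  generate_cohort, train_feature_model)

train, dev = generate_cohort(CohortSpec(seed=1))   # 40 train / 16 dev subjects
y_dev = np.array([s.phq8_score for s in dev], dtype=float)

enc = EncoderConfig(num_layers=2, num_heads=1, ff_hidden=64, embed_dim=16)
cfg = TrainConfig(learning_rate=3e-3, batch_size=48, epochs=200,
                  loss_weights=LossWeights(a=0.9, b=0.1), seed=1)
sampling = SamplingSpec(n_frames=64, segments=8, seed=1)

preds = []
for name in ("acoustic_strong", "visual_medium", "noise_stream"):
    _, pred = train_feature_model(train, dev, name, enc, cfg, sampling)
    preds.append(pred)
    print(f"{name:<16} dev CCC {pred.validation_ccc:+.3f}  RMSE {pred.validation_rmse:.2f}")

fused = adaptive_fusion(preds)
print("adaptive weights:", {k: round(v, 3) for k, v in fused.weights.items()})
print(f"adaptive fusion  dev CCC {ccc(y_dev, fused.fused_scores):+.3f}")
print(f"averaged fusion  dev CCC {ccc(y_dev, averaged_fusion(preds).fused_scores):+.3f}")
```

Output:

```
acoustic_strong  dev CCC +0.953  RMSE 1.94
visual_medium    dev CCC +0.855  RMSE 3.59
noise_stream     dev CCC +0.004  RMSE 11.41
adaptive weights: {'acoustic_strong': 0.526, 'visual_medium': 0.472, 'noise_stream': 0.002}
adaptive fusion  dev CCC +0.959
averaged fusion  dev CCC +0.715
```

The strongly informative stream recovers severity almost perfectly, the
pure-noise stream sits at the null, and adaptive fusion — which gives the
noise stream weight 0.002 instead of 1/3 — beats plain averaging by a
wide margin.  The same pipeline is available from the shell:

```
maft synth --out cohort/ --seed 1
maft pipeline --config run.yaml
maft report --run out/
```

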