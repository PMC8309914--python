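"""Shared fixtures: toy-scale model/training settings and the seeded
multi-replicate study used by the slower end-to-end tests.

The toy operating point (2 encoder layers, 64-frame budget, Adam at 3e-3
for 200 epochs on the default 40/16 cohort) is the package's desk-scale
study condition; the replicate study trains all three default feature
streams under it for five cohort seeds and caches the per-feature dev
CCCs plus both fusion results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from maft.fusion import adaptive_fusion, averaged_fusion
from maft.losses import LossWeights, ccc
from maft.preprocess import SamplingSpec
from maft.synthetic import CohortSpec, generate_cohort
from maft.training import TrainConfig, train_feature_model
from maft.transformer import EncoderConfig

TOY_FEATURES = ("acoustic_strong", "visual_medium", "noise_stream")
TOY_LR = 3e-3
TOY_EPOCHS = 200
N_REPLICATES = 5


def toy_encoder_config(**overrides) -> EncoderConfig:
    base = dict(num_layers=2, num_heads=1, ff_hidden=64, embed_dim=16, dropout=0.1)
    base.update(overrides)
    return EncoderConfig(**base)


def toy_train_config(seed: int, **overrides) -> TrainConfig:
    base = dict(
        learning_rate=TOY_LR,
        batch_size=48,
        epochs=TOY_EPOCHS,
        loss_weights=LossWeights(0.9, 0.1),
        seed=seed,
        eval_every=10,
    )
    base.update(overrides)
    return TrainConfig(**base)


def toy_sampling(seed: int) -> SamplingSpec:
    return SamplingSpec(n_frames=64, segments=8, seed=seed)


@dataclass
class Replicate:
    seed: int
    feature_ccc: dict[str, float]
    adaptive_ccc: float
    averaged_ccc: float


@pytest.fixture(scope="session")
def replicate_study() -> list[Replicate]:
    """Train all default feature streams for five cohort seeds and fuse."""
    out = []
    for seed in range(N_REPLICATES):
        train, dev = generate_cohort(CohortSpec(seed=seed))
        y_dev = np.array([s.phq8_score for s in dev], dtype=float)
        preds = []
        for feat in TOY_FEATURES:
            _, pred = train_feature_model(
                train, dev, feat,
                enc_cfg=toy_encoder_config(),
                train_cfg=toy_train_config(seed),
                sampling=toy_sampling(seed),
            )
            preds.append(pred)
        adaptive = adaptive_fusion(preds)
        averaged = averaged_fusion(preds)
        out.append(
            Replicate(
                seed=seed,
                feature_ccc={p.feature_name: p.validation_ccc for p in preds},
                adaptive_ccc=ccc(y_dev, adaptive.fused_scores),
                averaged_ccc=ccc(y_dev, averaged.fused_scores),
            )
        )
    return out
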