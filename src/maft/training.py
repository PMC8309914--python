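"""Per-feature model training and out-of-sample evaluation.

One encoder is trained independently per feature stream.  Each epoch the
frame subsequences are redrawn by segment sampling (acting as a mild data
augmentation; a flag freezes the draw), standardized with statistics
frozen on the training split, and fed through the model in minibatches;
Adam minimizes ``a * (1 - CCC) + b * cross-entropy``.  The development
split is sampled once with a fixed seed, so dev evaluation is
deterministic; the parameters with the best dev CCC are retained.

The result of a training run is a :class:`PredictionSet`: out-of-sample
PHQ-8 predictions and class probabilities for the dev subjects, tagged
with the dev CCC that later drives adaptive fusion weighting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Adam
from .data_io import FeatureLevel, SubjectRecord, subjects_with_feature
from .losses import LossWeights, ccc, multitask_loss_t, rmse
from .preprocess import SamplingSpec, Standardizer, segment_sample
from .transformer import DepressionTransformer, EncoderConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the reference operating point: Adam at learning rate
    1e-5, batch 48 and 500 epochs for low/middle-level features (24 and
    200 for high-level), loss weights (0.9, 0.1) for multi-task or
    (1.0, 0.0) for single-task.  Toy-scale runs override these.
    """

    learning_rate: float = 1e-5
    batch_size: int = 48
    epochs: int = 500
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    eval_every: int = 10
    resample_each_epoch: bool = True
    normalize: bool = True
    keep_best: bool = True  # retain the best-dev-CCC checkpoint

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")

    @classmethod
    def for_level(cls, level: FeatureLevel, **overrides) -> "TrainConfig":
        """Level-dependent defaults: high-level features train with batch 24
        for 200 epochs, low/middle with batch 48 for 500."""
        if FeatureLevel(level) is FeatureLevel.HIGH:
            base = cls(batch_size=24, epochs=200)
        else:
            base = cls(batch_size=48, epochs=500)
        return replace(base, **overrides)


@dataclass
class PredictionSet:
    """Out-of-sample predictions of one feature model over a subject set."""

    feature_name: str
    subject_ids: list[str]
    scores: np.ndarray  # predicted PHQ-8, (n,)
    class_probs: np.ndarray  # (n, 5)
    validation_ccc: float
    validation_rmse: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.class_probs = np.asarray(self.class_probs, dtype=np.float64)
        n = len(self.subject_ids)
        if self.scores.shape != (n,) or self.class_probs.shape[0] != n:
            raise ValueError("prediction lengths do not match subject ids")
        if not -1.0 <= self.validation_ccc <= 1.0:
            raise ValueError("validation_ccc outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_ids,
                           "prediction": self.scores})
        for c in range(self.class_probs.shape[1]):
            df[f"class_probs_{c}"] = self.class_probs[:, c]
        return df

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / f"{self.feature_name}.csv", index=False)
        meta = {
            "feature_name": self.feature_name,
            "validation_ccc": self.validation_ccc,
            "validation_rmse": self.validation_rmse,
        }
        (directory / f"{self.feature_name}.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path, feature_name: str) -> "PredictionSet":
        directory = Path(directory)
        df = pd.read_csv(directory / f"{feature_name}.csv")
        meta = json.loads((directory / f"{feature_name}.json").read_text())
        prob_cols = sorted(c for c in df.columns if c.startswith("class_probs_"))
        return cls(
            feature_name=meta["feature_name"],
            subject_ids=[str(s) for s in df["subject_id"]],
            scores=df["prediction"].to_numpy(),
            class_probs=df[prob_cols].to_numpy(),
            validation_ccc=meta["validation_ccc"],
            validation_rmse=meta["validation_rmse"],
        )


@dataclass
class Checkpoint:
    """Serialized model + the preprocessing statistics it was trained with."""

    feature_name: str
    state: dict
    sampling: SamplingSpec
    standardizer: Standardizer | None

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_name": self.feature_name,
            "state": self.state,
            "sampling": {
                "n_frames": self.sampling.n_frames,
                "segments": self.sampling.segments,
                "seed": self.sampling.seed,
                "pad_short": self.sampling.pad_short,
            },
        }
        if self.standardizer is not None:
            payload["norm_mean"] = self.standardizer.mean
            payload["norm_std"] = self.standardizer.std
        np.savez(path, blob=np.frombuffer(
            json.dumps(_jsonify(payload)).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as npz:
            payload = json.loads(npz["blob"].tobytes().decode())
        state = payload["state"]
        state["params"] = [np.asarray(p) for p in state["params"]]
        std = None
        if "norm_mean" in payload:
            std = Standardizer(
                mean=np.asarray(payload["norm_mean"]),
                std=np.asarray(payload["norm_std"]),
            )
        return cls(
            feature_name=payload["feature_name"],
            state=state,
            sampling=SamplingSpec(**payload["sampling"]),
            standardizer=std,
        )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _sample_batch(
    subjects: list[SubjectRecord],
    feature_name: str,
    sampling: SamplingSpec,
    rng: np.random.Generator,
    standardizer: Standardizer | None,
) -> np.ndarray:
    """Stack per-subject segment-sampled (and standardized) frame blocks."""
    seqs = []
    for s in subjects:
        seq = segment_sample(s.features[feature_name], sampling, rng=rng)
        if standardizer is not None:
            seq = standardizer.transform(seq)
        seqs.append(seq.frames)
    return np.stack(seqs)


def train_feature_model(
    train: list[SubjectRecord],
    dev: list[SubjectRecord],
    feature_name: str,
    enc_cfg: EncoderConfig,
    train_cfg: TrainConfig,
    sampling: SamplingSpec,
) -> tuple[Checkpoint, PredictionSet]:
    """Train one encoder on ``feature_name`` and evaluate on the dev split.

    Returns the (best-dev-CCC) checkpoint and the dev-split
    :class:`PredictionSet` carrying the validation CCC/RMSE that adaptive
    fusion will consume.
    """
    train = subjects_with_feature(train, feature_name)
    dev = subjects_with_feature(dev, feature_name)
    if not train or not dev:
        raise ValueError(f"feature {feature_name!r} missing from train or dev split")

    y_train = np.array([s.phq8_score for s in train], dtype=np.float64)
    cls_train = np.array([s.severity_class for s in train], dtype=int)
    y_dev = np.array([s.phq8_score for s in dev], dtype=np.float64)

    rng = np.random.default_rng(train_cfg.seed)
    base_seed = int(rng.integers(0, 2**31 - 1))

    # Normalization statistics frozen on one deterministic draw of the train split
    standardizer = None
    if train_cfg.normalize:
        frozen = [
            segment_sample(s.features[feature_name], sampling,
                           rng=np.random.default_rng(base_seed))
            for s in train
        ]
        standardizer = Standardizer.fit(frozen)

    # Dev inputs are sampled once, deterministically
    x_dev = _sample_batch(dev, feature_name, sampling,
                          np.random.default_rng(base_seed + 1), standardizer)

    input_dim = train[0].features[feature_name].d
    model = DepressionTransformer(input_dim, enc_cfg, seed=train_cfg.seed)
    optimizer = Adam(model.params(), lr=train_cfg.learning_rate)

    frozen_train = None
    if not train_cfg.resample_each_epoch:
        frozen_train = _sample_batch(train, feature_name, sampling,
                                     np.random.default_rng(base_seed + 2),
                                     standardizer)

    n = len(train)
    best_ccc = -np.inf
    best_state = None
    loss_log: list[float] = []
    for epoch in range(train_cfg.epochs):
        if frozen_train is None:
            x_train = _sample_batch(train, feature_name, sampling,
                                    np.random.default_rng(base_seed + 3 + epoch),
                                    standardizer)
        else:
            x_train = frozen_train
        order = np.random.default_rng(base_seed + 5000 + epoch).permutation(n)
        epoch_losses = []
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo : lo + train_cfg.batch_size]
            if len(idx) < 2:
                continue  # batch CCC needs at least two subjects
            scores, logits = model.forward(x_train[idx], train=True)
            loss = multitask_loss_t(scores, y_train[idx], logits, cls_train[idx],
                                    train_cfg.loss_weights)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(feature {feature_name!r})"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        loss_log.append(float(np.mean(epoch_losses)))

        last = epoch == train_cfg.epochs - 1
        if train_cfg.keep_best and (epoch % train_cfg.eval_every == 0 or last):
            dev_scores, _ = model.predict(x_dev)
            dev_ccc = ccc(y_dev, dev_scores, on_degenerate="one")
            if dev_ccc > best_ccc:
                best_ccc = dev_ccc
                best_state = model.state_dict()

    if train_cfg.keep_best and best_state is not None:
        model.load_state_dict(best_state)
    logger.info(
        "feature %r: trained %d epochs, first-epoch loss %.4f, last %.4f",
        feature_name, train_cfg.epochs, loss_log[0], loss_log[-1],
    )

    checkpoint = Checkpoint(
        feature_name=feature_name,
        state=model.state_dict(),
        sampling=sampling,
        standardizer=standardizer,
    )
    pred_set = evaluate(checkpoint, dev, feature_name, eval_seed=base_seed + 1)
    pred_set.loss_log = loss_log  # type: ignore[attr-defined]
    return checkpoint, pred_set


def evaluate(
    checkpoint: Checkpoint,
    subjects: list[SubjectRecord],
    feature_name: str,
    eval_seed: int = 0,
) -> PredictionSet:
    """Deterministic eval-mode predictions + metrics for ``subjects``."""
    subjects = subjects_with_feature(subjects, feature_name)
    if not subjects:
        raise ValueError(f"no subjects carry feature {feature_name!r}")
    model = DepressionTransformer.from_state_dict(checkpoint.state)
    dims = {s.features[feature_name].d for s in subjects}
    if dims != {model.input_dim}:
        raise ValueError(
            f"feature dimension mismatch: checkpoint expects {model.input_dim}, "
            f"subjects have {sorted(dims)}"
        )
    x = _sample_batch(subjects, feature_name, checkpoint.sampling,
                      np.random.default_rng(eval_seed), checkpoint.standardizer)
    scores, probs = model.predict(x)
    y = np.array([s.phq8_score for s in subjects], dtype=np.float64)
    return PredictionSet(
        feature_name=feature_name,
        subject_ids=[s.subject_id for s in subjects],
        scores=scores,
        class_probs=probs,
        validation_ccc=ccc(y, scores, on_degenerate="one"),
        validation_rmse=rmse(y, scores),
    )
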