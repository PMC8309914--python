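"""End-to-end run configuration and orchestration.

A run is described by a single structured config (YAML on disk): cohort
location, feature streams with their levels, sampling budgets, encoder
and optimizer hyperparameters, and the fusion strategy.  ``run_pipeline``
executes the two-phase design — train one encoder per feature stream,
then fuse the per-feature dev predictions at the decision level — and
writes every artifact (checkpoints, prediction sets, fused scores,
weight table, metrics JSON and the resolved config echo) to the output
directory.  Every random draw derives from the single run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .data_io import FeatureLevel
from .fusion import fuse
from .losses import LossWeights
from .preprocess import DEFAULT_N_HIGH, DEFAULT_N_LOW_MID, SamplingSpec
from .synthetic import read_cohort
from .training import TrainConfig, train_feature_model
from .transformer import EncoderConfig

logger = logging.getLogger(__name__)

#: Loss-weight presets.
MULTI_TASK_WEIGHTS = LossWeights(a=0.9, b=0.1)
SINGLE_TASK_WEIGHTS = LossWeights(a=1.0, b=0.0)

DEFAULT_SEGMENTS = 32


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown {section} config keys: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    data_dir: str
    out_dir: str
    features: dict[str, str]  # feature name -> level
    seed: int = 0
    n_low_mid: int = DEFAULT_N_LOW_MID
    n_high: int = DEFAULT_N_HIGH
    segments: int = DEFAULT_SEGMENTS
    normalize: bool = True
    multitask: bool = True
    encoder: dict = field(default_factory=dict)  # EncoderConfig overrides
    training: dict = field(default_factory=dict)  # TrainConfig overrides
    strategy: str = "adaptive"
    top_m: int | None = None

    _TOP = {"data_dir", "out_dir", "features", "seed", "sampling", "normalize",
            "multitask", "encoder", "training", "fusion"}
    _SAMPLING = {"n_low_mid", "n_high", "segments"}
    _ENCODER = {"num_layers", "num_heads", "ff_hidden", "d_model", "embed_dim",
                "dropout"}
    _TRAINING = {"learning_rate", "batch_size", "epochs", "eval_every",
                 "resample_each_epoch", "keep_best"}
    _FUSION = {"strategy", "top_m"}

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys("top-level", raw, cls._TOP)
        for key in ("data_dir", "out_dir", "features"):
            if key not in raw:
                raise ConfigError(f"missing required config key {key!r}")
        sampling = raw.get("sampling", {})
        _check_keys("sampling", sampling, cls._SAMPLING)
        encoder = raw.get("encoder", {})
        _check_keys("encoder", encoder, cls._ENCODER)
        training = raw.get("training", {})
        _check_keys("training", training, cls._TRAINING)
        fusion_cfg = raw.get("fusion", {})
        _check_keys("fusion", fusion_cfg, cls._FUSION)
        features = {str(k): str(FeatureLevel(v).value)
                    for k, v in raw["features"].items()}
        cfg = cls(
            data_dir=str(raw["data_dir"]),
            out_dir=str(raw["out_dir"]),
            features=features,
            seed=int(raw.get("seed", 0)),
            n_low_mid=int(sampling.get("n_low_mid", DEFAULT_N_LOW_MID)),
            n_high=int(sampling.get("n_high", DEFAULT_N_HIGH)),
            segments=int(sampling.get("segments", DEFAULT_SEGMENTS)),
            normalize=bool(raw.get("normalize", True)),
            multitask=bool(raw.get("multitask", True)),
            encoder=dict(encoder),
            training=dict(training),
            strategy=str(fusion_cfg.get("strategy", "adaptive")),
            top_m=fusion_cfg.get("top_m"),
        )
        if cfg.strategy not in ("averaged", "adaptive"):
            raise ConfigError(f"unknown fusion strategy {cfg.strategy!r}")
        # fail fast on invalid hyperparameters
        cfg.encoder_config()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sampling"] = {"n_low_mid": d.pop("n_low_mid"),
                         "n_high": d.pop("n_high"),
                         "segments": d.pop("segments")}
        d["fusion"] = {"strategy": d.pop("strategy"), "top_m": d.pop("top_m")}
        return d

    # -- derived objects -----------------------------------------------------

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(**self.encoder)

    def sampling_spec(self, level: FeatureLevel | str, seed: int) -> SamplingSpec:
        n = (self.n_high if FeatureLevel(level) is FeatureLevel.HIGH
             else self.n_low_mid)
        return SamplingSpec(n_frames=n, segments=min(self.segments, n), seed=seed)

    def train_config(self, level: FeatureLevel | str, seed: int) -> TrainConfig:
        weights = MULTI_TASK_WEIGHTS if self.multitask else SINGLE_TASK_WEIGHTS
        return TrainConfig.for_level(
            level, loss_weights=weights, seed=seed, **self.training
        )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute train-then-fuse end to end; returns the metrics dict.

    Artifacts written to ``cfg.out_dir``: ``config.yaml`` (resolved echo),
    per-feature ``<name>.npz`` checkpoints and ``<name>.csv/.json``
    prediction sets under ``predictions/``, ``fused.csv``, ``weights.csv``
    and ``metrics.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))

    train_split, dev_split = read_cohort(cfg.data_dir, cfg.features)
    logger.info("cohort: %d train / %d dev subjects, %d feature stream(s)",
                len(train_split), len(dev_split), len(cfg.features))

    pred_dir = out / "predictions"
    preds = []
    metrics: dict[str, dict] = {}
    for offset, (name, level) in enumerate(sorted(cfg.features.items())):
        feature_seed = cfg.seed * 1000 + offset
        checkpoint, pred = train_feature_model(
            train_split, dev_split, name,
            enc_cfg=cfg.encoder_config(),
            train_cfg=cfg.train_config(level, feature_seed),
            sampling=cfg.sampling_spec(level, feature_seed),
        )
        checkpoint.save(out / f"{name}.npz")
        pred.save(pred_dir)
        preds.append(pred)
        metrics[name] = {"ccc": pred.validation_ccc, "rmse": pred.validation_rmse}
        logger.info("feature %r: dev CCC %.3f, RMSE %.3f",
                    name, pred.validation_ccc, pred.validation_rmse)

    result = fuse(preds, strategy=cfg.strategy, top_m=cfg.top_m)
    result.to_frame().to_csv(out / "fused.csv", index=False)
    result.weight_table(preds).to_csv(out / "weights.csv", index=False)

    import numpy as np

    from .losses import ccc, rmse

    y = {s.subject_id: float(s.phq8_score) for s in dev_split}
    y_dev = np.array([y[sid] for sid in result.subject_ids])
    metrics["fused"] = {
        "ccc": ccc(y_dev, result.fused_scores, on_degenerate="one"),
        "rmse": rmse(y_dev, result.fused_scores),
        "strategy": result.strategy,
        "m": result.m,
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return metrics
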