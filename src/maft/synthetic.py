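"""Synthetic multi-modal cohort generator with a planted severity signal.

Real interview corpora with clinical labels are access-restricted, so the
package ships a generator that emulates their statistical shape: per
subject a latent PHQ-8 severity in [0, 24] drawn from a skewed-low
histogram (most subjects minimal/mild, few severe — the class imbalance
typical of screening cohorts), and per feature type an AR(1) frame
sequence whose per-dimension mean shifts linearly with severity:

    x_t = signal_strength * (score / 24) * u + e_t,
    e_t = ar * e_{t-1} + sqrt(1 - ar^2) * noise_sd * w_t,

with ``u`` a fixed unit direction per feature and ``w_t`` i.i.d. standard
normal.  ``signal_strength`` controls how recoverable severity is from
the stream (0 gives exchangeable pure noise), ``noise_sd`` the frame-level
noise floor, and ``ar`` the temporal smoothness that gives segment
sampling something to preserve.  Feature types differ in dimension and
length, mirroring the heterogeneity of low- vs high-level descriptors.

Everything is deterministic under the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (
    FeatureLevel,
    FeatureSequence,
    LabelTable,
    SubjectRecord,
    read_feature_csv,
    read_label_table,
    write_feature_csv,
    write_label_table,
)

#: Severity-class weights of the default score histogram (minimal ... severe),
#: matching the skewed-low imbalance of screening cohorts.
DEFAULT_CLASS_WEIGHTS = (77, 36, 26, 17, 7)


@dataclass(frozen=True)
class FeatureSpec:
    """Shape and signal parameters of one synthetic feature stream."""

    name: str
    level: FeatureLevel
    dim: int
    t_range: tuple[int, int]  # inclusive frame-count range
    signal_strength: float = 0.5  # in [0, 1]
    noise_sd: float = 0.3
    ar: float = 0.8  # temporal autocorrelation, in [0, 1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", FeatureLevel(self.level))
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if not 0.0 <= self.ar < 1.0:
            raise ValueError("ar must lie in [0, 1)")
        if self.dim < 1 or self.t_range[0] < 1 or self.t_range[1] < self.t_range[0]:
            raise ValueError("invalid dimension or frame-count range")


def default_feature_specs() -> list[FeatureSpec]:
    """Three streams spanning the informative-to-useless range: a strongly
    informative dense stream, a moderately informative one, and a pure-noise
    stream that a robust fusion rule must learn to ignore."""
    return [
        FeatureSpec("acoustic_strong", FeatureLevel.LOW, dim=8,
                    t_range=(400, 800), signal_strength=0.9),
        FeatureSpec("visual_medium", FeatureLevel.LOW, dim=8,
                    t_range=(400, 800), signal_strength=0.45),
        FeatureSpec("noise_stream", FeatureLevel.LOW, dim=8,
                    t_range=(400, 800), signal_strength=0.0),
    ]


def default_score_histogram() -> np.ndarray:
    """Skewed-low distribution over PHQ-8 scores 0..24: class weights spread
    uniformly over each class's five integer scores, then normalized."""
    hist = np.repeat(np.asarray(DEFAULT_CLASS_WEIGHTS, dtype=np.float64) / 5.0, 5)
    return hist / hist.sum()


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes, score distribution and feature streams to generate."""

    n_train: int = 40
    n_dev: int = 16
    score_histogram: np.ndarray = field(default_factory=default_score_histogram)
    feature_specs: list[FeatureSpec] = field(default_factory=default_feature_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        hist = np.asarray(self.score_histogram, dtype=np.float64)
        if hist.shape != (25,) or (hist < 0).any() or hist.sum() <= 0:
            raise ValueError(
                "score_histogram must be a non-negative length-25 vector "
                "with positive mass"
            )
        object.__setattr__(self, "score_histogram", hist / hist.sum())
        if self.n_train + self.n_dev < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if not self.feature_specs:
            raise ValueError("at least one feature spec required")


def _ar1_noise(rng: np.random.Generator, t: int, d: int, sd: float, ar: float
               ) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    w = rng.standard_normal((t, d))
    e = np.empty((t, d))
    e[0] = w[0]
    scale = np.sqrt(1.0 - ar**2)
    for i in range(1, t):
        e[i] = ar * e[i - 1] + scale * w[i]
    return sd * e


def _make_subject(
    sid: str,
    score: int,
    gender: str,
    spec: CohortSpec,
    directions: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> SubjectRecord:
    features = {}
    for fs in spec.feature_specs:
        t = int(rng.integers(fs.t_range[0], fs.t_range[1] + 1))
        mean = fs.signal_strength * (score / 24.0) * directions[fs.name]
        frames = mean[None, :] + _ar1_noise(rng, t, fs.dim, fs.noise_sd, fs.ar)
        features[fs.name] = FeatureSequence(fs.name, fs.level, frames)
    return SubjectRecord(
        subject_id=sid,
        phq8_score=score,
        phq8_binary=int(score >= 10),
        gender=gender,
        features=features,
    )


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Generate disjoint train and dev subject lists, deterministic under
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    directions = {}
    for fs in spec.feature_specs:
        u = rng.standard_normal(fs.dim)
        directions[fs.name] = u / np.linalg.norm(u)
    n = spec.n_train + spec.n_dev
    scores = rng.choice(25, size=n, p=spec.score_histogram)
    genders = rng.choice(["female", "male"], size=n)
    subjects = [
        _make_subject(f"S{i:04d}", int(scores[i]), str(genders[i]),
                      spec, directions, rng)
        for i in range(n)
    ]
    return subjects[: spec.n_train], subjects[spec.n_train :]


def write_cohort(
    train: list[SubjectRecord],
    dev: list[SubjectRecord],
    directory: str | Path,
) -> None:
    """Write label CSVs and per-subject per-feature CSVs in the data_io dialect.

    Layout: ``<dir>/labels_train.csv``, ``<dir>/labels_dev.csv`` and
    ``<dir>/features/<subject_id>_<feature_name>.csv``.
    """
    import pandas as pd

    directory = Path(directory)
    (directory / "features").mkdir(parents=True, exist_ok=True)
    for split, subjects in (("train", train), ("dev", dev)):
        df = pd.DataFrame(
            {
                "Participant_ID": [s.subject_id for s in subjects],
                "PHQ8_Score": [s.phq8_score for s in subjects],
                "PHQ8_Binary": [s.phq8_binary for s in subjects],
                "Gender": [s.gender for s in subjects],
            }
        )
        write_label_table(LabelTable(frame=df), directory / f"labels_{split}.csv")
        for s in subjects:
            for name, seq in s.features.items():
                write_feature_csv(
                    seq, directory / "features" / f"{s.subject_id}_{name}.csv"
                )


def read_cohort(
    directory: str | Path,
    feature_levels: dict[str, FeatureLevel | str],
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    splits = []
    for split in ("train", "dev"):
        table = read_label_table(directory / f"labels_{split}.csv")
        subjects = []
        for row in table:
            features = {}
            for name, level in feature_levels.items():
                path = directory / "features" / f"{row.Participant_ID}_{name}.csv"
                if path.exists():
                    features[name] = read_feature_csv(path, name, level)
            subjects.append(
                SubjectRecord(
                    subject_id=row.Participant_ID,
                    phq8_score=row.PHQ8_Score,
                    phq8_binary=row.PHQ8_Binary,
                    gender=row.Gender,
                    features=features,
                )
            )
        splits.append(subjects)
    return splits[0], splits[1]
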