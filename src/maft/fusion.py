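"""Decision-level fusion of per-feature PHQ-8 predictions.

Each feature stream's model predicts a PHQ-8 score per subject; fusion
combines these into one final score.  Two strategies are provided:

* *averaged* late fusion — the plain mean over features;
* *adaptive* late fusion — a weighted mean with weight proportional to
  each feature model's validation CCC, so well-performing streams
  dominate and poor ones are down-weighted:

      w_m = CCC_m / sum_m CCC_m.

Negative validation CCCs are clamped to zero before normalization (a
negative-agreement model should not contribute with a flipped sign).
Optionally only the top-M features ranked by validation CCC are fused.
Only regression scores are fused; class probabilities are a training aid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .training import PredictionSet


class AlignmentError(ValueError):
    """Prediction sets cover different subject sets."""


@dataclass
class FusionResult:
    subject_ids: list[str]
    fused_scores: np.ndarray
    weights: dict[str, float]
    strategy: str  # "averaged" | "adaptive"
    m: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "prediction": self.fused_scores}
        )

    def weight_table(self, preds: list[PredictionSet] | None = None) -> pd.DataFrame:
        """(feature_name, ccc, weight) table in descending-weight order."""
        cccs = {p.feature_name: p.validation_ccc for p in preds or []}
        rows = [
            {"feature_name": name, "ccc": cccs.get(name, np.nan), "weight": w}
            for name, w in sorted(self.weights.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


def _aligned_scores(preds: list[PredictionSet]) -> tuple[list[str], np.ndarray]:
    """Align by subject id; returns ids and a (n_features, n_subjects) matrix."""
    if not preds:
        raise ValueError("no prediction sets to fuse")
    ref = list(preds[0].subject_ids)
    ref_set = set(ref)
    for p in preds[1:]:
        missing = ref_set.symmetric_difference(p.subject_ids)
        if missing:
            raise AlignmentError(
                f"subject mismatch between {preds[0].feature_name!r} and "
                f"{p.feature_name!r}: {sorted(missing)}"
            )
    rows = []
    for p in preds:
        pos = {sid: i for i, sid in enumerate(p.subject_ids)}
        rows.append(p.scores[[pos[sid] for sid in ref]])
    return ref, np.stack(rows)


def averaged_fusion(preds: list[PredictionSet]) -> FusionResult:
    """Plain mean of per-feature scores (every feature weighted 1/M)."""
    ids, scores = _aligned_scores(preds)
    m = len(preds)
    return FusionResult(
        subject_ids=ids,
        fused_scores=scores.mean(axis=0),
        weights={p.feature_name: 1.0 / m for p in preds},
        strategy="averaged",
        m=m,
    )


def adaptive_fusion(preds: list[PredictionSet]) -> FusionResult:
    """CCC-weighted mean: weight_m = max(CCC_m, 0) / sum of clamped CCCs."""
    ids, scores = _aligned_scores(preds)
    cccs = np.array([max(p.validation_ccc, 0.0) for p in preds])
    total = cccs.sum()
    if total <= 0.0:
        raise ValueError(
            "adaptive fusion undefined: no feature has positive validation CCC"
        )
    weights = cccs / total
    return FusionResult(
        subject_ids=ids,
        fused_scores=weights @ scores,
        weights={p.feature_name: float(w) for p, w in zip(preds, weights)},
        strategy="adaptive",
        m=len(preds),
    )


def select_top_m(preds: list[PredictionSet], m: int) -> list[PredictionSet]:
    """The M sets with largest validation CCC.

    Ties break toward the lexicographically smaller feature name; the
    returned list is ordered by descending CCC.
    """
    if not 1 <= m <= len(preds):
        raise ValueError(f"top-M must lie in [1, {len(preds)}], got {m}")
    ranked = sorted(preds, key=lambda p: (-p.validation_ccc, p.feature_name))
    return ranked[:m]


def fuse(
    preds: list[PredictionSet],
    strategy: str = "adaptive",
    top_m: int | None = None,
) -> FusionResult:
    """Convenience front end: optional top-M selection, then fusion."""
    if top_m is not None:
        preds = select_top_m(preds, top_m)
    if strategy == "averaged":
        return averaged_fusion(preds)
    if strategy == "adaptive":
        return adaptive_fusion(preds)
    raise ValueError(f"unknown fusion strategy {strategy!r}")
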