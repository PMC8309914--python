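"""Sequence shortening and functional-feature derivation.

Frame-level streams are far too long to encode whole (dense acoustic
descriptors run to tens of thousands of frames), so before encoding we
shorten every sequence to a fixed budget of N frames by segment-based
sampling: the sequence is split evenly into s segments and a run of
L = N/s successive frames is drawn at random from each, preserving both
local dynamics (runs are contiguous) and global coverage (one run per
segment).

"Functional" variants of a stream summarize it with sliding-window
per-dimension mean and standard deviation, resampled to a fixed length,
mirroring the fixed-length summary features that ship with AVEC-style
corpora.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import FeatureSequence

#: Default frame budgets per feature level.
DEFAULT_N_LOW_MID = 2048
DEFAULT_N_HIGH = 720
#: Default length of functional summary sequences.
DEFAULT_FUNCTIONAL_LEN = 1768


class LengthError(ValueError):
    """Sequence too short for the requested operation."""


@dataclass(frozen=True)
class SamplingSpec:
    """Segment-sampling parameters: keep ``n_frames`` of the input in
    ``segments`` contiguous runs."""

    n_frames: int
    segments: int
    seed: int = 0
    pad_short: bool = True  # cyclically repeat-pad sequences shorter than n_frames

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.segments < 1:
            raise ValueError("n_frames and segments must be positive")
        if self.segments > self.n_frames:
            raise ValueError("segments must not exceed n_frames")

    def block_lengths(self) -> np.ndarray:
        """Per-segment run lengths; sums to n_frames.

        When n_frames is not divisible by segments, L = floor(N/s) and the
        first N - s*L segments contribute one extra frame.
        """
        base = self.n_frames // self.segments
        extra = self.n_frames - base * self.segments
        lengths = np.full(self.segments, base, dtype=int)
        lengths[:extra] += 1
        return lengths


@dataclass(frozen=True)
class FunctionalSpec:
    """Sliding-window functional summary: window length, hop, output length."""

    window_len: int = 64
    hop: int = 32
    target_len: int = DEFAULT_FUNCTIONAL_LEN

    def __post_init__(self) -> None:
        if self.window_len < 1 or self.hop < 1 or self.target_len < 1:
            raise ValueError("window_len, hop and target_len must be positive")


def segment_sample(
    seq: FeatureSequence,
    spec: SamplingSpec,
    rng: np.random.Generator | None = None,
) -> FeatureSequence:
    """Shorten ``seq`` to exactly ``spec.n_frames`` frames by segment sampling.

    The input is split evenly into ``spec.segments`` contiguous segments
    (earlier segments absorb the remainder when t is not divisible).  From
    segment k a run of ``L_k`` successive frames is drawn uniformly at
    random; the runs are concatenated in order.  Identical (input, spec,
    rng state) yields identical output.

    A segment shorter than its run length contributes all of its frames and
    is right-padded by repeating its last frame.  An input shorter than
    ``n_frames`` is cyclically repeat-padded first when ``pad_short`` is on,
    otherwise a :class:`LengthError` is raised.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    frames = seq.frames
    if frames.shape[0] < spec.n_frames:
        if not spec.pad_short:
            raise LengthError(
                f"sequence has {frames.shape[0]} frames, budget is {spec.n_frames}"
            )
        reps = -(-spec.n_frames // frames.shape[0])  # ceil
        frames = np.tile(frames, (reps, 1))[: spec.n_frames]
    t = frames.shape[0]
    seg_bounds = np.linspace(0, t, spec.segments + 1).astype(int)
    run_lengths = spec.block_lengths()
    blocks = []
    for k in range(spec.segments):
        lo, hi = seg_bounds[k], seg_bounds[k + 1]
        L = int(run_lengths[k])
        if hi - lo >= L:
            start = int(rng.integers(lo, hi - L + 1))
            block = frames[start : start + L]
        else:
            block = frames[lo:hi]
            pad = np.repeat(block[-1:], L - block.shape[0], axis=0)
            block = np.concatenate([block, pad], axis=0)
        blocks.append(block)
    out = np.concatenate(blocks, axis=0)
    assert out.shape[0] == spec.n_frames
    return FeatureSequence(seq.feature_name, seq.level, out)


def compute_functionals(
    seq: FeatureSequence, spec: FunctionalSpec
) -> FeatureSequence:
    """Sliding-window mean/std summary of a frame stream.

    Per window of ``window_len`` frames advanced by ``hop``, emit the
    concatenation of per-dimension mean and population standard deviation
    (output dimension 2d), then resample the resulting sequence to exactly
    ``target_len`` windows by nearest-index resampling.
    """
    x = seq.frames
    t, d = x.shape
    if t < spec.window_len:
        raise LengthError(
            f"sequence has {t} frames, functional window is {spec.window_len}"
        )
    starts = np.arange(0, t - spec.window_len + 1, spec.hop)
    windows = np.stack([x[s : s + spec.window_len] for s in starts])  # (n, w, d)
    mean = windows.mean(axis=1)
    std = windows.std(axis=1)  # population convention
    funcs = np.concatenate([mean, std], axis=1)  # (n, 2d)
    n = funcs.shape[0]
    if n != spec.target_len:
        idx = np.minimum(
            (np.arange(spec.target_len) * n / spec.target_len).astype(int), n - 1
        )
        funcs = funcs[idx]
    return FeatureSequence(seq.feature_name + "_functional", seq.level, funcs)


@dataclass
class Standardizer:
    """Per-dimension z-normalization with statistics frozen on training data."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, train: list[FeatureSequence], eps: float = 1e-8) -> "Standardizer":
        if not train:
            raise ValueError("cannot fit normalization on an empty training list")
        pooled = np.concatenate([s.frames for s in train], axis=0)
        mean = pooled.mean(axis=0)
        std = pooled.std(axis=0)
        std = np.where(std < eps, 1.0, std)  # constant dims map to zero
        return cls(mean=mean, std=std)

    def transform(self, seq: FeatureSequence) -> FeatureSequence:
        return FeatureSequence(
            seq.feature_name, seq.level, (seq.frames - self.mean) / self.std
        )


def zscore_normalize(
    train: list[FeatureSequence], apply_to: list[FeatureSequence]
) -> tuple[list[FeatureSequence], Standardizer]:
    """Normalize ``apply_to`` with statistics fitted on ``train`` only."""
    stats = Standardizer.fit(train)
    return [stats.transform(s) for s in apply_to], stats
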