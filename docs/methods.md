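# Methods

## Problem and model

The package estimates PHQ-8 depression severity (integer, 0–24) from
per-subject collections of frame-level feature streams.  Each stream is
modeled independently: a transformer encoder maps the (shortened,
standardized) frame sequence to a fixed embedding, from which a
regression head predicts the score and an auxiliary classification head
predicts the 5-class severity label derived from the standard clinical
cut-points (0, 5, 10, 15, 20; closed integer brackets, so 10 is
"moderate" and 19 "moderately severe").  The auxiliary task exists only
to shape the embedding during training; fusion and reporting use the
regression output.

The encoder is deliberately the plain post-norm architecture: sinusoidal
positional encoding added once before the first layer, then `N_enc`
identical layers of multi-head scaled dot-product self-attention and a
two-layer ReLU feed-forward block, each sub-block wrapped as
`LayerNorm(x + sublayer(x))`.  Attention scores are scaled by `1/√d_k`.
By default the model dimension equals the input feature dimension (no
input projection); setting `EncoderConfig.d_model` inserts a learned
linear projection before the positional encoding.  For an odd model
dimension the final unpaired positional-encoding column uses the sine
term.

## Losses and metrics

Agreement is measured by Lin's concordance correlation coefficient with
population (divide-by-n) moments; the regression loss is `1 − CCC`
computed over each training batch, with `1e-8` added to the denominator
so a collapsed batch cannot divide by zero.  On the metric path CCC is
computed once over the full evaluation set, on raw (unrounded)
predictions.  When both vectors are constant with equal means the
coefficient is 0/0; the metric raises by default and returns 1.0 under an
explicit flag (used only where a degenerate toy model should count as
"no disagreement").  The classification term is mean cross-entropy; the
heads emit logits and the training-path loss normalizes internally with
log-sum-exp, while the metric-path function accepts probabilities and
clips at `1e-12`.  The joint loss is `a·L_re + b·L_cl`, defaults
`(0.9, 0.1)` multi-task and `(1.0, 0.0)` single-task.

## Sequence shortening and functionals

Segment sampling keeps `N` of `t` frames as `s` contiguous runs, one per
equal segment, preserving local temporal structure while covering the
whole interview.  Degenerate cases are resolved so the output length
contract always holds: if `s ∤ N`, `L = ⌊N/s⌋` and the first `N − sL`
segments contribute one extra frame; a segment shorter than its run is
taken whole and right-padded by repeating its last frame; an input
shorter than `N` is repeat-padded cyclically (a flag turns this into an
error).  Defaults: `N = 2048` (low/middle-level), `N = 720` (high-level),
`s = 32`.  The segment count is a free hyperparameter; 32 keeps runs of
64 frames at the default budgets, long enough for attention to see local
dynamics.

Functional features summarize a stream by per-window, per-dimension mean
and population standard deviation (output dimension `2d`), windows of 64
frames advanced by 32 by default, then nearest-index resampling to
exactly 1768 windows.  The window/hop values are package defaults, not a
claim of fidelity to any particular corpus's shipped functionals.

Per-dimension z-normalization (statistics frozen on the training split,
standard-deviation floor `1e-8`, constant dimensions mapped to zero) is
on by default: the feature streams have wildly heterogeneous scales and
unnormalized inputs destabilize training.

## Training

One model per feature stream, Adam with canonical moment coefficients.
Reference defaults: learning rate `1e-5`, batch 48 / 500 epochs for
low- and middle-level streams, batch 24 / 200 epochs for high-level.
Segment draws are refreshed every epoch (mild augmentation; a flag
freezes them); the dev split is drawn once with a fixed seed so
evaluation is deterministic.  The checkpoint with the best dev CCC
(checked every `eval_every` epochs and at the last) is retained, since
model selection is performed on the development set.  No early stopping
or schedule.  Every random draw (init, dropout, sampling, batch order)
derives from the run seed, so a run is bit-reproducible on one machine.

The models are small enough that the whole stack runs on a compact
reverse-mode autodiff engine over float64 NumPy arrays
(`maft.autodiff`); gradient correctness is pinned to central finite
differences in the test suite.

## Fusion

Adaptive late fusion weights each feature's dev predictions by its dev
CCC, normalized over the fused set; averaged fusion is the equal-weight
baseline.  Negative CCCs are clamped to zero before normalizing — a
model in negative agreement carries no usable signal and must not enter
with a flipped sign — and fusion errors out if no feature has positive
CCC.  Top-M selection ranks by dev CCC with ties broken toward the
lexicographically smaller feature name.  Only regression scores are
fused; class probabilities are not.

## Synthetic cohort

The generator plants a recoverable severity signal in otherwise
structureless streams: per subject a score is drawn from a skewed-low
histogram (severity-class weights 77/36/26/17/7 spread uniformly within
classes, the imbalance typical of screening cohorts), and per feature an
AR(1) sequence (autocorrelation 0.8, marginal noise SD 0.3) whose mean
is offset by `signal_strength · (score/24) · u` along a fixed unit
direction `u`.  Signal strength 0 gives exchangeable pure noise;
strength 1 with zero noise makes the sequence mean an exact affine
function of the score.  The default cohort is 40 training / 16 dev
subjects with three 8-dimensional streams of 400–800 frames: strongly
informative (0.9), moderately informative (0.45) and pure noise (0.0).

What the generator does **not** emulate: real acoustic/visual feature
distributions, nonlinear or non-monotone severity effects,
inter-feature correlation, bag-of-words discreteness, missing data.
Passing tests therefore demonstrate that the pipeline recovers a planted
monotone signal and that CCC-weighted fusion suppresses uninformative
streams — not that any particular accuracy would be reached on clinical
data.

## Toy-scale operating point

End-to-end tests and the worked example run a reduced configuration
chosen once for desk-scale runtimes: 2 encoder layers, feed-forward
width 64, embedding 16, dropout 0.1, 64-frame budget in 8 segments,
full-batch Adam at learning rate `3e-3` for 200 epochs (the reference
rate of `1e-5` is matched to 500-epoch runs on far larger cohorts and
barely moves a 40-subject toy model in 200 epochs).  Under these
conditions, across five replicate cohort seeds: the strong stream
reaches dev CCC well above 0.5, the noise stream stays within ±0.4 of
zero, dev-CCC ranking follows planted signal strength, and adaptive
fusion matches or beats averaged fusion in every replicate.

## Known limitations

- Attention is dense; memory scales as O(t²) per layer, so frame budgets
  beyond a few thousand are impractical without approximation.
- The CPU-bound engine is intended for research-scale experiments, not
  corpus-scale training.
- Skewed training distributions bias predictions toward low scores at
  the severe end; adaptive fusion does not correct calibration, only
  weighting.
- CCC-proportional weights are a heuristic, not an optimal combination
  rule; features with correlated errors are double-counted.
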