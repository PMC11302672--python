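# Methods

## The modeling problem

`mtmask` implements self-supervised masked modeling for trial-aligned,
multi-region spike-count data, together with the test-time-masking benchmark
used to evaluate such models. The data unit is a session: a tensor of
non-negative counts `X` indexed `(trial, time bin, neuron)` (20 ms bins by
default), a brain-region label per neuron, and per-trial behavior (a binary
choice and a continuous whisker-motion-energy trace on the same time grid).

The model is an NDT1-style encoder: each time bin of population activity is
one transformer token. Training hides part of `X`, feeds the visible part to
the network, and maximizes the Poisson likelihood of the hidden part under
the inferred rates `r`:

```
M ~ U(causal, neuron, intra-region, inter-region)
Z = Tokenizer(M ⊙ X)
Z_prompt = [P_M, Z]
r = Transformer(Z_prompt)
loss = Poisson NLL of X at the scored entries of M
```

Alternating uniformly among the four masking schemes — multi-task masking
(MtM) — forces one network to learn population-level, region-level and
single-neuron structure at once; the learnable per-scheme prompt token `P_M`
tells the network which task is active and is re-used at test time to switch
modes. The baseline is classic temporal masking (hide random whole time
bins), trained identically but with a single scheme and no prompt.

## Masking schemes: context vs. target

Every scheme yields two disjoint boolean `(time, neuron)` masks: the
*context* mask (entries the model may see) and the *target* mask (entries
scored by the loss). They do not tile the array: intra-region masking hides
all out-of-region neurons without scoring them, so reconstruction can only
draw on same-region context, and inter-region masking hides the whole chosen
region while scoring it against other-region context. Hidden entries are
zero-filled and the binary context mask is concatenated to the count vector
before the input projection, so the model can distinguish "hidden" from an
observed zero — essential at 20 ms bins where most counts are zero.

Mask ratios are not part of the scheme definitions and default to common
masked-modeling practice: 0.3 of neurons (neuron masking), 0.3 of bins
(temporal), 0.3 of the chosen region's neurons for intra-region (context must
survive within the region) and 1.0 for inter-region (context lives
elsewhere). The causal scheme deterministically hides the final 10% of bins,
matching the forward-prediction benchmark; regions with fewer than 5 neurons
are never chosen for region masking. All ratios are configurable.

## Architecture

Tokenization concatenates the zero-filled counts and the context-mask row
(2·N values) and applies a per-session linear projection to the model width,
adds a learned per-session context embedding and learned positional
embeddings — the "stitching" that lets one network consume sessions with
disjoint neuron sets. The encoder is a pre-LayerNorm bidirectional
transformer (GELU feed-forward); causality is imposed by the input mask, not
by attention masking, so a single set of weights serves all schemes. The
prompt token is prepended before encoding and its output position dropped.
A per-session output projection maps each time token to per-neuron rates
through a softplus link floored at 1e-6 (the exponential link is available
but overflows early in training). The output bias is initialized to the
inverse-softplus of each neuron's training-split mean rate, so an untrained
model reproduces the per-neuron mean-rate null.

The network and its optimizer (AdamW) are built on a small reverse-mode
automatic-differentiation engine over float32 numpy arrays
(`mtmask._autograd`), verified against finite differences in the test suite.
The default benchmark model is deliberately small — `d_model` 64, 2 layers,
2 heads, feed-forward 256 — so every experiment in the test suite and the
acceptance script trains on one CPU core in minutes; `ModelConfig` scales all
of these up.

## Training, regularization, checkpoint selection

Default training: AdamW, constant learning rate 1e-3, batch 32 trials, one
masking scheme sampled per batch. Small synthetic sessions (160 training
trials) overfit the causal objective quickly — the network memorizes
train-trial tails — so the defaults carry strong regularization: dropout 0.25
and decoupled weight decay 0.1. Without them forward prediction never rises
above the null on held-out trials while all other metrics look healthy.

Checkpoints are scored periodically on validation trials by the mean
single-neuron reconstruction R² over the `k_active` = 50 most active neurons
(tallied on training trials), with scored neurons hidden in groups of 10
under neuron masking; the best-scoring epoch is restored for evaluation, ties
going to the earlier epoch. Note this rule is deliberately scheme-agnostic:
for single-scheme ablation models it can select checkpoints that are poor on
that scheme's own metric (visible in the causal-only ablation), which is part
of the benchmarked behavior, not a defect.

Trial splits are a seeded random partition, 80/10/10 by default, sizes
floored with the remainder assigned to train.

## Evaluation

All activity metrics share one mechanism — hide part of the test-split
input with the metric's mask, predict rates with the matched prompt, score
hidden entries — and are reported in *bits per spike*:

```
bps = [LL(X | r) − LL(X | null)] / (S · ln 2)
```

with the Poisson log-likelihood summed over scored entries, `S` their total
spike count, and the null a per-neuron constant rate fit on training trials
(floored at 1e-9 inside logarithms). The null scores exactly 0 by
construction; `S = 0` is reported as NaN rather than raised. Pooling is
micro-averaged across neurons (per-region values are additionally reported
for the region metrics). Co-smoothing and intra-region co-smoothing iterate
held-out neurons one at a time in reference mode; a batched mode hides
groups of `k` neurons jointly and is used by the long-running tests
(`k = 4`) at a small, empirically negligible cost in fidelity.

Behavior decoding fits linear readouts on inferred rates from unmasked
input: L2-regularized logistic regression (C = 1) on per-trial flattened
rates for choice, and per-bin ridge regression (α = 1) for motion energy,
with R² = 1 − SSE/SST computed on test-split variance. The neuron-masking
prompt is used for choice and the causal prompt for motion energy; the
choice of prompt is exposed as a flag since the two give similar results.
Region-restricted decoding hides all other regions, uses the intra-region
prompt, and feeds only the region's rate columns to the decoders.

## The synthetic cohort

The generator emulates the structure of repeated-site Neuropixels
recordings; it is the study condition for every test, not a tuning knob.
Per session: 3 named regions × 40 neurons, 200 trials of 100 bins at 20 ms.
Region latents (2 per region) follow a linear AR(1) process whose
region-to-region weight matrix has diagonal 0.55 and off-diagonal 0.2 —
eigenvalues (0.95, 0.35, 0.35), i.e. a slow mode shared across regions plus
faster local dynamics. The slow mode makes future activity genuinely
predictable several bins out (forward prediction has signal), and the
off-diagonal drive makes each region informative about the others
(inter-region prediction has signal). A per-trial binary choice shifts the
latent initial condition by 1.5 along a fixed unit direction shared by all
sessions, so choice is linearly decodable from rates and nothing else.
Rates follow an exponential-link GLM, `λ = exp(log 0.3 + w·z)` per bin with
per-session loadings `w ~ N(0, 0.7²)` — mean ≈ 0.35 counts/bin (≈ 17 Hz)
with lognormal-like rate heterogeneity. Counts are Poisson given rates;
motion energy is a fixed unit linear readout of the pooled latents plus
N(0, 0.1²) noise. Sessions of a cohort share regions, dynamics, the choice
direction and the motion readout, but have disjoint neurons and fresh
loadings — the repeated-site analogue. Everything is bit-reproducible from
`(seed, session_index)`.

With these conditions the clairvoyant oracle (the generator's true rates)
scores roughly 0.2–0.35 bps on co-smoothing across seeds, and the
conditional ceiling for forward prediction (Monte-Carlo rollout of the
latent process from the last visible bin) is ≈ 0.24 bps; trained small
models recover a substantial fraction of the former and a smaller fraction
of the latter.

What the generator does *not* emulate: refractoriness and bursting,
stimulus structure and block structure of the real task, non-Poisson
dispersion, electrode drift, and realistic region-specific timescale
differences. Passing tests therefore demonstrate that the machinery learns
and is scored correctly under a faithful low-dimensional Poisson world, not
that it reaches any particular performance on real recordings.

## Numerical and design choices

- Bins are half-open `[t, t + Δ)`; spikes outside every trial window are
  silently dropped by the binner (documented in its docstring).
- Loss is averaged over scored entries, keeping its scale comparable across
  schemes with very different target sizes; the `log x!` term is included so
  the loss is the exact negative log-likelihood.
- Region-scheme batches on sessions lacking eligible regions fall back to
  neuron masking with a logged warning, keeping multi-session training
  robust.
- Fine-tuning on an unseen session registers fresh stitching parameters and
  trains *all* weights with the model's own self-supervised objective; the
  prompt table is reused.
- Checkpoints store every parameter array plus the config and stitcher
  registry in a single `.npz` with a JSON header.
- The problem sizes used by the long-running tests and the acceptance script
  (one default session; 200-epoch budgets; 4+1 sessions at 100 trials × 60
  bins for the multi-session experiment; 3 paired seeds) are the package's
  own scaled-down benchmark, chosen so the full suite runs on one CPU core
  in well under half an hour.

## Known limitations

- Whole-neuron masking is used for the neuron scheme (matching the
  co-smoothing evaluation) rather than per-(neuron, time) cells.
- The causal scheme masks a fixed final fraction rather than a sampled
  horizon; next-step-only prediction is a special case via the horizon
  fraction.
- The evaluation treats the prompt token as always attendable when prompting
  is enabled; no prompt-free inference path exists for MtM models.
- Single-CPU float32 training: results are deterministic for a fixed seed
  and platform, but bit-level reproducibility across BLAS builds is not
  guaranteed.
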