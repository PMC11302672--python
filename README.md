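# mtmask — multi-task masked modeling of multi-region spiking data

`mtmask` is a self-contained toolkit for training and benchmarking masked
autoencoding models of trial-aligned neural population activity recorded
across multiple brain regions. It is aimed at computational neuroscientists
who want to study how masked self-supervised objectives shape what a
population model learns — at the population, region, and single-neuron
level — without needing access to large electrophysiology datasets: a
bundled simulator generates repeated-site-style cohorts (shared regions and
dynamics, disjoint neurons per session) on which every experiment runs in
minutes on a CPU.

## The method

For a session of binned spike counts `X` (trial × time × neuron, 20 ms bins)
the model is trained by *multi-task masking* (MtM): for each batch a masking
scheme `M` is drawn uniformly from

- **neuron masking** — hide whole neurons, reconstruct them from the rest of
  the population;
- **causal masking** — hide the final fraction of time bins, predict the
  future from the past;
- **intra-region masking** — hide part of one brain region *and* all other
  regions, reconstruct from same-region context only;
- **inter-region masking** — hide one whole region, reconstruct it from the
  other regions;

and the masked data is encoded by an NDT1-style transformer (one token per
time bin, per-session linear "stitching" projections, session embedding),
conditioned by a learnable per-scheme prompt token:

```
M ~ U(causal, neuron, intra-region, inter-region)
Z = Tokenizer(M ⊙ X);   Z_prompt = [P_M, Z];   r = Transformer(Z_prompt)
X̂ ~ Poisson(X | r)
```

The loss is the Poisson negative log-likelihood of the *hidden, scored*
entries. At test time the prompt token matched to the downstream task
switches the model's mode. The baseline is classic temporal masking (hide
random time bins, no prompt).

Evaluation is by *test-time masking*: co-smoothing, forward prediction, and
intra-/inter-region co-smoothing are all scored in bits per spike,

```
bps = [LL(X | r) − LL(X | null)] / (S · ln 2)
```

against a per-neuron mean-rate null (0 = no better than the null), plus
linear behavior decoding from inferred rates (choice accuracy,
whisker-motion-energy R²), optionally restricted to single regions. See
`docs/methods.md` for the full model, simulator, and benchmark description.

## Worked example

The whole pipeline is scriptable from the shell (or from Python via
`mtmask.synthetic` / `mtmask.training` / `mtmask.evaluation`):

```shell
mtm simulate --out-dir runs/sim --n-sessions 1 --seed 1
mtm train --session runs/sim/session_000.h5 --method mtm \
    --epochs 200 --out-dir runs/mtm --seed 1
mtm evaluate --checkpoint runs/mtm/checkpoint.npz \
    --session runs/sim/session_000.h5 --out-dir runs/eval --group-size 4
```

On the default synthetic session (3 regions × 40 neurons, 200 trials of 100
bins), seed 1, the evaluation prints

```json
{
  "session_id": "synth-1-000",
  "model_id": "checkpoint",
  "co_smoothing_bps": 0.26039212618007385,
  "forward_bps": 0.1721452517183106,
  "intra_region_bps_mean": 0.26442534103443477,
  "inter_region_bps_mean": 0.17775764740316544,
  "choice_accuracy": 1.0,
  "motion_energy_r2": 0.8456881055864816
}
```

(exact values can shift slightly with the BLAS build). Reading: the MtM
model predicts held-out neurons ≈ 0.26 bits/spike better than the
mean-rate null, recovers cross-region structure (inter-region 0.18 bps —
impossible for a model that ignores region labels), predicts the final
200 ms of each trial well above the null, and its inferred rates support
perfect choice decoding on the test trials. A temporal-masking baseline
trained under the same budget (`--method temporal`) lands near
0.11 / 0.07 / 0.05 / 0.11 on the four activity metrics — the
characteristic MtM-over-temporal gap, largest on region-level structure.

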