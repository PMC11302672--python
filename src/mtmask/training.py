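"""Training loops for multi-task masked modeling and the temporal baseline.

``train_mtm`` alternates uniformly among the four masking schemes (causal,
neuron, intra-region, inter-region), one scheme per batch, prepending the
scheme's prompt token.  ``train_temporal_baseline`` fixes the scheme to
temporal masking with no prompt — the NDT-style baseline.  Both support
multiple sessions through the model's stitcher, and a pretrained model can be
adapted to an unseen session with :func:`finetune_session`.

Checkpoints are scored by the mean single-neuron reconstruction R^2 over the
``k_active`` most active neurons, computed on validation trials with each
scored neuron hidden (neuron masking), and the best-scoring epoch is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._autograd import AdamW
from .io_core import SessionBundle, TrialSplit, most_active_neurons, split_trials
from .masking import (
    MaskParams,
    MaskResult,
    MaskScheme,
    TRAINING_SCHEMES,
    apply_scheme,
    mask_input,
)
from .model import ModelConfig, PopulationTransformer, poisson_nll

__all__ = [
    "TrainConfig",
    "CheckpointRecord",
    "TrainResult",
    "train_step",
    "train_mtm",
    "train_temporal_baseline",
    "train_single_scheme",
    "select_checkpoint",
    "finetune_session",
    "topk_neuron_r2",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    mask_params: MaskParams = field(default_factory=MaskParams)
    schemes: tuple[MaskScheme, ...] = TRAINING_SCHEMES
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    checkpoint_metric: str = "top_k_neuron_r2"
    k_active: int = 50
    #: validation-scoring period in epochs (the final epoch is always scored)
    eval_every: int = 10
    #: neurons hidden jointly per forward pass when scoring checkpoints
    score_group_size: int = 10

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        bad = [s for s in self.schemes if not isinstance(s, MaskScheme)]
        if bad:
            raise ValueError(f"unknown schemes {bad}")
        if self.checkpoint_metric != "top_k_neuron_r2":
            raise ValueError("only top_k_neuron_r2 checkpoint selection is implemented")


@dataclass
class CheckpointRecord:
    epoch: int
    score: float
    state: dict[str, np.ndarray]


@dataclass
class TrainResult:
    model: PopulationTransformer
    history: list[CheckpointRecord]
    splits: dict[str, TrialSplit]
    log_rows: list[dict]

    @property
    def best(self) -> CheckpointRecord:
        return select_checkpoint(self.history)

    def restore_best(self) -> PopulationTransformer:
        self.model.load_state_arrays(self.best.state)
        return self.model


def _eligible_for(scheme: MaskScheme, session: SessionBundle, params: MaskParams) -> bool:
    if scheme not in (MaskScheme.INTRA_REGION, MaskScheme.INTER_REGION):
        return True
    sizes = [len(ix) for ix in session.regions.region_index.values()]
    n_elig = sum(s >= params.min_region_size for s in sizes)
    if scheme is MaskScheme.INTER_REGION:
        return len(sizes) >= 2 and n_elig >= 1
    return n_elig >= 1


def train_step(
    model: PopulationTransformer,
    optimizer: AdamW,
    counts: np.ndarray,
    session: SessionBundle,
    scheme: MaskScheme,
    params: MaskParams,
    rng: np.random.Generator,
) -> tuple[float, MaskScheme]:
    """One masked-reconstruction gradient step on a (batch, T, N) count block.

    If the sampled region scheme is infeasible for this session (too few
    eligible regions) it falls back to neuron masking with a warning; the
    scheme actually applied is returned alongside the loss.
    """
    if not _eligible_for(scheme, session, params):
        log.warning("scheme %s infeasible for session %s; falling back to neuron masking",
                    scheme.value, session.session_id)
        scheme = MaskScheme.NEURON
    shape = (counts.shape[1], counts.shape[2])
    mask: MaskResult = apply_scheme(scheme, shape, session.regions, params, rng)
    masked = mask_input(counts, mask)
    seq = model.tokenize(masked, mask.context_mask, session.session_id)
    if model.config.prompt_enabled and scheme is not MaskScheme.TEMPORAL:
        seq = model.prepend_prompt(seq, scheme)
    rates = model.forward_rates(seq)
    loss = poisson_nll(rates, counts, mask.target_mask)
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return float(loss.data), scheme


def _run_training(
    sessions: list[SessionBundle],
    config: TrainConfig,
    model_config: ModelConfig,
    model: PopulationTransformer | None = None,
    trainable_sessions: list[str] | None = None,
    splits: dict[str, TrialSplit] | None = None,
) -> TrainResult:
    if not sessions:
        raise ValueError("need at least one session")
    rng = np.random.default_rng([config.seed, 0xBA7C])
    if splits is None:
        splits = {
            s.session_id: split_trials(s.n_trials, config.split_fractions, seed=config.seed)
            for s in sessions
        }
    if model is None:
        model = PopulationTransformer(model_config, rng=np.random.default_rng([config.seed, 0x1217]))
    for s in sessions:
        if s.session_id not in model.stitcher:
            mean_rates = s.spikes.counts[splits[s.session_id].train].mean(axis=(0, 1))
            model.register_session(s.session_id, s.n_neurons, mean_rates=mean_rates)
    if trainable_sessions is None:
        params_list = model.shared_parameters() + model.session_parameters()
    else:
        params_list = model.shared_parameters() + model.session_parameters(trainable_sessions)
    optimizer = AdamW(params_list, lr=config.learning_rate, weight_decay=config.weight_decay)

    history: list[CheckpointRecord] = []
    log_rows: list[dict] = []
    for epoch in range(config.epochs):
        model.training = True
        batches: list[tuple[int, np.ndarray]] = []
        for i, s in enumerate(sessions):
            train_trials = splits[s.session_id].train.copy()
            rng.shuffle(train_trials)
            for j in range(0, len(train_trials), config.batch_size):
                batches.append((i, train_trials[j : j + config.batch_size]))
        order = rng.permutation(len(batches))
        losses: list[float] = []
        scheme_counts: dict[str, int] = {s.value: 0 for s in config.schemes}
        for b in order:
            i, trials = batches[b]
            s = sessions[i]
            scheme = config.schemes[rng.integers(len(config.schemes))]
            counts = s.spikes.counts[trials]
            loss, applied = train_step(model, optimizer, counts, s, scheme, config.mask_params, rng)
            losses.append(loss)
            scheme_counts[scheme.value] = scheme_counts.get(scheme.value, 0) + 1
        model.training = False
        row = {"epoch": epoch, "loss": float(np.mean(losses)), **scheme_counts}
        if (epoch + 1) % config.eval_every == 0 or epoch == config.epochs - 1:
            score = float(
                np.mean(
                    [
                        topk_neuron_r2(model, s, splits[s.session_id], config)
                        for s in sessions
                    ]
                )
            )
            snap = {k: v.copy() for k, v in model.state_arrays().items()}
            history.append(CheckpointRecord(epoch=epoch, score=score, state=snap))
            row["val_score"] = score
        log_rows.append(row)
    return TrainResult(model=model, history=history, splits=splits, log_rows=log_rows)


def train_mtm(
    sessions: list[SessionBundle],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> TrainResult:
    """Multi-task-masking training: uniform scheme per batch, prompts on."""
    mc = model_config or ModelConfig()
    if not mc.prompt_enabled:
        mc = replace(mc, prompt_enabled=True)
    cfg = replace(config, schemes=tuple(config.schemes))
    return _run_training(sessions, cfg, mc)


def train_temporal_baseline(
    sessions: list[SessionBundle],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> TrainResult:
    """NDT-style baseline: temporal masking only, no prompt token."""
    mc = replace(model_config or ModelConfig(), prompt_enabled=False)
    cfg = replace(config, schemes=(MaskScheme.TEMPORAL,))
    return _run_training(sessions, cfg, mc)


def train_single_scheme(
    sessions: list[SessionBundle],
    scheme: MaskScheme,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> TrainResult:
    """Ablation helper: train with one masking scheme only (prompted)."""
    mc = model_config or ModelConfig()
    cfg = replace(config, schemes=(scheme,))
    if scheme is MaskScheme.TEMPORAL:
        mc = replace(mc, prompt_enabled=False)
    return _run_training(sessions, cfg, mc)


def topk_neuron_r2(
    model: PopulationTransformer,
    session: SessionBundle,
    split: TrialSplit,
    config: TrainConfig,
) -> float:
    """Mean single-neuron reconstruction R^2 over the most active neurons.

    The ``k_active`` most active neurons (tallied on training trials) are
    hidden in groups on validation trials, predicted under the neuron-masking
    prompt, and scored per neuron as R^2 between predicted rate and observed
    count across all validation (trial, bin) pairs.
    """
    k = min(config.k_active, session.n_neurons - 1)
    neurons = most_active_neurons(session.spikes, k, trials=split.train)
    counts = session.spikes.counts[split.val]
    T, N = counts.shape[1], counts.shape[2]
    pred = np.zeros((counts.shape[0], T, N), dtype=np.float32)
    for g in range(0, len(neurons), config.score_group_size):
        group = neurons[g : g + config.score_group_size]
        cm = np.ones((T, N), dtype=bool)
        cm[:, group] = False
        rates = model.predict_rates(counts, cm, session.session_id, scheme=MaskScheme.NEURON)
        pred[:, :, group] = rates[:, :, group]
    r2s = []
    for n in neurons:
        y = counts[:, :, n].ravel().astype(float)
        yhat = pred[:, :, n].ravel().astype(float)
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0:
            continue
        sse = float(((y - yhat) ** 2).sum())
        r2s.append(1.0 - sse / sst)
    if not r2s:
        return float("nan")
    return float(np.mean(r2s))


def select_checkpoint(history: list[CheckpointRecord]) -> CheckpointRecord:
    """Best-scoring checkpoint; ties resolved in favour of the earliest epoch."""
    if not history:
        raise ValueError("empty checkpoint history")
    scores = np.array([h.score for h in history], dtype=float)
    if np.all(np.isnan(scores)):
        raise ValueError("all checkpoint scores are NaN")
    best = int(np.nanargmax(scores))  # argmax returns the first maximum
    return history[best]


def finetune_session(
    model: PopulationTransformer,
    session: SessionBundle,
    config: TrainConfig,
    split: TrialSplit | None = None,
) -> TrainResult:
    """Adapt a pretrained model to an unseen session.

    Registers fresh stitching parameters (input/output projections and a
    session embedding) for the new session, then continues the model's own
    self-supervised objective on it with all weights trainable.  The prompt
    table is reused as-is.
    """
    if session.session_id in model.stitcher:
        raise ValueError(f"session {session.session_id!r} is already registered")
    splits = None if split is None else {session.session_id: split}
    return _run_training(
        [session], config, model.config, model=model, splits=splits
    )
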