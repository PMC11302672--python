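"""Test-time-masking benchmark: bits-per-spike metrics and behavior decoding.

All activity metrics share one mechanism: hide part of the test-trial input
with the metric's masking scheme, predict Poisson rates with the associated
prompt token, and score the hidden entries in *bits per spike* — the
log-likelihood improvement over a per-neuron mean-rate null model, normalized
by the total spike count of the scored entries and ln 2.  A model no better
than the null scores 0.

Metric -> mask -> prompt correspondence:

=====================  ==============  =================================
metric                 mask at test    scored entries
=====================  ==============  =================================
co-smoothing           neuron          each neuron, hidden one at a time
forward prediction     causal          final 10% of time bins
intra-region           intra-region    each neuron, same-region context
inter-region           inter-region    whole region, other-region context
=====================  ==============  =================================

Behavior decoding fits linear readouts (L2-regularized logistic for choice,
ridge for motion energy) on the model's inferred rates from unmasked input;
region-restricted decoding first hides every other region and uses the
intra-region prompt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil, log

import numpy as np
from scipy.special import gammaln
from sklearn.linear_model import LogisticRegression, Ridge

from .io_core import SessionBundle, TrialSplit
from .masking import MaskParams, MaskScheme
from .model import PopulationTransformer

__all__ = [
    "NullModel",
    "EvalReport",
    "ModelPredictor",
    "OraclePredictor",
    "NullPredictor",
    "bits_per_spike",
    "eval_co_smoothing",
    "eval_forward_prediction",
    "eval_intra_region",
    "eval_inter_region",
    "decode_choice",
    "decode_motion_energy",
    "region_restricted_decoding",
    "evaluate_all",
]

_RATE_EPS = 1e-9  # floor inside likelihood logs; avoids silent -inf


@dataclass
class NullModel:
    """Per-neuron constant rate: mean count per bin over training trials."""

    rates: np.ndarray  # (n_neurons,)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("null rates must be non-negative")

    @classmethod
    def from_session(cls, session: SessionBundle, train_trials: np.ndarray) -> "NullModel":
        return cls(session.spikes.counts[np.asarray(train_trials, dtype=int)].mean(axis=(0, 1)))


class ModelPredictor:
    """Adapts a :class:`PopulationTransformer` to the evaluation interface."""

    def __init__(self, model: PopulationTransformer, prompt_override: MaskScheme | None = None):
        self.model = model
        #: when set, every metric uses this prompt instead of its matched one
        self.prompt_override = prompt_override

    def rates_for(
        self,
        session: SessionBundle,
        trials: np.ndarray,
        context_mask: np.ndarray,
        scheme: MaskScheme | None,
    ) -> np.ndarray:
        if self.prompt_override is not None:
            scheme = self.prompt_override
        if not self.model.config.prompt_enabled:
            scheme = None
        counts = session.spikes.counts[np.asarray(trials, dtype=int)]
        return self.model.predict_rates(counts, context_mask, session.session_id, scheme=scheme)


class OraclePredictor:
    """Ground-truth rates from the simulator; ignores masks and prompts."""

    def __init__(self, rates: np.ndarray):
        self.rates = np.asarray(rates, dtype=float)

    def rates_for(self, session, trials, context_mask, scheme) -> np.ndarray:
        return self.rates[np.asarray(trials, dtype=int)]


class NullPredictor:
    """Constant per-neuron mean rates; scores exactly 0 bps by construction."""

    def __init__(self, null: NullModel):
        self.null = null

    def rates_for(self, session, trials, context_mask, scheme) -> np.ndarray:
        n_trials = len(np.asarray(trials))
        T = session.n_bins
        return np.broadcast_to(self.null.rates, (n_trials, T, session.n_neurons)).copy()


def _masked_ll(counts: np.ndarray, rates: np.ndarray, target_mask: np.ndarray) -> float:
    """Poisson log-likelihood (nats) summed over scored entries."""
    x = counts.astype(float)
    w = np.broadcast_to(np.asarray(target_mask, dtype=bool), x.shape)
    lam = np.maximum(np.broadcast_to(np.asarray(rates, dtype=float), x.shape)[w], _RATE_EPS)
    xw = x[w]
    return float((xw * np.log(lam) - lam - gammaln(xw + 1.0)).sum())


def bits_per_spike(
    rates: np.ndarray,
    counts: np.ndarray,
    target_mask: np.ndarray,
    null: NullModel,
) -> float:
    """Normalized likelihood gain over the mean-rate null, in bits per spike.

    ``bps = [LL(counts | rates) - LL(counts | null)] / (S * ln 2)`` with the
    log-likelihood summed over scored entries and ``S`` their total spike
    count.  Returns NaN (flagged-undefined) when ``S == 0``.
    """
    counts = np.asarray(counts)
    w = np.broadcast_to(np.asarray(target_mask, dtype=bool), counts.shape)
    S = float(counts[w].sum())
    if S == 0:
        return float("nan")
    null_full = np.broadcast_to(null.rates, counts.shape)
    ll_model = _masked_ll(counts, np.broadcast_to(rates, counts.shape), target_mask)
    ll_null = _masked_ll(counts, null_full, target_mask)
    return (ll_model - ll_null) / (S * log(2.0))


@dataclass
class _Pooled:
    """Accumulator pooling likelihoods across forward passes (micro-average)."""

    ll_model: float = 0.0
    ll_null: float = 0.0
    spikes: float = 0.0

    def add(self, counts, rates, null_rates, target_mask) -> None:
        w = np.broadcast_to(np.asarray(target_mask, dtype=bool), counts.shape)
        self.ll_model += _masked_ll(counts, np.broadcast_to(rates, counts.shape), target_mask)
        self.ll_null += _masked_ll(counts, np.broadcast_to(null_rates, counts.shape), target_mask)
        self.spikes += float(counts[w].sum())

    @property
    def bps(self) -> float:
        if self.spikes == 0:
            return float("nan")
        return (self.ll_model - self.ll_null) / (self.spikes * log(2.0))


def eval_co_smoothing(
    predictor,
    session: SessionBundle,
    split: TrialSplit,
    null: NullModel | None = None,
    group_size: int = 1,
) -> float:
    """Held-out-neuron prediction, pooled over every neuron in the session.

    ``group_size=1`` hides neurons one at a time (the exact reference mode);
    larger groups hide ``group_size`` neurons jointly for speed.
    """
    null = null or NullModel.from_session(session, split.train)
    counts = session.spikes.counts[split.test]
    T, N = session.n_bins, session.n_neurons
    pool = _Pooled()
    for g in range(0, N, group_size):
        group = np.arange(g, min(g + group_size, N))
        cm = np.ones((T, N), dtype=bool)
        cm[:, group] = False
        tm = np.zeros((T, N), dtype=bool)
        tm[:, group] = True
        rates = predictor.rates_for(session, split.test, cm, MaskScheme.NEURON)
        pool.add(counts, rates, null.rates, tm)
    return pool.bps


def eval_forward_prediction(
    predictor,
    session: SessionBundle,
    split: TrialSplit,
    null: NullModel | None = None,
    horizon_fraction: float = 0.10,
) -> float:
    """Predict the final fraction of each trial's bins from the preceding bins."""
    null = null or NullModel.from_session(session, split.train)
    counts = session.spikes.counts[split.test]
    T, N = session.n_bins, session.n_neurons
    h = int(ceil(horizon_fraction * T))
    cm = np.ones((T, N), dtype=bool)
    cm[T - h :] = False
    tm = ~cm
    rates = predictor.rates_for(session, split.test, cm, MaskScheme.CAUSAL)
    pool = _Pooled()
    pool.add(counts, rates, null.rates, tm)
    return pool.bps


def _eligible_regions(session: SessionBundle, min_region_size: int) -> list[str]:
    return [
        r
        for r in session.regions.regions
        if len(session.regions.region_index[r]) >= min_region_size
    ]


def eval_intra_region(
    predictor,
    session: SessionBundle,
    split: TrialSplit,
    null: NullModel | None = None,
    min_region_size: int = 5,
    group_size: int = 1,
) -> tuple[dict[str, float], float]:
    """Held-out-neuron prediction with only same-region context.

    For each eligible region and each of its neurons: the neuron and every
    out-of-region neuron are hidden (out-of-region entries are never scored),
    and the neuron's entries are scored.  ``group_size > 1`` hides that many
    same-region neurons jointly (batched mode).  Returns per-region pooled
    bps and their unweighted mean; NaN when no region is eligible.
    """
    null = null or NullModel.from_session(session, split.train)
    counts = session.spikes.counts[split.test]
    T, N = session.n_bins, session.n_neurons
    per_region: dict[str, float] = {}
    for region in _eligible_regions(session, min_region_size):
        members = session.regions.neurons_in(region)
        inside = session.regions.membership(region)
        pool = _Pooled()
        for g in range(0, len(members), group_size):
            group = members[g : g + group_size]
            cm = np.zeros((T, N), dtype=bool)
            cm[:, inside] = True
            cm[:, group] = False
            tm = np.zeros((T, N), dtype=bool)
            tm[:, group] = True
            rates = predictor.rates_for(session, split.test, cm, MaskScheme.INTRA_REGION)
            pool.add(counts, rates, null.rates, tm)
        per_region[region] = pool.bps
    if not per_region:
        return {}, float("nan")
    return per_region, float(np.nanmean(list(per_region.values())))


def eval_inter_region(
    predictor,
    session: SessionBundle,
    split: TrialSplit,
    null: NullModel | None = None,
    min_region_size: int = 5,
) -> tuple[dict[str, float], float]:
    """Predict each whole region from the other regions.

    The chosen region is entirely hidden and all of its entries are scored;
    context is every other region.  NaN when the session has a single region.
    """
    if len(session.regions.regions) < 2:
        return {}, float("nan")
    null = null or NullModel.from_session(session, split.train)
    counts = session.spikes.counts[split.test]
    T, N = session.n_bins, session.n_neurons
    per_region: dict[str, float] = {}
    for region in _eligible_regions(session, min_region_size):
        inside = session.regions.membership(region)
        cm = np.ones((T, N), dtype=bool)
        cm[:, inside] = False
        tm = np.zeros((T, N), dtype=bool)
        tm[:, inside] = True
        rates = predictor.rates_for(session, split.test, cm, MaskScheme.INTER_REGION)
        pool = _Pooled()
        pool.add(counts, rates, null.rates, tm)
        per_region[region] = pool.bps
    if not per_region:
        return {}, float("nan")
    return per_region, float(np.nanmean(list(per_region.values())))


def _rates_unmasked(predictor, session, trials, scheme) -> np.ndarray:
    cm = np.ones((session.n_bins, session.n_neurons), dtype=bool)
    return predictor.rates_for(session, trials, cm, scheme)


def decode_choice(
    predictor,
    session: SessionBundle,
    split: TrialSplit,
    scheme: MaskScheme = MaskScheme.NEURON,
    neuron_subset: np.ndarray | None = None,
    C: float = 1.0,
) -> float:
    """Binary choice accuracy of an L2-regularized linear classifier.

    The classifier is fit on per-trial flattened (time x neuron) inferred
    rates from unmasked input with the neuron-masking prompt (the scheme is
    overridable), and scored on test trials.
    """
    y_train = session.behavior.choice[split.train]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single choice class")
    rates_train = _rates_unmasked(predictor, session, split.train, scheme)
    rates_test = _rates_unmasked(predictor, session, split.test, scheme)
    if neuron_subset is not None:
        rates_train = rates_train[:, :, neuron_subset]
        rates_test = rates_test[:, :, neuron_subset]
    X_train = rates_train.reshape(len(split.train), -1)
    X_test = rates_test.reshape(len(split.test), -1)
    clf = LogisticRegression(C=C, max_iter=5000)
    clf.fit(X_train, y_train)
    return float(clf.score(X_test, session.behavior.choice[split.test]))


def decode_motion_energy(
    predictor,
    session: SessionBundle,
    split: TrialSplit,
    scheme: MaskScheme = MaskScheme.CAUSAL,
    neuron_subset: np.ndarray | None = None,
    alpha: float = 1.0,
) -> float:
    """R^2 of a per-bin ridge readout from inferred rates to motion energy.

    One sample per (trial, bin): the rate vector at that bin predicts the
    motion-energy value at that bin.  R^2 = 1 - SSE/SST with SST taken from
    the test-split target variance; NaN if the test target has no variance.
    """
    rates_train = _rates_unmasked(predictor, session, split.train, scheme)
    rates_test = _rates_unmasked(predictor, session, split.test, scheme)
    if neuron_subset is not None:
        rates_train = rates_train[:, :, neuron_subset]
        rates_test = rates_test[:, :, neuron_subset]
    n_feat = rates_train.shape[-1]
    X_train = rates_train.reshape(-1, n_feat)
    X_test = rates_test.reshape(-1, n_feat)
    y_train = session.behavior.motion_energy[split.train].ravel()
    y_test = session.behavior.motion_energy[split.test].ravel()
    sst = float(((y_test - y_test.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    reg = Ridge(alpha=alpha)
    reg.fit(X_train, y_train)
    sse = float(((y_test - reg.predict(X_test)) ** 2).sum())
    return 1.0 - sse / sst


def region_restricted_decoding(
    predictor,
    session: SessionBundle,
    region: str,
    split: TrialSplit,
) -> tuple[float, float]:
    """Decode behavior from one region's inferred rates only.

    Every other region is hidden at the input, the intra-region prompt is
    used, and both decoders see only the chosen region's rate columns.
    """
    members = session.regions.neurons_in(region)  # raises KeyError if unknown
    inside = session.regions.membership(region)
    cm = np.zeros((session.n_bins, session.n_neurons), dtype=bool)
    cm[:, inside] = True

    class _Restricted:
        def rates_for(self, sess, trials, _cm, _scheme):
            return predictor.rates_for(sess, trials, cm, MaskScheme.INTRA_REGION)

    r = _Restricted()
    acc = decode_choice(r, session, split, neuron_subset=members)
    r2 = decode_motion_energy(r, session, split, neuron_subset=members)
    return acc, r2


@dataclass
class EvalReport:
    """All benchmark values for one model x session."""

    session_id: str
    model_id: str
    co_smoothing_bps: float
    forward_bps: float
    intra_region_bps: dict[str, float]
    intra_region_bps_mean: float
    inter_region_bps: dict[str, float]
    inter_region_bps_mean: float
    choice_accuracy: float
    motion_energy_r2: float
    region_decoding: dict[str, tuple[float, float]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "session_id": self.session_id,
            "model_id": self.model_id,
            "co_smoothing_bps": self.co_smoothing_bps,
            "forward_bps": self.forward_bps,
            "intra_region_bps_mean": self.intra_region_bps_mean,
            "inter_region_bps_mean": self.inter_region_bps_mean,
            "choice_accuracy": self.choice_accuracy,
            "motion_energy_r2": self.motion_energy_r2,
            "intra_region_bps": dict(self.intra_region_bps),
            "inter_region_bps": dict(self.inter_region_bps),
            "region_decoding": {k: list(v) for k, v in self.region_decoding.items()},
            "metadata": dict(self.metadata),
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, default=float)

    def to_rows(self) -> list[dict]:
        """Flat (session_id, region, metric, value) rows for CSV export."""
        rows = [
            {"session_id": self.session_id, "region": "", "metric": m, "value": getattr(self, m)}
            for m in (
                "co_smoothing_bps",
                "forward_bps",
                "intra_region_bps_mean",
                "inter_region_bps_mean",
                "choice_accuracy",
                "motion_energy_r2",
            )
        ]
        for region, v in self.intra_region_bps.items():
            rows.append({"session_id": self.session_id, "region": region, "metric": "intra_region_bps", "value": v})
        for region, v in self.inter_region_bps.items():
            rows.append({"session_id": self.session_id, "region": region, "metric": "inter_region_bps", "value": v})
        for region, (acc, r2) in self.region_decoding.items():
            rows.append({"session_id": self.session_id, "region": region, "metric": "region_choice_accuracy", "value": acc})
            rows.append({"session_id": self.session_id, "region": region, "metric": "region_motion_energy_r2", "value": r2})
        return rows


def evaluate_all(
    predictor,
    session: SessionBundle,
    split: TrialSplit,
    model_id: str = "model",
    decode_behavior: bool = True,
    per_region_decoding: bool = False,
    co_smoothing_group_size: int = 1,
) -> EvalReport:
    """Run every benchmark metric with its matched prompt and assemble a report."""
    null = NullModel.from_session(session, split.train)
    intra, intra_mean = eval_intra_region(
        predictor, session, split, null, group_size=co_smoothing_group_size
    )
    inter, inter_mean = eval_inter_region(predictor, session, split, null)
    acc = r2 = float("nan")
    if decode_behavior:
        acc = decode_choice(predictor, session, split)
        r2 = decode_motion_energy(predictor, session, split)
    region_dec: dict[str, tuple[float, float]] = {}
    if per_region_decoding:
        for region in session.regions.regions:
            region_dec[region] = region_restricted_decoding(predictor, session, region, split)
    prompt_override = getattr(predictor, "prompt_override", None)
    return EvalReport(
        session_id=session.session_id,
        model_id=model_id,
        co_smoothing_bps=eval_co_smoothing(predictor, session, split, null, co_smoothing_group_size),
        forward_bps=eval_forward_prediction(predictor, session, split, null),
        intra_region_bps=intra,
        intra_region_bps_mean=intra_mean,
        inter_region_bps=inter,
        inter_region_bps_mean=inter_mean,
        choice_accuracy=acc,
        motion_energy_r2=r2,
        region_decoding=region_dec,
        metadata={
            "prompt_override": getattr(prompt_override, "value", None),
            "n_test_trials": int(len(split.test)),
        },
    )
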