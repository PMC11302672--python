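"""Data model for trial-aligned, multi-region spiking sessions.

A recording session is represented by a :class:`SessionBundle`: a binned
spike-count tensor (trials x time bins x neurons), a per-neuron brain-region
assignment, and per-trial behavior (a binary choice plus a continuous
motion-energy trace sampled on the same time grid as the spikes).  Bundles are
persisted in a small bespoke HDF5 layout (see :func:`save_session`).

Conventions: trial time starts at 0 at the alignment event, bins are half-open
``[t, t + bin_size)``, and neuron / trial indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "BinnedSpikeTensor",
    "RegionAssignment",
    "BehaviorTable",
    "SessionBundle",
    "TrialSplit",
    "bin_spike_times",
    "save_session",
    "load_session",
    "load_region_csv",
    "split_trials",
    "most_active_neurons",
]

#: Default bin width in seconds (20 ms windows).
DEFAULT_BIN_SIZE = 0.020
#: Default trial duration in seconds (2 s trials -> 100 bins of 20 ms per second).
DEFAULT_TRIAL_DURATION = 2.0


class FormatError(ValueError):
    """Raised when a session container is missing a required group or attribute."""


@dataclass
class BinnedSpikeTensor:
    """Non-negative spike counts indexed ``(trial, time_bin, neuron)``."""

    counts: np.ndarray
    bin_size: float
    trial_duration: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (trial, time_bin, neuron)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        n_bins = self.counts.shape[1]
        if abs(n_bins * self.bin_size - self.trial_duration) > self.bin_size:
            raise ValueError(
                f"{n_bins} bins of {self.bin_size}s inconsistent with "
                f"trial_duration={self.trial_duration}s"
            )

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[2]


@dataclass
class RegionAssignment:
    """One brain-region label per neuron, plus the inverse index."""

    region_label: list[str]
    region_index: dict[str, list[int]] = field(init=False)

    def __post_init__(self) -> None:
        self.region_label = [str(r) for r in self.region_label]
        index: dict[str, list[int]] = {}
        for i, lab in enumerate(self.region_label):
            index.setdefault(lab, []).append(i)
        self.region_index = {lab: sorted(ix) for lab, ix in index.items()}

    @property
    def n_neurons(self) -> int:
        return len(self.region_label)

    @property
    def regions(self) -> list[str]:
        """Region labels in sorted order."""
        return sorted(self.region_index)

    def neurons_in(self, region: str) -> np.ndarray:
        if region not in self.region_index:
            raise KeyError(f"unknown region {region!r}")
        return np.asarray(self.region_index[region], dtype=int)

    def membership(self, region: str) -> np.ndarray:
        """Boolean membership vector of length n_neurons for ``region``."""
        m = np.zeros(self.n_neurons, dtype=bool)
        m[self.neurons_in(region)] = True
        return m


@dataclass
class BehaviorTable:
    """Per-trial binary choice and per-(trial, bin) motion-energy trace."""

    choice: np.ndarray
    motion_energy: np.ndarray

    def __post_init__(self) -> None:
        self.choice = np.asarray(self.choice, dtype=int)
        self.motion_energy = np.asarray(self.motion_energy, dtype=float)
        if self.choice.ndim != 1:
            raise ValueError("choice must be one label per trial")
        if not np.isin(self.choice, [0, 1]).all():
            raise ValueError("choice labels must be binary (0/1)")
        if self.motion_energy.ndim != 2:
            raise ValueError("motion_energy must be (trial, time_bin)")
        if self.motion_energy.shape[0] != self.choice.shape[0]:
            raise ValueError("choice and motion_energy disagree on trial count")

    @property
    def n_trials(self) -> int:
        return self.choice.shape[0]


@dataclass
class SessionBundle:
    """One session's spikes, region labels, behavior, and identity."""

    session_id: str
    spikes: BinnedSpikeTensor
    regions: RegionAssignment
    behavior: BehaviorTable

    def __post_init__(self) -> None:
        if self.regions.n_neurons != self.spikes.n_neurons:
            raise ValueError("neuron count mismatch between spikes and regions")
        if self.behavior.n_trials != self.spikes.n_trials:
            raise ValueError("trial count mismatch between spikes and behavior")
        if self.behavior.motion_energy.shape[1] != self.spikes.n_bins:
            raise ValueError("motion_energy time axis must match spike time axis")

    @property
    def n_neurons(self) -> int:
        return self.spikes.n_neurons

    @property
    def n_trials(self) -> int:
        return self.spikes.n_trials

    @property
    def n_bins(self) -> int:
        return self.spikes.n_bins


@dataclass
class TrialSplit:
    """Disjoint train/val/test trial indices, reproducible from ``seed``."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.val = np.asarray(self.val, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        parts = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(parts)) != parts.size:
            raise ValueError("train/val/test must be disjoint")


def bin_spike_times(
    spike_times: list[np.ndarray],
    trial_starts: np.ndarray,
    bin_size: float = DEFAULT_BIN_SIZE,
    trial_duration: float = DEFAULT_TRIAL_DURATION,
) -> BinnedSpikeTensor:
    """Bin per-neuron spike times into a (trial, time_bin, neuron) count tensor.

    ``counts[r, t, n]`` is the number of spikes of neuron ``n`` in the half-open
    window ``[trial_starts[r] + t*bin_size, trial_starts[r] + (t+1)*bin_size)``.
    Spikes falling outside every trial window are silently dropped.

    Parameters
    ----------
    spike_times
        One array of spike times (seconds) per neuron.
    trial_starts
        Start time (seconds) of each trial's alignment window.
    bin_size, trial_duration
        Bin width and window length; ``trial_duration`` must be an integer
        multiple of ``bin_size`` (within floating-point tolerance).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins_f = trial_duration / bin_size
    n_bins = int(round(n_bins_f))
    if n_bins < 1 or abs(n_bins_f - n_bins) > 1e-6:
        raise ValueError("trial_duration must be an integer multiple of bin_size")
    trial_starts = np.asarray(trial_starts, dtype=float)
    n_trials = trial_starts.shape[0]
    n_neurons = len(spike_times)
    counts = np.zeros((n_trials, n_bins, n_neurons), dtype=np.int64)
    edges = np.arange(n_bins + 1) * bin_size
    for n, st in enumerate(spike_times):
        st = np.asarray(st, dtype=float)
        for r, t0 in enumerate(trial_starts):
            rel = st - t0
            inside = rel[(rel >= 0) & (rel < trial_duration)]
            if inside.size:
                # floor division keeps every bin half-open, unlike np.histogram
                # whose final bin is closed on the right
                idx = np.minimum((inside / bin_size).astype(int), n_bins - 1)
                np.add.at(counts[r, :, n], idx, 1)
    return BinnedSpikeTensor(counts, bin_size=bin_size, trial_duration=trial_duration)


def save_session(bundle: SessionBundle, path) -> None:
    """Write a bundle to the HDF5 session container layout.

    Layout: ``/spikes/counts`` (uint64), ``/regions/labels`` (string per
    neuron), ``/behavior/choice`` (int per trial), ``/behavior/motion_energy``
    (float, trial x time); root attributes ``session_id``, ``bin_size_s``,
    ``trial_duration_s``.
    """
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = bundle.session_id
        f.attrs["bin_size_s"] = bundle.spikes.bin_size
        f.attrs["trial_duration_s"] = bundle.spikes.trial_duration
        f.create_dataset("spikes/counts", data=bundle.spikes.counts.astype(np.uint64))
        f.create_dataset(
            "regions/labels",
            data=np.array(bundle.regions.region_label, dtype=h5py.string_dtype()),
        )
        f.create_dataset("behavior/choice", data=bundle.behavior.choice.astype(np.int64))
        f.create_dataset("behavior/motion_energy", data=bundle.behavior.motion_energy)


def load_session(path) -> SessionBundle:
    """Read a bundle written by :func:`save_session`.

    Raises :class:`FormatError` naming the first missing group or attribute.
    """
    with h5py.File(path, "r") as f:
        for key in ("spikes/counts", "regions/labels", "behavior/choice", "behavior/motion_energy"):
            if key not in f:
                raise FormatError(f"session container missing group {key!r}")
        for attr in ("session_id", "bin_size_s", "trial_duration_s"):
            if attr not in f.attrs:
                raise FormatError(f"session container missing attribute {attr!r}")
        counts = np.asarray(f["spikes/counts"], dtype=np.int64)
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["regions/labels"]]
        spikes = BinnedSpikeTensor(
            counts,
            bin_size=float(f.attrs["bin_size_s"]),
            trial_duration=float(f.attrs["trial_duration_s"]),
        )
        behavior = BehaviorTable(
            choice=np.asarray(f["behavior/choice"]),
            motion_energy=np.asarray(f["behavior/motion_energy"]),
        )
        return SessionBundle(
            session_id=str(f.attrs["session_id"]),
            spikes=spikes,
            regions=RegionAssignment(labels),
            behavior=behavior,
        )


def load_region_csv(path) -> RegionAssignment:
    """Import a region map from a two-column CSV (neuron_index, region_label)."""
    import pandas as pd

    df = pd.read_csv(path, header=None, names=["neuron_index", "region_label"], comment="#")
    df = df.sort_values("neuron_index")
    idx = df["neuron_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise FormatError("region CSV must cover neuron indices 0..N-1 exactly once")
    return RegionAssignment(list(df["region_label"]))


def split_trials(
    n_trials: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> TrialSplit:
    """Deterministic random partition of trials into train/val/test.

    Sizes are floored per fraction with the remainder assigned to train, so the
    split is an exact partition.  The permutation is drawn from
    ``np.random.default_rng(seed)``.
    """
    if n_trials < 3:
        raise ValueError("need at least 3 trials to populate train/val/test")
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must be positive and sum to 1")
    n_val = int(np.floor(fr[1] * n_trials))
    n_test = int(np.floor(fr[2] * n_trials))
    n_train = n_trials - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("n_trials too small to populate all split parts")
    perm = np.random.default_rng(seed).permutation(n_trials)
    return TrialSplit(
        train=np.sort(perm[:n_train]),
        val=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
        seed=seed,
    )


def most_active_neurons(
    spikes: BinnedSpikeTensor, k: int, trials: np.ndarray | None = None
) -> np.ndarray:
    """Indices of the ``k`` neurons with the highest total spike count.

    Ties are broken in favour of the lower neuron index.  ``trials`` restricts
    the tally (e.g. to the training split); ``None`` uses all trials.
    """
    if k > spikes.n_neurons:
        raise ValueError(f"k={k} exceeds neuron count {spikes.n_neurons}")
    counts = spikes.counts if trials is None else spikes.counts[np.asarray(trials, dtype=int)]
    totals = counts.sum(axis=(0, 1))
    # stable sort on (-total, index) implements the lower-index tie-break
    order = np.argsort(-totals, kind="stable")
    return order[:k]
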