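"""Masking schemes for multi-task masked modeling of spiking data.

Every scheme produces a :class:`MaskResult` holding two boolean
``(time_bin, neuron)`` masks:

* ``context_mask`` — entries the model is allowed to see;
* ``target_mask`` — entries scored by the reconstruction loss or metric.

The two sets are always disjoint but need not tile the array: region schemes
hide out-of-region (inter) or in-region-unchosen (never) entries without
scoring them, i.e. "masked, but not reconstructed".  Four schemes form the
multi-task training set — causal, neuron, intra-region, inter-region — and a
fifth, temporal, is the classic NDT-style baseline of hiding whole time bins.

Hidden entries are later zero-filled by :func:`mask_input`; the binary context
mask travels with the data so the model can tell "hidden" apart from an
observed zero count (zeros are the majority class in 20 ms bins).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from math import ceil

import numpy as np

from .io_core import RegionAssignment

__all__ = [
    "MaskScheme",
    "MaskParams",
    "MaskResult",
    "sample_scheme",
    "apply_neuron_mask",
    "apply_causal_mask",
    "apply_intra_region_mask",
    "apply_inter_region_mask",
    "apply_temporal_mask",
    "apply_scheme",
    "mask_input",
]


class MaskScheme(str, enum.Enum):
    TEMPORAL = "temporal"
    NEURON = "neuron"
    CAUSAL = "causal"
    INTRA_REGION = "intra_region"
    INTER_REGION = "inter_region"


#: The four schemes alternated during multi-task training (temporal is the
#: baseline and is never sampled here).
TRAINING_SCHEMES: tuple[MaskScheme, ...] = (
    MaskScheme.CAUSAL,
    MaskScheme.NEURON,
    MaskScheme.INTRA_REGION,
    MaskScheme.INTER_REGION,
)


@dataclass
class MaskParams:
    """Mask-ratio knobs; all fractions live in (0, 1] as documented per field."""

    neuron_mask_ratio: float = 0.3
    temporal_mask_ratio: float = 0.3
    causal_horizon_fraction: float = 0.10
    #: fraction of the chosen region's neurons that become targets; intra-region
    #: needs < 1 so that same-region context remains, inter-region defaults to
    #: hiding the entire region since context comes from elsewhere
    region_mask_ratio: float = 0.3
    inter_region_mask_ratio: float = 1.0
    min_region_size: int = 5

    def __post_init__(self) -> None:
        for name in ("neuron_mask_ratio", "temporal_mask_ratio", "causal_horizon_fraction", "region_mask_ratio"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 < self.inter_region_mask_ratio <= 1.0:
            raise ValueError("inter_region_mask_ratio must lie in (0, 1]")
        if self.min_region_size < 2:
            raise ValueError("min_region_size must be >= 2")


@dataclass
class MaskResult:
    context_mask: np.ndarray  # (time_bin, neuron), True = visible to the model
    target_mask: np.ndarray  # (time_bin, neuron), True = scored in the loss
    scheme: MaskScheme
    chosen_region: str | None = None

    def __post_init__(self) -> None:
        self.context_mask = np.asarray(self.context_mask, dtype=bool)
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        if self.context_mask.shape != self.target_mask.shape:
            raise ValueError("context and target masks must share a shape")
        if np.any(self.context_mask & self.target_mask):
            raise ValueError("no scored entry may be visible to the model")
        if not self.target_mask.any():
            raise ValueError("target mask must be nonempty")


def sample_scheme(rng: np.random.Generator) -> MaskScheme:
    """Draw a training scheme uniformly from the four multi-task schemes."""
    return TRAINING_SCHEMES[rng.integers(len(TRAINING_SCHEMES))]


def _ceil_count(ratio: float, n: int) -> int:
    return int(ceil(ratio * n))


def apply_neuron_mask(
    shape: tuple[int, int], params: MaskParams, rng: np.random.Generator
) -> MaskResult:
    """Hide a random subset of whole neurons; score them at every time bin."""
    T, N = shape
    if N < 2:
        raise ValueError("neuron masking needs at least 2 neurons")
    k = _ceil_count(params.neuron_mask_ratio, N)
    if k >= N:
        raise ValueError("neuron_mask_ratio leaves no context neurons")
    masked = rng.choice(N, size=k, replace=False)
    context = np.ones((T, N), dtype=bool)
    target = np.zeros((T, N), dtype=bool)
    context[:, masked] = False
    target[:, masked] = True
    return MaskResult(context, target, MaskScheme.NEURON)


def apply_causal_mask(shape: tuple[int, int], params: MaskParams) -> MaskResult:
    """Hide the final fraction of time bins; predict the future from the past."""
    T, N = shape
    h = _ceil_count(params.causal_horizon_fraction, T)
    if h < 1 or h >= T:
        raise ValueError("causal horizon must leave >= 1 visible and >= 1 masked bin")
    context = np.ones((T, N), dtype=bool)
    target = np.zeros((T, N), dtype=bool)
    context[T - h :, :] = False
    target[T - h :, :] = True
    return MaskResult(context, target, MaskScheme.CAUSAL)


def _eligible_regions(regions: RegionAssignment, min_size: int) -> list[str]:
    return [r for r in regions.regions if len(regions.region_index[r]) >= min_size]


def apply_intra_region_mask(
    shape: tuple[int, int],
    regions: RegionAssignment,
    params: MaskParams,
    rng: np.random.Generator,
) -> MaskResult:
    """Mask part of one region; context is the rest of the *same* region only.

    Out-of-region neurons are hidden but never scored, so the reconstruction
    can draw on within-region structure alone.
    """
    T, N = shape
    eligible = _eligible_regions(regions, params.min_region_size)
    if not eligible:
        raise ValueError(f"no region with >= {params.min_region_size} neurons")
    region = eligible[rng.integers(len(eligible))]
    members = regions.neurons_in(region)
    k = _ceil_count(params.region_mask_ratio, len(members))
    k = min(k, len(members) - 1)  # keep same-region context nonempty
    hidden = rng.choice(members, size=k, replace=False)
    context = np.zeros((T, N), dtype=bool)
    context[:, members] = True
    context[:, hidden] = False
    target = np.zeros((T, N), dtype=bool)
    target[:, hidden] = True
    return MaskResult(context, target, MaskScheme.INTRA_REGION, chosen_region=region)


def apply_inter_region_mask(
    shape: tuple[int, int],
    regions: RegionAssignment,
    params: MaskParams,
    rng: np.random.Generator,
) -> MaskResult:
    """Hide a whole region; context is every *other* region.

    A ratio < 1 scores only a subset of the hidden region, but the entire
    chosen region stays invisible either way.
    """
    T, N = shape
    if len(regions.regions) < 2:
        raise ValueError("inter-region masking needs >= 2 regions")
    eligible = _eligible_regions(regions, params.min_region_size)
    if not eligible:
        raise ValueError(f"no region with >= {params.min_region_size} neurons")
    region = eligible[rng.integers(len(eligible))]
    members = regions.neurons_in(region)
    k = max(1, _ceil_count(params.inter_region_mask_ratio, len(members)))
    scored = rng.choice(members, size=min(k, len(members)), replace=False)
    context = np.ones((T, N), dtype=bool)
    context[:, members] = False
    target = np.zeros((T, N), dtype=bool)
    target[:, scored] = True
    return MaskResult(context, target, MaskScheme.INTER_REGION, chosen_region=region)


def apply_temporal_mask(
    shape: tuple[int, int], params: MaskParams, rng: np.random.Generator
) -> MaskResult:
    """Baseline: hide a random subset of whole time bins across all neurons."""
    T, N = shape
    k = _ceil_count(params.temporal_mask_ratio, T)
    if k < 1 or k >= T:
        raise ValueError("temporal_mask_ratio must leave >= 1 visible and >= 1 masked bin")
    bins = rng.choice(T, size=k, replace=False)
    context = np.ones((T, N), dtype=bool)
    target = np.zeros((T, N), dtype=bool)
    context[bins, :] = False
    target[bins, :] = True
    return MaskResult(context, target, MaskScheme.TEMPORAL)


def apply_scheme(
    scheme: MaskScheme,
    shape: tuple[int, int],
    regions: RegionAssignment,
    params: MaskParams,
    rng: np.random.Generator,
) -> MaskResult:
    """Dispatch to the scheme-specific constructor."""
    if scheme is MaskScheme.NEURON:
        return apply_neuron_mask(shape, params, rng)
    if scheme is MaskScheme.CAUSAL:
        return apply_causal_mask(shape, params)
    if scheme is MaskScheme.INTRA_REGION:
        return apply_intra_region_mask(shape, regions, params, rng)
    if scheme is MaskScheme.INTER_REGION:
        return apply_inter_region_mask(shape, regions, params, rng)
    if scheme is MaskScheme.TEMPORAL:
        return apply_temporal_mask(shape, params, rng)
    raise ValueError(f"unknown scheme {scheme!r}")


def mask_input(counts: np.ndarray, mask: MaskResult) -> np.ndarray:
    """Zero-fill hidden entries of a (trial, time, neuron) count batch.

    Returns a fresh array (never a view) so mutating either side leaves the
    other intact.  The context mask itself is embedded downstream by the
    tokenizer, preserving the hidden-vs-observed-zero distinction.
    """
    counts = np.asarray(counts)
    if counts.shape[-2:] != mask.context_mask.shape:
        raise ValueError(
            f"counts trailing shape {counts.shape[-2:]} does not match mask "
            f"shape {mask.context_mask.shape}"
        )
    return np.where(mask.context_mask, counts, 0)
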