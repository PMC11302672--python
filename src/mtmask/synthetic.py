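"""Seeded simulator of multi-session, multi-region, trial-aligned spiking data.

The generator emulates the structure of repeated-site Neuropixels recordings:
every session samples the same named brain regions with shared latent dynamics
("same anatomical trajectory"), but carries its own disjoint set of neurons
with session-specific loadings.

The generative model, per trial:

* Each region ``r`` owns ``d`` latent dimensions.  The stacked latent vector
  follows a linear autoregressive process in which region ``r`` at time
  ``t + 1`` depends on region ``q`` at time ``t`` with weight
  ``cross_region_coupling[r, q]`` (applied dimension-wise), plus i.i.d.
  Gaussian innovations.  Stationarity requires the coupling matrix to have
  spectral radius < 1.
* A per-trial binary choice shifts the latent initial condition by
  ``choice_effect_size`` along a fixed unit direction shared by all sessions
  of a cohort, so choice is decodable from firing rates but enters nowhere
  else.
* Neuron ``n`` of region ``r`` fires with per-bin Poisson mean
  ``exp(baseline_log_rate + w_n . z[t, r])`` — an exponential-link GLM with
  session-specific loadings ``w_n`` (the bin width is folded into
  ``baseline_log_rate``, which is the log of the mean count per bin).
* Whisker-like motion energy is a fixed linear readout of the pooled latents
  plus Gaussian observation noise.

Everything is reproducible from ``(config.seed, session_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import BehaviorTable, BinnedSpikeTensor, RegionAssignment, SessionBundle

__all__ = ["SimConfig", "LatentTrajectories", "simulate_latents", "generate_session", "generate_cohort"]


def _default_regions() -> list[tuple[str, int]]:
    return [("VISa", 40), ("CA1", 40), ("LP", 40)]


def _default_coupling() -> np.ndarray:
    # self-dynamics with a slow shared mode plus genuine cross-region drive;
    # eigenvalues (0.95, 0.35, 0.35) keep the process stationary while giving
    # future activity a predictable component several bins out
    c = np.full((3, 3), 0.2)
    np.fill_diagonal(c, 0.55)
    return c


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults give a single session of 3 regions x 40 neurons, 200 trials of
    100 bins at 20 ms — a miniature of one repeated-site session that trains
    on a CPU in minutes.
    """

    n_sessions: int = 1
    n_trials: int = 200
    n_bins: int = 100
    bin_size: float = 0.020
    regions: list[tuple[str, int]] = field(default_factory=_default_regions)
    latent_dim_per_region: int = 2
    cross_region_coupling: np.ndarray = field(default_factory=_default_coupling)
    latent_noise_sd: float = 0.35
    baseline_log_rate: float = float(np.log(0.3))
    loading_scale: float = 0.7
    choice_effect_size: float = 1.5
    motion_energy_readout_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.cross_region_coupling = np.asarray(self.cross_region_coupling, dtype=float)
        if min(self.n_sessions, self.n_trials, self.n_bins, self.latent_dim_per_region) < 1:
            raise ValueError("all counts must be positive")
        if any(n < 1 for _, n in self.regions):
            raise ValueError("every region needs at least one neuron")
        R = len(self.regions)
        if self.cross_region_coupling.shape != (R, R):
            raise ValueError(
                f"coupling must be {R}x{R} (one row/col per region), "
                f"got {self.cross_region_coupling.shape}"
            )
        rho = np.max(np.abs(np.linalg.eigvals(self.cross_region_coupling)))
        if rho >= 1.0:
            raise ValueError(f"coupling spectral radius {rho:.3f} >= 1; latents non-stationary")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_labels(self) -> list[str]:
        return [lab for lab, _ in self.regions]

    @property
    def n_neurons(self) -> int:
        return sum(n for _, n in self.regions)

    @property
    def latent_dim_total(self) -> int:
        return self.n_regions * self.latent_dim_per_region


@dataclass
class LatentTrajectories:
    """Latent paths ``z`` indexed (trial, time_bin, region, latent_dim)."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 4 or not np.isfinite(self.z).all():
            raise ValueError("z must be finite with axes (trial, time, region, dim)")

    def pooled(self) -> np.ndarray:
        """Latents flattened over (region, dim): (trial, time, R*d)."""
        T, B = self.z.shape[:2]
        return self.z.reshape(T, B, -1)


def _cohort_rng(config: SimConfig) -> np.random.Generator:
    """RNG for parameters shared by every session of the cohort."""
    return np.random.default_rng([config.seed, 0xC0F0])


def _choice_direction(config: SimConfig) -> np.ndarray:
    """Fixed unit direction (in pooled latent space) of the choice shift."""
    u = _cohort_rng(config).standard_normal(config.latent_dim_total)
    return u / np.linalg.norm(u)


def _motion_readout(config: SimConfig) -> np.ndarray:
    """Fixed unit readout vector mapping pooled latents to motion energy."""
    rng = np.random.default_rng([config.seed, 0xD1A1])
    v = rng.standard_normal(config.latent_dim_total)
    return v / np.linalg.norm(v)


def simulate_latents(
    config: SimConfig,
    rng: np.random.Generator,
    choices: np.ndarray | None = None,
    z0: np.ndarray | None = None,
) -> LatentTrajectories:
    """Simulate the region-coupled AR(1) latent process for every trial.

    ``choices`` (0/1 per trial) shifts each trial's initial condition by
    ``+- choice_effect_size`` along the cohort's fixed direction; if omitted,
    no choice shift is applied.  ``z0`` overrides the random initial
    condition (useful for closed-form checks).
    """
    R, d = config.n_regions, config.latent_dim_per_region
    C = config.cross_region_coupling
    q = config.latent_noise_sd
    z = np.zeros((config.n_trials, config.n_bins, R, d))
    init = q * rng.standard_normal((config.n_trials, R, d)) if z0 is None else np.broadcast_to(z0, (config.n_trials, R, d)).copy()
    if choices is not None and config.choice_effect_size != 0.0:
        u = _choice_direction(config).reshape(R, d)
        sign = 2.0 * np.asarray(choices, dtype=float) - 1.0
        init = init + config.choice_effect_size * sign[:, None, None] * u
    z[:, 0] = init
    for t in range(1, config.n_bins):
        drive = np.einsum("rq,kqd->krd", C, z[:, t - 1])
        z[:, t] = drive + q * rng.standard_normal((config.n_trials, R, d))
    return LatentTrajectories(z)


def session_rates(
    config: SimConfig, latents: LatentTrajectories, loadings: np.ndarray, region_of: np.ndarray
) -> np.ndarray:
    """Per-neuron Poisson means exp(baseline + w_n . z[t, region(n)])."""
    # (trial, time, neuron): gather each neuron's own region's latents
    zn = latents.z[:, :, region_of, :]  # (trial, time, neuron, d)
    log_rate = config.baseline_log_rate + np.einsum("ktnd,nd->ktn", zn, loadings)
    return np.exp(log_rate)


def generate_session(
    config: SimConfig, session_index: int = 0, rng: np.random.Generator | None = None
) -> SessionBundle:
    """Generate one session; bit-reproducible from ``(config.seed, session_index)``."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 1 + session_index])
    region_label = [lab for lab, n in config.regions for _ in range(n)]
    region_of = np.array(
        [r for r, (_, n) in enumerate(config.regions) for _ in range(n)], dtype=int
    )
    choices = rng.integers(0, 2, size=config.n_trials)
    latents = simulate_latents(config, rng, choices=choices)
    loadings = config.loading_scale * rng.standard_normal(
        (config.n_neurons, config.latent_dim_per_region)
    )
    rates = session_rates(config, latents, loadings, region_of)
    counts = rng.poisson(rates)
    me = latents.pooled() @ _motion_readout(config)
    me = me + config.motion_energy_readout_noise_sd * rng.standard_normal(me.shape)
    return SessionBundle(
        session_id=f"synth-{config.seed}-{session_index:03d}",
        spikes=BinnedSpikeTensor(counts, bin_size=config.bin_size,
                                 trial_duration=config.n_bins * config.bin_size),
        regions=RegionAssignment(region_label),
        behavior=BehaviorTable(choice=choices, motion_energy=me),
    )


def oracle_rates(config: SimConfig, session_index: int = 0) -> np.ndarray:
    """Replay the generator and return the true Poisson means of a session.

    Used as the ground-truth oracle in evaluation sanity checks; follows the
    exact RNG consumption order of :func:`generate_session`.
    """
    rng = np.random.default_rng([config.seed, 1 + session_index])
    region_of = np.array(
        [r for r, (_, n) in enumerate(config.regions) for _ in range(n)], dtype=int
    )
    choices = rng.integers(0, 2, size=config.n_trials)
    latents = simulate_latents(config, rng, choices=choices)
    loadings = config.loading_scale * rng.standard_normal(
        (config.n_neurons, config.latent_dim_per_region)
    )
    return session_rates(config, latents, loadings, region_of)


def generate_cohort(config: SimConfig) -> list[SessionBundle]:
    """Generate ``n_sessions`` sessions sharing regions and dynamics.

    Sessions differ in neuron identity (fresh loadings, fresh trials) but share
    region labels and the latent transition — the repeated-site analogue.
    """
    if config.n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    return [generate_session(config, i) for i in range(config.n_sessions)]
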