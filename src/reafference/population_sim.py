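"""Heterogeneous sensor populations and interspike-interval structure.

A model fish carries ``n_sensors`` (default 30) independent lateral-line
sensors whose gain ``K1`` and regeneration rate ``K3`` are drawn
log-uniformly (spanning both canonical response regimes) with a shared
spontaneous rate ``s0``.  For each inhibition level the CD constant
``k2`` of every sensor is calibrated individually so that its spontaneous
rate drops to the same target fraction R_S of baseline — heterogeneous
sensors need different ``k2`` to reach the same measured suppression.

Each sensor is simulated for a single swim bout (stimulus and inhibition
on together, the sensor starting from its resting spontaneous steady
state) and the per-sensor spike trains of a fish are pooled.  ISIs are
computed within each fish and pooled across fish; strong inhibition
concentrates the surviving spikes at the stimulus peaks, so the ISI
density develops peaks at integer multiples of the stimulus period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .markov_sensor import (
    SensorParams,
    SimulationGrid,
    _simulate_chain,
    calibrate_inhibition,
    classify_parameter_set,
    make_stimulus,
)
from .spike_metrics import isi

__all__ = [
    "PopulationConfig",
    "ISIResult",
    "ISIPeaks",
    "sample_population",
    "simulate_fish_bout",
    "simulate_population_level",
    "aggregate_isi",
    "isi_peak_analysis",
    "run_population",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of the heterogeneous-population experiment."""

    n_sensors: int = 30
    k1_range: tuple[float, float] = (0.04, 4.0)
    k3_range: tuple[float, float] = (0.04, 4.0)
    s0: float = 4.0
    inhibition_levels: tuple[float, ...] = (1.0, 0.5, 0.1)
    n_fish: int = 1000
    frequency: float = 20.0
    sampling_rate: float = 2000.0
    n_wavelengths: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rng in (("k1_range", self.k1_range), ("k3_range", self.k3_range)):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"{name} must be positive with low <= high")
        if not all(0 < lv <= 1 for lv in self.inhibition_levels):
            raise ValueError("inhibition_levels must lie in (0, 1]")
        if self.n_sensors < 1 or self.n_fish < 1:
            raise ValueError("n_sensors and n_fish must be >= 1")

    @property
    def grid(self) -> SimulationGrid:
        return SimulationGrid(
            stimulus_frequency=self.frequency,
            sampling_rate=self.sampling_rate,
            n_wavelengths=self.n_wavelengths,
        )


def sample_population(
    config: PopulationConfig, seed: int | None = None
) -> list[tuple[SensorParams, str]]:
    """Draw the sensor parameters of one population.

    ``K1`` and ``K3`` are sampled log-uniformly within their ranges,
    ``s0`` is constant across sensors.  Each sensor is tagged with its
    empirical adapting/nonadapting classification.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo1, hi1 = np.log(config.k1_range[0]), np.log(config.k1_range[1])
    lo3, hi3 = np.log(config.k3_range[0]), np.log(config.k3_range[1])
    k1 = np.exp(rng.uniform(lo1, hi1, config.n_sensors))
    k3 = np.exp(rng.uniform(lo3, hi3, config.n_sensors))
    grid = config.grid
    out = []
    for a, b in zip(k1, k3):
        params = SensorParams(k1=float(a), k3=float(b), s0=config.s0)
        out.append((params, classify_parameter_set(params, grid)))
    return out


def _stationary_occupancy(params: SensorParams, grid: SimulationGrid) -> float:
    """Resting P(sensitive) under uninhibited spontaneous drive."""
    lam = grid.lambda_star
    p_b = min(params.s0 * lam, 1.0)
    p_c = min(params.k3 * lam, 1.0)
    return p_c / (p_b + p_c) if (p_b + p_c) > 0 else 1.0


def _bout_spikes(
    params: SensorParams,
    grid: SimulationGrid,
    k2: float,
    n_fish: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean spike array (n_fish, bout_steps) for one sensor."""
    stim = make_stimulus(grid.stimulus_frequency, grid)
    lam = grid.lambda_star
    p_b = np.clip((params.k1 * stim.values + k2 * params.s0) * lam, 0.0, 1.0)
    p_c = min(params.k3 * lam, 1.0)
    p0 = _stationary_occupancy(params, grid)
    return _simulate_chain(p_b, p_c, n_fish, rng, init_sensitive=p0)


def simulate_fish_bout(
    sensors: list[SensorParams],
    k2_values: np.ndarray,
    grid: SimulationGrid,
    seed: int = 0,
) -> np.ndarray:
    """Merged, sorted spike train of one fish for a single swim bout.

    Each sensor runs independently with its pre-calibrated ``k2``; spike
    times are pooled and sorted (coincident spikes from different sensors
    are kept, so the merge conserves the total count).
    """
    if len(sensors) == 0:
        raise ValueError("empty sensor list")
    if len(k2_values) != len(sensors):
        raise ValueError("need one k2 per sensor")
    rng = np.random.default_rng(seed)
    times = []
    for params, k2 in zip(sensors, k2_values):
        spikes = _bout_spikes(params, grid, float(k2), 1, rng)[0]
        times.append(np.flatnonzero(spikes) / grid.sampling_rate)
    return np.sort(np.concatenate(times))


@dataclass
class LevelResult:
    """Per-inhibition-level population output."""

    target_rs: float
    k2_values: np.ndarray
    counts_per_step: np.ndarray  # (n_fish, bout_steps) pooled over sensors
    grid: SimulationGrid

    def fish_spike_times(self, fish: int) -> np.ndarray:
        steps = np.repeat(
            np.arange(self.counts_per_step.shape[1]), self.counts_per_step[fish]
        )
        return steps / self.grid.sampling_rate

    @property
    def total_spikes(self) -> int:
        return int(self.counts_per_step.sum())

    def pooled_phases(self) -> np.ndarray:
        """Phases (radians) of all spikes pooled over fish."""
        period = self.grid.period_steps
        counts = self.counts_per_step.sum(axis=0)
        steps = np.repeat(np.arange(counts.size), counts)
        return 2 * np.pi * (steps % period) / period


def simulate_population_level(
    sensors: list[SensorParams],
    grid: SimulationGrid,
    target_rs: float,
    n_fish: int,
    seed: int = 0,
) -> LevelResult:
    """Simulate ``n_fish`` independent fish at one calibrated inhibition level.

    Calibration uses the closed-form stationary-rate inversion, matching
    the resting state each bout starts from.
    """
    k2s = np.array(
        [
            calibrate_inhibition(p, grid, target_rs, method="stationary")
            for p in sensors
        ]
    )
    rng = np.random.default_rng(seed)
    bout_steps = grid.segment_steps
    counts = np.zeros((n_fish, bout_steps), dtype=np.int16)
    for params, k2 in zip(sensors, k2s):
        counts += _bout_spikes(params, grid, float(k2), n_fish, rng)
    return LevelResult(target_rs=target_rs, k2_values=k2s, counts_per_step=counts, grid=grid)


@dataclass
class ISIResult:
    """Pooled within-fish interspike intervals and their histogram density."""

    isis: np.ndarray
    bin_centers: np.ndarray
    density: np.ndarray
    n_fish: int
    n_zero_dropped: int = 0


def aggregate_isi(
    fish_trains: list[np.ndarray] | LevelResult,
    bin_width: float = 0.001,
    max_isi: float | None = None,
) -> ISIResult:
    """ISIs computed within each fish, pooled, and binned.

    Fish with fewer than two spikes contribute no intervals.  Coincident
    pooled spikes (zero ISI, different sensors firing in the same time
    step) are dropped and counted in ``n_zero_dropped``.
    """
    if isinstance(fish_trains, LevelResult):
        lvl = fish_trains
        fish_trains = [lvl.fish_spike_times(i) for i in range(lvl.counts_per_step.shape[0])]
    all_isis = [isi(t) for t in fish_trains if len(t) >= 2]
    pooled = np.concatenate(all_isis) if all_isis else np.empty(0)
    if pooled.size == 0:
        raise ValueError("no interspike intervals in any fish")
    n_zero = int((pooled == 0).sum())
    pooled = pooled[pooled > 0]
    hi = max_isi if max_isi is not None else float(pooled.max()) + bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(pooled, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ISIResult(
        isis=pooled, bin_centers=centers, density=density,
        n_fish=len(fish_trains), n_zero_dropped=n_zero,
    )


@dataclass(frozen=True)
class ISIPeaks:
    """Density peaks and the integer-multiple ISI fraction."""

    peak_locations: np.ndarray
    integer_multiple_fraction: float
    tolerance: float
    period: float


def isi_peak_analysis(
    result: ISIResult,
    period: float,
    tolerance: float = 0.1,
    prominence_fraction: float = 0.1,
) -> ISIPeaks:
    """Locate ISI density peaks and the stimulus-locked interval fraction.

    ``integer_multiple_fraction`` is the share of ISIs within
    ``tolerance * period`` of some integer multiple n*T (n >= 1); peaks
    are local density maxima with prominence above
    ``prominence_fraction * max(density)``.
    """
    if result.isis.size == 0:
        raise ValueError("empty ISI set")
    if period <= 0:
        raise ValueError("period must be > 0")
    n = np.round(result.isis / period)
    frac = float(
        np.mean((n >= 1) & (np.abs(result.isis - n * period) <= tolerance * period))
    )
    prominence = prominence_fraction * result.density.max()
    idx, _ = find_peaks(result.density, prominence=prominence)
    return ISIPeaks(
        peak_locations=result.bin_centers[idx],
        integer_multiple_fraction=frac,
        tolerance=tolerance,
        period=period,
    )


def run_population(config: PopulationConfig, seed: int | None = None) -> dict:
    """Full experiment: one population, all inhibition levels.

    Returns ``{target_rs: (LevelResult, ISIResult, ISIPeaks)}`` using one
    shared sensor draw across levels.
    """
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    pop_seed, *level_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(1 + len(config.inhibition_levels))]
    sensors = [p for p, _ in sample_population(config, seed=pop_seed)]
    grid = config.grid
    out = {}
    for lv, lseed in zip(config.inhibition_levels, level_seeds):
        level = simulate_population_level(sensors, grid, lv, config.n_fish, seed=lseed)
        isis = aggregate_isi(level)
        peaks = isi_peak_analysis(isis, period=grid.period)
        out[lv] = (level, isis, peaks)
    return out
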