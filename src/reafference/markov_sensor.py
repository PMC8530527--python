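"""Discrete-time two-state stochastic model of a lateral-line sensor.

A sensor (hair cell + afferent treated as one unit) is either *sensitive*
(state 1) or *insensitive* (state 2).  On each time step of duration
``1/fs`` a sensitive sensor fires a spike with probability

    P_B = clip((K1 * s(t) + K2 * s0) * lambda*, 0, 1)

and, having fired, becomes insensitive (conceptually: the readily releasable
vesicle pool is spent).  An insensitive sensor regenerates with probability

    P_C = clip(K3 * lambda*, 0, 1)

per step and cannot spike.  ``lambda* = f / fs`` converts per-wavelength
rates (the natural units of the model constants) into per-step
probabilities, so ``s0`` is the expected number of spontaneous spikes per
stimulus wavelength and ``K3`` the expected number of regenerations per
wavelength.  The corollary-discharge (CD) strength ``K2`` in [0, 1]
multiplies only the spontaneous term; suppression of evoked activity is an
emergent property of the state dynamics, not a separate knob.

Simulated sessions mirror the stimulation protocol: each sweep consists of a
stimulated segment of ``n_wavelengths`` stimulus cycles (stimulus and
inhibition active) followed by an equally long re-equilibration segment in
which all drive is switched off so the pool can silently regenerate
(``requil_mode="off"``).  Setting ``requil_mode="release"`` instead restores
uninhibited spontaneous drive in the second segment, which is the protocol
that exhibits post-inhibition rebound spiking.  The first two sweeps of each
chain are flagged as burn-in and excluded from summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SensorParams",
    "SimulationGrid",
    "StimulusTrace",
    "TransitionMatrix",
    "SweepResult",
    "Session",
    "ADAPTING_SENSOR",
    "NONADAPTING_SENSOR",
    "BURN_IN_SWEEPS",
    "make_stimulus",
    "transition_probs",
    "simulate_sweep",
    "simulate_session",
    "classify_parameter_set",
    "calibrate_inhibition",
    "enumerate_expected_spikes",
    "expected_session_counts",
    "spontaneous_rate",
    "session_inhibition_ratios",
    "InhibitionRatios",
]

#: Number of initial sweeps per chain discarded from summaries.
BURN_IN_SWEEPS = 2


@dataclass(frozen=True)
class SensorParams:
    """Model constants of one sensor.

    Parameters
    ----------
    k1 : stimulus gain (dimensionless multiplier of the stimulus value).
    k3 : regeneration rate, expected regenerations per stimulus wavelength.
    s0 : spontaneous spike rate, expected spikes per stimulus wavelength.
    k2 : CD inhibition constant in [0, 1]; 1 means no inhibition.
    """

    k1: float
    k3: float
    s0: float
    k2: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {self.k1}")
        if not 0.0 <= self.k2 <= 1.0:
            raise ValueError(f"k2 must be in [0, 1], got {self.k2}")
        if self.k3 <= 0:
            raise ValueError(f"k3 must be > 0, got {self.k3}")
        if self.s0 < 0:
            raise ValueError(f"s0 must be >= 0, got {self.s0}")

    def with_k2(self, k2: float) -> "SensorParams":
        return SensorParams(self.k1, self.k3, self.s0, k2)


# Reference parameter sets for the two canonical response regimes.  The
# labels are assigned by `classify_parameter_set` (high gain relative to
# regeneration depletes the pool and adapts; fast regeneration does not),
# see docs/methods.md for the discussion of the naming.
ADAPTING_SENSOR = SensorParams(k1=4.0, k3=0.04, s0=40.0)
NONADAPTING_SENSOR = SensorParams(k1=0.04, k3=4.0, s0=4.0)


@dataclass(frozen=True)
class SimulationGrid:
    """Time discretization of a simulation.

    ``lambda_star = stimulus_frequency / sampling_rate`` is the per-step
    normalization factor; ``fs / f`` steps span one stimulus wavelength.
    """

    stimulus_frequency: float
    sampling_rate: float = 2000.0
    n_wavelengths: int = 20

    def __post_init__(self) -> None:
        if self.stimulus_frequency <= 0:
            raise ValueError("stimulus_frequency must be > 0")
        if self.sampling_rate < 10 * self.stimulus_frequency:
            raise ValueError(
                "sampling_rate must be at least 10x the stimulus frequency "
                f"(got fs={self.sampling_rate}, f={self.stimulus_frequency})"
            )
        if self.n_wavelengths < 1:
            raise ValueError("n_wavelengths must be >= 1")

    @property
    def lambda_star(self) -> float:
        return self.stimulus_frequency / self.sampling_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def period_steps(self) -> int:
        return int(round(self.sampling_rate / self.stimulus_frequency))

    @property
    def segment_steps(self) -> int:
        """Steps in the stimulated segment (n_wavelengths cycles)."""
        return self.n_wavelengths * self.period_steps

    @property
    def sweep_steps(self) -> int:
        """Steps per sweep: stimulated segment plus equal re-equilibration."""
        return 2 * self.segment_steps

    @property
    def period(self) -> float:
        return 1.0 / self.stimulus_frequency


@dataclass(frozen=True)
class StimulusTrace:
    """Sampled stimulus s(t): one dimensionless value per time step."""

    values: np.ndarray
    period_steps: int
    frequency: float


def make_stimulus(
    frequency: float,
    grid: SimulationGrid | None = None,
    rectified: bool = True,
) -> StimulusTrace:
    """Unit-peak sinusoid sampled on the grid, peaking at phase pi/2.

    With ``rectified=True`` (default) the negative half-cycle is set to 0:
    a polarized hair cell is driven only by deflection in its sense
    direction.
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    if grid is None:
        grid = SimulationGrid(stimulus_frequency=frequency)
    if frequency >= grid.sampling_rate / 2:
        raise ValueError(
            f"frequency {frequency} Hz is at or above the Nyquist rate of "
            f"the grid ({grid.sampling_rate / 2} Hz)"
        )
    period_steps = int(round(grid.sampling_rate / frequency))
    n = grid.n_wavelengths * period_steps
    t = np.arange(n) / grid.sampling_rate
    values = np.sin(2 * np.pi * frequency * t)
    if rectified:
        values = np.clip(values, 0.0, None)
    return StimulusTrace(values=values, period_steps=period_steps, frequency=frequency)


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-step transition probabilities of the two-state chain."""

    p_a: float  # stay sensitive
    p_b: float  # spike / release (1 -> 2)
    p_c: float  # regenerate (2 -> 1)
    p_d: float  # stay insensitive
    clipped: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([[self.p_a, self.p_b], [self.p_c, self.p_d]])


def _p_spike(params: SensorParams, stimulus_value: float | np.ndarray, lam: float):
    raw = (params.k1 * np.asarray(stimulus_value, dtype=float) + params.k2 * params.s0) * lam
    return np.clip(raw, 0.0, 1.0), bool(np.any((raw < 0) | (raw > 1)))


def transition_probs(
    params: SensorParams, stimulus_value: float, grid: SimulationGrid
) -> TransitionMatrix:
    """Transition matrix entries for one stimulus sample."""
    if not math.isfinite(stimulus_value):
        raise ValueError("stimulus_value must be finite")
    lam = grid.lambda_star
    p_b, clipped_b = _p_spike(params, stimulus_value, lam)
    p_b = float(p_b)
    raw_c = params.k3 * lam
    p_c = min(max(raw_c, 0.0), 1.0)
    clipped = clipped_b or raw_c > 1.0
    return TransitionMatrix(p_a=1.0 - p_b, p_b=p_b, p_c=p_c, p_d=1.0 - p_c, clipped=clipped)


# ---------------------------------------------------------------------------
# Simulation kernels


def _simulate_chain(
    p_b: np.ndarray,
    p_c: float,
    n_chains: int,
    rng: np.random.Generator,
    init_sensitive: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Simulate ``n_chains`` independent chains over a shared p_b schedule.

    A single uniform per step per chain decides both the spike (if
    sensitive) and the regeneration (if insensitive); the two comparisons
    are mutually exclusive so independence is preserved.

    Returns a boolean spike array of shape ``(n_chains, n_steps)``.
    """
    n_steps = p_b.shape[0]
    spikes = np.zeros((n_chains, n_steps), dtype=bool)
    if np.isscalar(init_sensitive) or np.ndim(init_sensitive) == 0:
        sens = rng.random(n_chains) < float(init_sensitive)
    else:
        sens = np.asarray(init_sensitive, dtype=bool).copy()
    for t in range(n_steps):
        u = rng.random(n_chains)
        spike = sens & (u < p_b[t])
        regen = (~sens) & (u < p_c)
        spikes[:, t] = spike
        sens = (sens & ~spike) | regen
    return spikes


def _occupancy_propagation(
    p_b: np.ndarray, p_c: float, p0: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Exact forward propagation of P(sensitive).

    Returns ``(p_sens, expected_spikes_per_step)`` where
    ``expected_spikes_per_step[t] = p_sens[t] * p_b[t]``.
    """
    n = p_b.shape[0]
    p_sens = np.empty(n)
    p = float(p0)
    for t in range(n):
        p_sens[t] = p
        p = p * (1.0 - p_b[t]) + (1.0 - p) * p_c
    return p_sens, p_sens * p_b


@dataclass(frozen=True)
class SweepResult:
    """One realization of the chain over an explicit stimulus."""

    spike_times: np.ndarray
    spike_steps: np.ndarray
    n_steps: int
    dt: float
    states: np.ndarray | None = None


def simulate_sweep(
    params: SensorParams,
    stimulus: StimulusTrace,
    grid: SimulationGrid,
    inhibition_schedule: np.ndarray | None = None,
    seed: int = 0,
    record_states: bool = False,
) -> SweepResult:
    """Simulate a single sweep over ``stimulus``.

    ``inhibition_schedule`` gives a per-step ``k2`` value (defaults to the
    constant ``params.k2``).  A spike is emitted at the step of each
    sensitive->insensitive transition; identical seeds give identical spike
    times.
    """
    values = np.asarray(stimulus.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty stimulus")
    lam = grid.lambda_star
    if inhibition_schedule is None:
        k2 = np.full(values.shape, params.k2)
    else:
        k2 = np.asarray(inhibition_schedule, dtype=float)
        if k2.shape != values.shape:
            raise ValueError(
                f"inhibition schedule length {k2.shape} does not match "
                f"stimulus length {values.shape}"
            )
    p_b = np.clip((params.k1 * values + k2 * params.s0) * lam, 0.0, 1.0)
    p_c = min(params.k3 * lam, 1.0)
    rng = np.random.default_rng(seed)
    if record_states:
        # scalar path retaining the state trajectory
        n = values.size
        states = np.empty(n, dtype=np.int8)
        spikes = np.zeros(n, dtype=bool)
        sens = True
        for t in range(n):
            states[t] = 1 if sens else 2
            u = rng.random()
            if sens:
                if u < p_b[t]:
                    spikes[t] = True
                    sens = False
            elif u < p_c:
                sens = True
        steps = np.flatnonzero(spikes)
        return SweepResult(steps * grid.dt, steps, n, grid.dt, states)
    spikes = _simulate_chain(p_b, p_c, 1, rng)[0]
    steps = np.flatnonzero(spikes)
    return SweepResult(steps * grid.dt, steps, values.size, grid.dt, None)


def _session_p_b(
    params: SensorParams,
    grid: SimulationGrid,
    k2: float,
    with_stimulus: bool,
    requil_mode: str,
    rectified: bool = True,
) -> np.ndarray:
    """Per-step spike probability over one sweep (stim + requil segment)."""
    if requil_mode not in ("off", "release"):
        raise ValueError("requil_mode must be 'off' or 'release'")
    lam = grid.lambda_star
    stim = make_stimulus(grid.stimulus_frequency, grid, rectified=rectified)
    s = stim.values if with_stimulus else np.zeros_like(stim.values)
    active = (params.k1 * s + k2 * params.s0) * lam
    requil_k2 = 0.0 if requil_mode == "off" else 1.0
    requil = np.full(grid.segment_steps, requil_k2 * params.s0 * lam)
    return np.clip(np.concatenate([active, requil]), 0.0, 1.0)


@dataclass
class Session:
    """Spike output of a simulated stimulation session.

    ``spikes`` is a boolean array of shape ``(n_sweeps_total, sweep_steps)``
    where sweeps from all chains are stacked; ``burn_in`` flags the first
    ``BURN_IN_SWEEPS`` sweeps of every chain.
    """

    spikes: np.ndarray
    burn_in: np.ndarray
    params: SensorParams
    grid: SimulationGrid
    k2: float
    with_stimulus: bool
    requil_mode: str
    seed: int

    @property
    def n_sweeps(self) -> int:
        return self.spikes.shape[0]

    @property
    def stim_steps(self) -> int:
        return self.grid.segment_steps

    def _segment_slice(self, segment: str) -> slice:
        if segment == "stim":
            return slice(0, self.stim_steps)
        if segment == "requil":
            return slice(self.stim_steps, self.spikes.shape[1])
        if segment == "all":
            return slice(None)
        raise ValueError(f"unknown segment {segment!r}")

    def sweep_counts(self, segment: str = "stim", include_burn_in: bool = False) -> np.ndarray:
        counts = self.spikes[:, self._segment_slice(segment)].sum(axis=1)
        if include_burn_in:
            return counts
        return counts[~self.burn_in]

    def cycle_counts(self, include_burn_in: bool = False) -> np.ndarray:
        """Spike counts per stimulus cycle, shape (n_sweeps, n_wavelengths)."""
        stim = self.spikes[:, : self.stim_steps]
        per_cycle = stim.reshape(
            stim.shape[0], self.grid.n_wavelengths, self.grid.period_steps
        ).sum(axis=2)
        if include_burn_in:
            return per_cycle
        return per_cycle[~self.burn_in]

    def rate(self, segment: str = "stim") -> float:
        """Mean spike rate (spikes/s) in a segment, burn-in excluded."""
        counts = self.sweep_counts(segment)
        sl = self._segment_slice(segment)
        duration = (sl.stop or self.spikes.shape[1]) - (sl.start or 0)
        return float(counts.mean()) / (duration * self.grid.dt)

    def spike_phases(self, include_burn_in: bool = False) -> np.ndarray:
        """Phases (radians) of stimulated-segment spikes, pooled over sweeps."""
        keep = slice(None) if include_burn_in else ~self.burn_in
        sweeps, steps = np.nonzero(self.spikes[keep, : self.stim_steps])
        return 2 * np.pi * (steps % self.grid.period_steps) / self.grid.period_steps

    def spike_table(self, cell_id: str = "sim") -> pd.DataFrame:
        """Long-format spike table (cell_id, sweep, time_s, step, segment, burn_in)."""
        sweeps, steps = np.nonzero(self.spikes)
        segment = np.where(steps < self.stim_steps, "stim", "requil")
        return pd.DataFrame(
            {
                "cell_id": cell_id,
                "sweep": sweeps,
                "time_s": steps * self.grid.dt,
                "step": steps,
                "segment": segment,
                "burn_in": self.burn_in[sweeps].astype(int),
            }
        )


def _chain_layout(n_post_sweeps: int, sweeps_per_chain: int = 10) -> tuple[int, int]:
    """Split a requested post-burn-in sweep budget into parallel chains."""
    kept = max(sweeps_per_chain - BURN_IN_SWEEPS, 1)
    n_chains = max(1, math.ceil(n_post_sweeps / kept))
    return n_chains, sweeps_per_chain


def simulate_session(
    params: SensorParams,
    grid: SimulationGrid,
    n_sweeps: int,
    seed: int = 0,
    k2: float | None = None,
    with_stimulus: bool = True,
    requil_mode: str = "off",
    n_chains: int = 1,
    rectified: bool = True,
) -> Session:
    """Simulate ``n_chains`` chains of ``n_sweeps`` consecutive sweeps each.

    Within a chain the state carries over from sweep to sweep; the first
    ``BURN_IN_SWEEPS`` sweeps of each chain are flagged burn-in.  The
    stimulated segment has the stimulus (if ``with_stimulus``) and CD
    inhibition ``k2`` active; the re-equilibration segment follows
    ``requil_mode`` (see module docstring).
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    k2 = params.k2 if k2 is None else float(k2)
    if not 0.0 <= k2 <= 1.0:
        raise ValueError("k2 must be in [0, 1]")
    p_b_sweep = _session_p_b(params, grid, k2, with_stimulus, requil_mode, rectified)
    p_b = np.tile(p_b_sweep, n_sweeps)
    p_c = min(params.k3 * grid.lambda_star, 1.0)
    rng = np.random.default_rng(seed)
    raw = _simulate_chain(p_b, p_c, n_chains, rng)
    spikes = raw.reshape(n_chains, n_sweeps, grid.sweep_steps).reshape(
        n_chains * n_sweeps, grid.sweep_steps
    )
    burn = np.zeros((n_chains, n_sweeps), dtype=bool)
    burn[:, : min(BURN_IN_SWEEPS, n_sweeps)] = True
    return Session(
        spikes=spikes,
        burn_in=burn.reshape(-1),
        params=params,
        grid=grid,
        k2=k2,
        with_stimulus=with_stimulus,
        requil_mode=requil_mode,
        seed=seed,
    )


def simulate_session_mc(
    params: SensorParams,
    grid: SimulationGrid,
    n_post_sweeps: int,
    seed: int = 0,
    **kwargs,
) -> Session:
    """Session with at least ``n_post_sweeps`` post-burn-in sweeps.

    Splits the budget over parallel chains of 10 sweeps (2 burn-in + 8
    kept) so the sweep dimension can be simulated vectorized.
    """
    n_chains, sweeps_per_chain = _chain_layout(n_post_sweeps)
    return simulate_session(
        params, grid, sweeps_per_chain, seed=seed, n_chains=n_chains, **kwargs
    )


# ---------------------------------------------------------------------------
# Deterministic expectations


def expected_session_counts(
    params: SensorParams,
    grid: SimulationGrid,
    k2: float,
    with_stimulus: bool = False,
    requil_mode: str = "off",
    n_sweeps: int = 6,
) -> np.ndarray:
    """Exact expected spike count in the stimulated segment of each sweep.

    Computed by forward propagation of the state occupancy over
    ``n_sweeps`` consecutive sweeps (the chain forgets its initialization
    within the burn-in sweeps, so later entries are cycle-stationary).
    """
    p_b_sweep = _session_p_b(params, grid, k2, with_stimulus, requil_mode)
    p_b = np.tile(p_b_sweep, n_sweeps)
    p_c = min(params.k3 * grid.lambda_star, 1.0)
    _, ex = _occupancy_propagation(p_b, p_c, p0=1.0)
    per_sweep = ex.reshape(n_sweeps, grid.sweep_steps)[:, : grid.segment_steps]
    return per_sweep.sum(axis=1)


def expected_cycle_counts(
    params: SensorParams,
    grid: SimulationGrid,
    k2: float = 1.0,
    requil_mode: str = "off",
    n_sweeps: int = 6,
) -> np.ndarray:
    """Exact expected per-cycle evoked counts of a cycle-stationary sweep."""
    p_b_sweep = _session_p_b(params, grid, k2, True, requil_mode)
    p_b = np.tile(p_b_sweep, n_sweeps)
    p_c = min(params.k3 * grid.lambda_star, 1.0)
    _, ex = _occupancy_propagation(p_b, p_c, p0=1.0)
    last = ex.reshape(n_sweeps, grid.sweep_steps)[-1, : grid.segment_steps]
    return last.reshape(grid.n_wavelengths, grid.period_steps).sum(axis=1)


def enumerate_expected_spikes(
    params: SensorParams,
    stimulus: StimulusTrace,
    n_steps: int | None = None,
    grid: SimulationGrid | None = None,
    inhibition_schedule: np.ndarray | None = None,
    max_steps: int = 16,
    p0_sensitive: float = 1.0,
) -> float:
    """Exact expected spike count over a short stimulus prefix.

    Propagates the two-state occupancy distribution step by step and sums
    ``P(sensitive) * P_B`` — the closed-form oracle against which the Monte
    Carlo simulator is validated.  Capped at ``max_steps`` steps.
    """
    values = np.asarray(stimulus.values, dtype=float)
    if n_steps is None:
        n_steps = values.size
    if n_steps > max_steps:
        raise ValueError(f"n_steps={n_steps} exceeds the cap of {max_steps}")
    if grid is None:
        grid = SimulationGrid(stimulus_frequency=stimulus.frequency)
    values = values[:n_steps]
    lam = grid.lambda_star
    if inhibition_schedule is None:
        k2 = np.full(values.shape, params.k2)
    else:
        k2 = np.asarray(inhibition_schedule, dtype=float)[:n_steps]
    p_b = np.clip((params.k1 * values + k2 * params.s0) * lam, 0.0, 1.0)
    p_c = min(params.k3 * lam, 1.0)
    _, ex = _occupancy_propagation(p_b, p_c, p0=p0_sensitive)
    return float(ex.sum())


# ---------------------------------------------------------------------------
# Classification and calibration


def classify_parameter_set(
    params: SensorParams,
    grid: SimulationGrid,
    tau: float = 0.5,
    requil_mode: str = "off",
) -> str:
    """Label a parameter set "adapting" or "nonadapting".

    The label is assigned empirically from the exact expected per-cycle
    evoked counts (CD off) of a cycle-stationary sweep: adapting iff the
    mean over the last two cycles is below ``tau`` times the mean over the
    first two.
    """
    cycles = expected_cycle_counts(params, grid, k2=1.0, requil_mode=requil_mode)
    first = cycles[:2].mean()
    last = cycles[-2:].mean()
    if first <= 0:
        raise ValueError("undriven sensor: first-cycle expected count is zero")
    return "adapting" if last < tau * first else "nonadapting"


def spontaneous_rate(
    params: SensorParams,
    grid: SimulationGrid,
    k2: float,
    n_post_sweeps: int = 400,
    seed: int = 0,
    requil_mode: str = "off",
) -> tuple[float, float]:
    """Monte Carlo spontaneous rate (spikes/s) in the active window.

    Simulates a spontaneous-only session (no stimulus, inhibition ``k2``
    in the active segment) and returns ``(rate, standard_error)``.
    """
    ses = simulate_session_mc(
        params, grid, n_post_sweeps, seed=seed, k2=k2, with_stimulus=False,
        requil_mode=requil_mode,
    )
    counts = ses.sweep_counts("stim")
    duration = grid.segment_steps * grid.dt
    rate = counts.mean() / duration
    se = counts.std(ddof=1) / math.sqrt(counts.size) / duration
    return float(rate), float(se)


def _stationary_rate(p_b: float, p_c: float) -> float:
    """Long-run spikes/step of the chain under constant drive."""
    if p_b <= 0:
        return 0.0
    return p_b * p_c / (p_b + p_c)


def calibrate_inhibition(
    params: SensorParams,
    grid: SimulationGrid,
    target_rs: float,
    seed: int = 0,
    method: str = "expected",
    tol: float = 0.002,
    n_post_sweeps: int = 400,
    max_iter: int = 60,
    requil_mode: str = "off",
) -> float:
    """Find ``k2`` such that the spontaneous inhibition ratio equals ``target_rs``.

    R_S is the spontaneous rate with inhibition ``k2`` divided by the rate
    without inhibition (k2 = 1), measured in the active segment of
    spontaneous-only sessions.  Nonlinearities make R_S != k2 in general,
    so the observed ratio is used, not the constant itself.

    Methods
    -------
    ``"expected"`` (default): bisection on the exact expected-count ratio
    obtained by occupancy propagation — deterministic and free of Monte
    Carlo noise.
    ``"session"``: bisection on Monte Carlo session rates with common
    random numbers (``n_post_sweeps`` per evaluation).
    ``"stationary"``: closed-form inversion of the stationary-rate ratio
    ``r(k2) = p_b(k2) p_c / (p_b(k2) + p_c)``; appropriate when the sensor
    sits at its spontaneous steady state (e.g. before a swim bout).
    """
    if not 0.0 < target_rs <= 1.0:
        raise ValueError("target_rs must be in (0, 1]")
    if target_rs == 1.0:
        return 1.0
    lam = grid.lambda_star
    p_c = min(params.k3 * lam, 1.0)
    p_b1 = min(params.s0 * lam, 1.0)
    if p_b1 <= 0:
        raise ValueError("sensor has no spontaneous activity to calibrate against")

    if method == "stationary":
        k2 = target_rs * p_c / (p_b1 + p_c - target_rs * p_b1)
        return float(min(max(k2, 0.0), 1.0))

    if method == "expected":
        base = expected_session_counts(
            params, grid, 1.0, with_stimulus=False, requil_mode=requil_mode
        )[-1]

        def measured_rs(k2: float) -> float:
            val = expected_session_counts(
                params, grid, k2, with_stimulus=False, requil_mode=requil_mode
            )[-1]
            return val / base

    elif method == "session":
        base, _ = spontaneous_rate(
            params, grid, 1.0, n_post_sweeps, seed=seed, requil_mode=requil_mode
        )
        if base <= 0:
            raise ValueError("baseline spontaneous rate is zero")

        def measured_rs(k2: float) -> float:
            rate, _ = spontaneous_rate(
                params, grid, k2, n_post_sweeps, seed=seed, requil_mode=requil_mode
            )
            return rate / base

    else:
        raise ValueError(f"unknown calibration method {method!r}")

    lo, hi = 0.0, 1.0
    rs_lo = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rs = measured_rs(mid)
        if abs(rs - target_rs) < tol:
            return mid
        if rs < target_rs:
            lo, rs_lo = mid, rs
        else:
            hi = mid
    if abs(rs_lo - target_rs) > 10 * tol and lo == 0.0:
        raise ValueError(f"target R_S={target_rs} unreachable within k2 in [0, 1]")
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Inhibition-ratio measurement on simulated sessions


@dataclass(frozen=True)
class InhibitionRatios:
    """Monte Carlo R_S, R_E and their ratio, with delta-method SEs."""

    r_s: float
    r_e: float
    r_s_se: float
    r_e_se: float
    n_sweeps: int

    @property
    def ratio(self) -> float:
        return self.r_e / self.r_s

    @property
    def ratio_se(self) -> float:
        return self.ratio * math.sqrt(
            (self.r_e_se / self.r_e) ** 2 + (self.r_s_se / self.r_s) ** 2
        )


def _mean_se(counts: np.ndarray) -> tuple[float, float]:
    return float(counts.mean()), float(counts.std(ddof=1) / math.sqrt(counts.size))


def _ratio_se(num: tuple[float, float], den: tuple[float, float]) -> tuple[float, float]:
    r = num[0] / den[0]
    se = r * math.sqrt((num[1] / num[0]) ** 2 + (den[1] / den[0]) ** 2)
    return r, se


def session_inhibition_ratios(
    params: SensorParams,
    grid: SimulationGrid,
    k2: float,
    n_post_sweeps: int = 2000,
    seed: int = 0,
    requil_mode: str = "off",
) -> InhibitionRatios:
    """Measure R_S and R_E for inhibition ``k2`` against the k2=1 baseline.

    Four sessions are simulated (spontaneous / evoked, inhibited /
    baseline); rates are taken from the active segment and ratios carry
    delta-method standard errors from the per-sweep count dispersion.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    kw = dict(requil_mode=requil_mode)
    spont_i = simulate_session_mc(
        params, grid, n_post_sweeps, seeds[0], k2=k2, with_stimulus=False, **kw
    ).sweep_counts("stim")
    spont_b = simulate_session_mc(
        params, grid, n_post_sweeps, seeds[1], k2=1.0, with_stimulus=False, **kw
    ).sweep_counts("stim")
    ev_i = simulate_session_mc(
        params, grid, n_post_sweeps, seeds[2], k2=k2, with_stimulus=True, **kw
    ).sweep_counts("stim")
    ev_b = simulate_session_mc(
        params, grid, n_post_sweeps, seeds[3], k2=1.0, with_stimulus=True, **kw
    ).sweep_counts("stim")
    r_s, r_s_se = _ratio_se(_mean_se(spont_i), _mean_se(spont_b))
    r_e, r_e_se = _ratio_se(_mean_se(ev_i), _mean_se(ev_b))
    return InhibitionRatios(r_s, r_e, r_s_se, r_e_se, int(spont_i.size))
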