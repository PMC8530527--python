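"""Fictive recording sessions for exercising the full analysis pipeline.

The generator emulates the stimulation protocol of the physiological
experiments — 100 sweeps of a sinusoidal dipole stimulus, 1 s on / 2 s off,
at 5, 20 or 40 Hz — with spontaneous swim bouts (60 ms to 1 s) during which
the corollary discharge inhibits the sensor.  Spiking comes from the
two-state Markov sensor; each synthetic cell is assigned one of three
response types mirroring the empirically observed clusters:

* group 1 — weakly adapting sensor, strong CD inhibition;
* group 2 — mixed adaptation, weak inhibition;
* group 3 — strongly adapting sensor, strong inhibition.

The per-group parameter presets are chosen to reproduce this qualitative
structure and are not fitted physiological values.  Ground truth
(parameters, group labels, calibrated k2) is returned in a manifest so
recovery of the planted structure can be tested end to end.

A small quasi-steady body-wave toy is included: with a traveling wave of
body wavelength ``lambda_body`` (in body lengths) at tail-beat frequency
``f``, peak cupular deflection at body position ``x`` in cycle ``c``
occurs at ``t = (c + x / lambda_body) / f`` — rostral neuromasts lead
caudal ones by a constant offset each cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cd_analysis import label_spikes
from .markov_sensor import SensorParams, SimulationGrid, calibrate_inhibition

__all__ = [
    "Protocol",
    "SwimBoutModel",
    "BodyWaveModel",
    "SyntheticDataset",
    "GROUP_PRESETS",
    "generate_protocol",
    "generate_swim_bouts",
    "generate_dataset",
    "body_wave_peak_times",
    "read_spike_table",
    "write_spike_table",
    "read_epoch_table",
    "write_epoch_table",
]


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol: n_sweeps of (on_duration, off_duration)."""

    frequency: float = 20.0
    n_sweeps: int = 100
    on_duration: float = 1.0
    off_duration: float = 2.0

    @property
    def sweep_duration(self) -> float:
        return self.on_duration + self.off_duration

    @property
    def session_length(self) -> float:
        return self.n_sweeps * self.sweep_duration

    @property
    def intervals_per_epoch(self) -> int:
        """Stimulus intervals (cycles) per on-epoch."""
        return int(round(self.frequency * self.on_duration))

    @property
    def stimulus_epochs(self) -> pd.DataFrame:
        starts = np.arange(self.n_sweeps) * self.sweep_duration
        return pd.DataFrame({"start_s": starts, "end_s": starts + self.on_duration})


def generate_protocol(
    frequency: float = 20.0,
    n_sweeps: int = 100,
    on_duration: float = 1.0,
    off_duration: float = 2.0,
) -> Protocol:
    """Deterministic stimulus-epoch table for one session."""
    if frequency <= 0 or n_sweeps < 1:
        raise ValueError("frequency must be > 0 and n_sweeps >= 1")
    return Protocol(frequency, n_sweeps, on_duration, off_duration)


@dataclass(frozen=True)
class SwimBoutModel:
    """Spontaneous swim-bout process.

    Onsets follow a Poisson process of ``rate`` bouts/s thinned so that
    consecutive bouts never overlap and each bout is followed by a free
    post-swim window of its own duration.  Durations are log-normal
    (median ``median_duration``, log-sd ``sigma``) clipped to
    [min_duration, max_duration] — 60 ms to 1 s, the observed range of
    larval swim bouts.
    """

    rate: float = 0.4
    median_duration: float = 0.15
    sigma: float = 0.5
    min_duration: float = 0.06
    max_duration: float = 1.0
    refractory: float = 0.05

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not 0 < self.min_duration <= self.max_duration:
            raise ValueError("need 0 < min_duration <= max_duration")


def generate_swim_bouts(
    model: SwimBoutModel, session_length: float, seed: int = 0
) -> pd.DataFrame:
    """Non-overlapping swim epochs (start_s, end_s) over one session."""
    rng = np.random.default_rng(seed)
    rows = []
    if model.rate <= 0:
        return pd.DataFrame(columns=["start_s", "end_s"])
    t = 0.0
    while True:
        start = t + rng.exponential(1.0 / model.rate)
        dur = float(
            np.clip(
                rng.lognormal(np.log(model.median_duration), model.sigma),
                model.min_duration,
                model.max_duration,
            )
        )
        end = start + dur
        if end > session_length:
            break
        rows.append({"start_s": start, "end_s": end})
        # leave room for the equal-duration post-swim window
        t = end + dur + model.refractory
    return pd.DataFrame(rows, columns=["start_s", "end_s"])


@dataclass(frozen=True)
class BodyWaveModel:
    """Quasi-steady traveling body wave sampled at neuromast positions."""

    tail_beat_frequency: float = 20.0
    body_wavelength: float = 1.0  # body lengths
    positions: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)

    def __post_init__(self) -> None:
        if self.tail_beat_frequency <= 0 or self.body_wavelength <= 0:
            raise ValueError("frequency and wavelength must be > 0")
        pos = np.asarray(self.positions, dtype=float)
        if np.any((pos < 0) | (pos > 1)):
            raise ValueError("positions must lie in [0, 1] (fraction of body length)")
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted rostro-caudally")


def body_wave_peak_times(model: BodyWaveModel, n_cycles: int) -> pd.DataFrame:
    """Times of peak cupular deflection per neuromast and tail-beat cycle.

    ``t_peak(x, c) = (c + x / lambda_body) / f``: within every cycle the
    deflection peak sweeps rostro-caudally along the body.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    f = model.tail_beat_frequency
    rows = [
        {"position": x, "cycle": c, "t_peak": (c + x / model.body_wavelength) / f}
        for c in range(n_cycles)
        for x in model.positions
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full synthetic dataset

# Per-group sensor presets: (params, target R_S during swims).  Group 2 mixes
# the two adaptation regimes at weak inhibition; groups 1 and 3 are strongly
# inhibited with weak and strong adaptation respectively.  The adapting
# preset needs evoked drive >> spontaneous drive and slow regeneration so the
# pool recovers between stimulus epochs and is dumped at each onset.
GROUP_PRESETS: dict[int, dict] = {
    1: {"params": [SensorParams(k1=0.6, k3=4.0, s0=20.0)], "target_rs": 0.2},
    2: {
        "params": [
            SensorParams(k1=0.6, k3=4.0, s0=20.0),
            SensorParams(k1=12.0, k3=0.3, s0=0.4),
        ],
        "target_rs": 0.9,
    },
    3: {"params": [SensorParams(k1=12.0, k3=0.3, s0=0.4)], "target_rs": 0.2},
}


@dataclass
class SyntheticDataset:
    """Labeled spike table plus epochs and the ground-truth manifest."""

    table: pd.DataFrame
    epochs: pd.DataFrame
    manifest: dict

    def cell_epochs(self, cell_id: str, kind: str) -> pd.DataFrame:
        df = self.epochs
        sel = (df["kind"] == kind) & (df["cell_id"].isin([cell_id, "*"]))
        return df[sel][["start_s", "end_s"]].reset_index(drop=True)


def _simulate_cells(
    p_b_chunk_fn, p_c: np.ndarray, n_steps: int, n_cells: int,
    rng: np.random.Generator, chunk: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential two-state simulation of many heterogeneous cells.

    Returns (step_indices, cell_indices) of all spikes.  The state is a
    vector over cells; chunks keep the per-step Python overhead small.
    """
    sens = np.ones(n_cells, dtype=bool)
    steps_out, cells_out = [], []
    for start in range(0, n_steps, chunk):
        stop = min(start + chunk, n_steps)
        pb = p_b_chunk_fn(start, stop)  # (stop-start, n_cells)
        u = rng.random((stop - start, n_cells))
        spk = np.zeros_like(pb, dtype=bool)
        for i in range(stop - start):
            fire = sens & (u[i] < pb[i])
            regen = (~sens) & (u[i] < p_c)
            spk[i] = fire
            sens = (sens & ~fire) | regen
        t_idx, c_idx = np.nonzero(spk)
        steps_out.append(t_idx + start)
        cells_out.append(c_idx)
    return np.concatenate(steps_out), np.concatenate(cells_out)


def generate_dataset(
    n_cells: int = 30,
    group_mixture: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    protocol: Protocol | None = None,
    swim_model: SwimBoutModel | None = None,
    seed: int = 0,
    sampling_rate: float = 2000.0,
    jitter: float = 0.15,
) -> SyntheticDataset:
    """Simulate a heterogeneous set of cells through the full protocol.

    Cells are assigned to the three response types in the proportions of
    ``group_mixture``; each cell gets its own swim-bout train, a CD
    schedule (inhibition ``k2`` active exactly during its swims,
    calibrated per cell to the group's target R_S at the resting state),
    and log-normal parameter jitter of relative width ``jitter``.
    """
    mix = np.asarray(group_mixture, dtype=float)
    if mix.size != 3 or abs(mix.sum() - 1) > 1e-9 or np.any(mix < 0):
        raise ValueError("group_mixture must be 3 non-negative proportions summing to 1")
    n_groups = int((mix > 0).sum())
    if n_cells < n_groups:
        raise ValueError(f"n_cells={n_cells} < number of nonzero groups ({n_groups})")
    protocol = protocol or generate_protocol()
    swim_model = swim_model or SwimBoutModel()
    rng = np.random.default_rng(seed)

    # largest-remainder apportionment of cells to groups
    raw = mix * n_cells
    counts = np.floor(raw).astype(int)
    rem = n_cells - counts.sum()
    counts[np.argsort(raw - counts)[::-1][:rem]] += 1

    grid = SimulationGrid(
        stimulus_frequency=protocol.frequency,
        sampling_rate=sampling_rate,
        n_wavelengths=protocol.intervals_per_epoch,
    )
    lam = grid.lambda_star
    n_steps = int(round(protocol.session_length * sampling_rate))
    t_axis = np.arange(n_steps) / sampling_rate

    # stimulus value per step (half-wave-rectified sine inside on-epochs)
    stim_vals = np.zeros(n_steps)
    for _, ep in protocol.stimulus_epochs.iterrows():
        sel = (t_axis >= ep["start_s"]) & (t_axis < ep["end_s"])
        stim_vals[sel] = np.clip(
            np.sin(2 * np.pi * protocol.frequency * (t_axis[sel] - ep["start_s"])), 0, None
        )

    cells, swim_tables = [], {}
    swim_mask = np.zeros((n_steps, n_cells), dtype=bool)
    idx = 0
    for group, n_g in zip((1, 2, 3), counts):
        preset = GROUP_PRESETS[group]
        for j in range(n_g):
            base = preset["params"][j % len(preset["params"])]
            params = SensorParams(
                k1=base.k1 * rng.lognormal(0, jitter),
                k3=base.k3 * rng.lognormal(0, jitter),
                s0=base.s0 * rng.lognormal(0, jitter),
            )
            target = float(
                np.clip(preset["target_rs"] + rng.uniform(-0.03, 0.03), 0.05, 1.0)
            )
            k2 = calibrate_inhibition(params, grid, target, method="stationary")
            cell_id = f"cell{idx:03d}"
            swims = generate_swim_bouts(
                swim_model, protocol.session_length,
                seed=int(rng.integers(2**31)),
            )
            swim_tables[cell_id] = swims
            for _, sw in swims.iterrows():
                swim_mask[
                    (t_axis >= sw["start_s"]) & (t_axis < sw["end_s"]), idx
                ] = True
            cells.append(
                {"cell_id": cell_id, "group": group, "params": params,
                 "k2": k2, "target_rs": target}
            )
            idx += 1

    k1v = np.array([c["params"].k1 for c in cells])
    k3v = np.array([c["params"].k3 for c in cells])
    s0v = np.array([c["params"].s0 for c in cells])
    k2v = np.array([c["k2"] for c in cells])
    p_c = np.minimum(k3v * lam, 1.0)

    def p_b_chunk(start: int, stop: int) -> np.ndarray:
        k2_t = np.where(swim_mask[start:stop, :], k2v[None, :], 1.0)
        drive = k1v[None, :] * stim_vals[start:stop, None] + k2_t * s0v[None, :]
        return np.clip(drive * lam, 0.0, 1.0)

    steps, cell_idx = _simulate_cells(p_b_chunk, p_c, n_steps, n_cells, rng)

    tables = []
    for i, cell in enumerate(cells):
        times = steps[cell_idx == i] / sampling_rate
        tables.append(
            label_spikes(
                times,
                protocol.stimulus_epochs,
                swim_tables[cell["cell_id"]],
                frequency=protocol.frequency,
                cell_id=cell["cell_id"],
            )
        )
    table = pd.concat(tables, ignore_index=True)

    ep_rows = [
        {"cell_id": "*", "kind": "stimulus", "start_s": r["start_s"], "end_s": r["end_s"]}
        for _, r in protocol.stimulus_epochs.iterrows()
    ]
    for cell_id, swims in swim_tables.items():
        ep_rows += [
            {"cell_id": cell_id, "kind": "swim", "start_s": r["start_s"], "end_s": r["end_s"]}
            for _, r in swims.iterrows()
        ]
    epochs = pd.DataFrame(ep_rows, columns=["cell_id", "kind", "start_s", "end_s"])

    manifest = {
        "seed": seed,
        "frequency_hz": protocol.frequency,
        "n_sweeps": protocol.n_sweeps,
        "session_length_s": protocol.session_length,
        "sampling_rate_hz": sampling_rate,
        "cells": [
            {
                "cell_id": c["cell_id"], "group": c["group"],
                "k1": c["params"].k1, "k3": c["params"].k3, "s0": c["params"].s0,
                "k2": c["k2"], "target_rs": c["target_rs"],
            }
            for c in cells
        ],
    }
    return SyntheticDataset(table=table, epochs=epochs, manifest=manifest)


# ---------------------------------------------------------------------------
# Spike-table and epoch-table CSV I/O

SPIKE_COLUMNS = [
    "cell_id", "frequency_hz", "sweep", "time_s", "evoked", "cd_on", "interval_index",
]
EPOCH_COLUMNS = ["cell_id", "kind", "start_s", "end_s"]


def write_spike_table(table: pd.DataFrame, path) -> None:
    """Write a labeled spike table as CSV (full float precision)."""
    missing = [c for c in SPIKE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spike table is missing required column(s): {missing}")
    table.to_csv(path, index=False)


def read_spike_table(path) -> pd.DataFrame:
    """Read a spike-table CSV, validating the required columns."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed spike table {path}: {err}") from err
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table {path} is missing required column(s): {missing}")
    df["evoked"] = df["evoked"].astype(bool)
    df["cd_on"] = df["cd_on"].astype(bool)
    df["interval_index"] = pd.array(df["interval_index"], dtype="Int64")
    return df


def write_epoch_table(epochs: pd.DataFrame, path) -> None:
    missing = [c for c in EPOCH_COLUMNS if c not in epochs.columns]
    if missing:
        raise ValueError(f"epoch table is missing required column(s): {missing}")
    epochs.to_csv(path, index=False)


def read_epoch_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed epoch table {path}: {err}") from err
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epoch table {path} is missing required column(s): {missing}")
    return df
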