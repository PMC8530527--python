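"""Circular statistics of stimulus-locked spike trains.

Within a stimulus interval of period ``T`` the phase of a spike at time
``t`` is the fraction ``(t mod T) / T``, stored in radians as
``theta = 2*pi*(t mod T)/T`` for all trigonometry.  The main quantities:

* vector strength ``VS = |mean resultant|`` of the spike phases on the
  unit circle, with circular variance ``sigma^2 = -2 log(VS)``;
* phase quantiles (0.1 / 0.5 / 0.9) of the phases unwrapped to
  ``(-pi, pi]`` around a reference median — the 0.1–0.9 spread is the
  *response interval*;
* spike gain = spike count x VS, which is bounded above by the count and
  discriminates a burst spread over the whole cycle from a single
  precisely timed spike.

Phases are compared across cells after subtracting each cell's median
phase measured with the corollary discharge off, which removes
cell-specific conduction delays.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "spike_phases",
    "vector_strength",
    "circular_variance",
    "reference_median",
    "center_phases",
    "phase_quantiles",
    "response_gain",
    "per_interval_summary",
    "psth",
    "isi",
]


def spike_phases(
    spike_times: np.ndarray, stimulus_onset: float, period: float
) -> pd.DataFrame:
    """Phase and stimulus-interval index of each spike.

    Returns a DataFrame with columns ``theta`` (radians in [0, 2*pi)),
    ``fraction`` (t/T in [0, 1)) and ``interval_index``
    (= floor((t - onset)/T)).  Spikes before the onset are an error.
    """
    t = np.asarray(spike_times, dtype=float)
    if period <= 0:
        raise ValueError("period must be > 0")
    if np.any(t < stimulus_onset):
        raise ValueError("spike times before the stimulus onset")
    rel = t - stimulus_onset
    interval = np.floor(rel / period).astype(int)
    fraction = rel / period - interval
    return pd.DataFrame(
        {"theta": 2 * np.pi * fraction, "fraction": fraction, "interval_index": interval}
    )


def vector_strength(phases: np.ndarray) -> float:
    """Length of the mean resultant vector of phases (radians)."""
    ph = np.asarray(phases, dtype=float)
    if ph.size == 0:
        raise ValueError("vector_strength requires at least one spike")
    return float(np.hypot(np.cos(ph).sum(), np.sin(ph).sum()) / ph.size)


def circular_variance(vs: float) -> float:
    """Circular variance -2 log(VS); +inf at VS = 0."""
    if vs < 0 or vs > 1:
        raise ValueError("vs must be in [0, 1]")
    if vs == 0:
        return math.inf
    return -2.0 * math.log(vs)


def reference_median(phases: np.ndarray) -> float:
    """Median phase of a concentrated sample, robust to wraparound.

    Phases are unwrapped to ``(-pi, pi]`` around the circular mean angle
    before taking the ordinary median; intended for the per-cell CD-OFF
    reference used to normalize conduction delays.
    """
    ph = np.asarray(phases, dtype=float)
    if ph.size == 0:
        raise ValueError("reference_median requires at least one spike")
    mean_angle = math.atan2(np.sin(ph).sum(), np.cos(ph).sum())
    unwrapped = _wrap(ph - mean_angle) + mean_angle
    return float(np.median(unwrapped))


def _wrap(delta: np.ndarray) -> np.ndarray:
    """Map angles to (-pi, pi]."""
    out = np.mod(np.asarray(delta, dtype=float) + np.pi, 2 * np.pi) - np.pi
    out[out == -np.pi] = np.pi
    return out


def center_phases(phases: np.ndarray, reference: float) -> np.ndarray:
    """Subtract a reference phase and wrap the result to (-pi, pi]."""
    return _wrap(np.asarray(phases, dtype=float) - reference)


def phase_quantiles(
    phases: np.ndarray, probs: tuple[float, ...] = (0.1, 0.5, 0.9)
) -> np.ndarray:
    """Linear-interpolation quantiles of centered phases.

    Input phases are wrapped to ``(-pi, pi]`` (they should already be
    centered on their CD-OFF reference median, so the response is
    concentrated away from the cut at +-pi) and quantiles are computed by
    the ordinary sort-and-interpolate (type-7) estimator.
    """
    ph = np.asarray(phases, dtype=float)
    if ph.size == 0:
        raise ValueError("phase_quantiles requires at least one spike")
    return np.quantile(_wrap(ph), probs)


def response_gain(n: int, vs: float) -> float:
    """Spike gain: count times vector strength (always <= count)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= vs <= 1.0:
        raise ValueError("vs must be in [0, 1]")
    return n * vs


def _summary_row(thetas: np.ndarray, n_sweeps: int) -> dict:
    n = thetas.size
    if n == 0:
        return {
            "n": 0, "n_mean": 0.0, "q10": np.nan, "q50": np.nan, "q90": np.nan,
            "width": np.nan, "vs": np.nan, "gain": np.nan,
        }
    q10, q50, q90 = phase_quantiles(thetas)
    vs = vector_strength(thetas)
    n_mean = n / n_sweeps
    return {
        "n": n, "n_mean": n_mean, "q10": q10, "q50": q50, "q90": q90,
        "width": q90 - q10, "vs": vs, "gain": response_gain(n, vs) / n_sweeps,
    }


def per_interval_summary(table: pd.DataFrame, frequency: float) -> pd.DataFrame:
    """Per-stimulus-interval phase summary, split by CD state.

    ``table`` is a labeled spike table (see `reafference.cd_analysis`)
    with at least the columns ``evoked``, ``cd_on``, ``interval_index``,
    ``theta`` and ``sweep``; rows flagged ``burn_in`` are dropped if the
    column is present.  Phases are centered on the cell's CD-OFF reference
    median before quantiles.  Intervals with no spikes in one CD state get
    a row with ``n = 0`` and missing phase fields.
    """
    df = table
    if "burn_in" in df.columns:
        df = df[df["burn_in"] == 0]
    ev = df[df["evoked"].astype(bool)].copy()
    if ev.empty:
        raise ValueError("no evoked spikes to summarize")
    n_sweeps = int(df["sweep"].nunique()) if "sweep" in df.columns else 1
    off = ev[~ev["cd_on"].astype(bool)]
    ref = reference_median(off["theta"].to_numpy()) if len(off) else 0.0
    ev["theta_c"] = center_phases(ev["theta"].to_numpy(), ref)

    intervals = np.arange(int(ev["interval_index"].max()) + 1)
    rows = []
    for cd_state, sub in (("off", ev[~ev["cd_on"].astype(bool)]), ("on", ev[ev["cd_on"].astype(bool)])):
        grouped = {k: v["theta_c"].to_numpy() for k, v in sub.groupby("interval_index")}
        for idx in intervals:
            row = _summary_row(grouped.get(idx, np.empty(0)), n_sweeps)
            row.update(
                interval_index=int(idx), cd_state=cd_state, frequency_hz=frequency,
                reference_median=ref,
            )
            rows.append(row)
    cols = [
        "frequency_hz", "interval_index", "cd_state", "n", "n_mean",
        "q10", "q50", "q90", "width", "vs", "gain", "reference_median",
    ]
    return pd.DataFrame(rows)[cols]


def psth(
    spike_times: np.ndarray,
    n_sweeps: int,
    sweep_length: float,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Cross-sweep mean firing rate in fixed bins aligned to sweep start.

    ``spike_times`` are in seconds relative to sweep start, pooled over
    ``n_sweeps`` sweeps.  Bins exactly partition ``[0, sweep_length]``
    (the requested width is adjusted to the nearest exact divisor), so
    ``sum(rate * width) * n_sweeps`` recovers the total spike count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    n_bins = max(1, int(round(sweep_length / bin_width)))
    edges = np.linspace(0.0, sweep_length, n_bins + 1)
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float), bins=edges)
    width = sweep_length / n_bins
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
            "rate": counts / (n_sweeps * width),
        }
    )


def isi(spike_times: np.ndarray) -> np.ndarray:
    """Interspike intervals of a sorted spike-time sequence."""
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    return np.diff(t)
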