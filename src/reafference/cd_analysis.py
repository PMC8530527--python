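"""Analysis of corollary-discharge modulation in labeled spike tables.

Every spike of a recording is labeled on two independent axes:

* **evoked / spontaneous** — inside or outside a stimulus-on epoch;
* **CD ON / CD OFF** — inside or outside a swim bout (the corollary
  discharge is active strictly during swimming).

The effect of the CD is quantified by the ratios of spike rates
``R_S = spontaneous rate CD ON / CD OFF`` and ``R_E = evoked rate CD ON /
CD OFF``; rates are per unit *exposure time* in each cell of the 2x2
label grid, since ON and OFF observation times differ.  Adaptation is the
ratio of mean evoked counts in the first two versus last two stimulus
intervals.  Cells (one point per cell x frequency) separate into response
types by k-means clustering in the (R_S, R_E) plane, and the dependence of
R_E on R_S and adaptation is summarized by a fixed-effects least-squares
regression with an R_S x adaptation interaction (no intercept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans

from .spike_metrics import (
    center_phases,
    phase_quantiles,
    reference_median,
    response_gain,
    vector_strength,
)

__all__ = [
    "label_spikes",
    "exposure_times",
    "ActivityRatios",
    "activity_ratios",
    "AdaptationIndex",
    "adaptation_index",
    "ResponseCluster",
    "cluster_response_types",
    "InteractionRegression",
    "interaction_regression",
    "classify_swims",
    "swim_normalized_timecourse",
]


def _as_epochs(epochs) -> np.ndarray:
    """Coerce an epoch table to a (n, 2) float array of [start, end)."""
    if isinstance(epochs, pd.DataFrame):
        arr = epochs[["start_s", "end_s"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(epochs, dtype=float).reshape(-1, 2)
    if arr.size and np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("epochs must have end > start")
    order = np.argsort(arr[:, 0]) if arr.size else slice(None)
    return arr[order]


def _check_non_overlapping(arr: np.ndarray, kind: str) -> None:
    if len(arr) > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
        raise ValueError(f"overlapping {kind} epochs")


def _membership(t: np.ndarray, arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each time, whether it falls in an epoch [start, end) and which."""
    if len(arr) == 0:
        return np.zeros(t.shape, dtype=bool), np.full(t.shape, -1)
    idx = np.searchsorted(arr[:, 0], t, side="right") - 1
    inside = (idx >= 0) & (t < arr[np.clip(idx, 0, None), 1])
    return inside, np.where(inside, idx, -1)


def label_spikes(
    spike_times: np.ndarray,
    stimulus_epochs,
    swim_epochs,
    frequency: float,
    cell_id: str = "cell",
) -> pd.DataFrame:
    """Label every spike as evoked/spontaneous and CD ON/OFF.

    Epoch boundaries are half-open ``[start, end)``.  Evoked spikes also
    get a stimulus-interval index (``floor((t - epoch_start) / T)``) and a
    phase ``theta`` in radians.  ``sweep`` is the index of the current or
    most recent stimulus epoch.
    """
    t = np.asarray(spike_times, dtype=float)
    stim = _as_epochs(stimulus_epochs)
    swim = _as_epochs(swim_epochs)
    _check_non_overlapping(stim, "stimulus")
    _check_non_overlapping(swim, "swim")
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    period = 1.0 / frequency

    evoked, stim_idx = _membership(t, stim)
    cd_on, _ = _membership(t, swim)
    rel = np.where(evoked, t - stim[np.clip(stim_idx, 0, None), 0], 0.0)
    # small epsilon so a spike nominally on an interval boundary is not pushed
    # into the previous interval by floating-point subtraction error
    frac_total = rel / period + 1e-9
    interval = np.where(evoked, np.floor(frac_total), -1).astype(int)
    frac = np.clip(frac_total - interval, 0.0, None)
    theta = np.where(evoked, 2 * np.pi * frac, np.nan)
    sweep = (
        np.clip(np.searchsorted(stim[:, 0], t, side="right") - 1, 0, None)
        if len(stim)
        else np.zeros(t.shape, dtype=int)
    )
    df = pd.DataFrame(
        {
            "cell_id": cell_id,
            "frequency_hz": frequency,
            "sweep": sweep,
            "time_s": t,
            "evoked": evoked,
            "cd_on": cd_on,
            "interval_index": pd.array(
                np.where(evoked, interval, -1), dtype="Int64"
            ),
            "theta": theta,
        }
    )
    df.loc[~df["evoked"], "interval_index"] = pd.NA
    return df


def _total_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Total length of the intersection of two unions of intervals."""
    if len(a) == 0 or len(b) == 0:
        return 0.0
    lo = np.maximum(a[:, 0][:, None], b[:, 0][None, :])
    hi = np.minimum(a[:, 1][:, None], b[:, 1][None, :])
    return float(np.clip(hi - lo, 0.0, None).sum())


def exposure_times(
    stimulus_epochs, swim_epochs, session_length: float
) -> dict[tuple[bool, bool], float]:
    """Observation time in each (evoked, cd_on) cell of the label grid."""
    stim = _as_epochs(stimulus_epochs)
    swim = _as_epochs(swim_epochs)
    t_stim = float((stim[:, 1] - stim[:, 0]).sum()) if len(stim) else 0.0
    t_swim = float((swim[:, 1] - swim[:, 0]).sum()) if len(swim) else 0.0
    both = _total_overlap(stim, swim)
    return {
        (True, True): both,
        (True, False): t_stim - both,
        (False, True): t_swim - both,
        (False, False): session_length - t_stim - t_swim + both,
    }


@dataclass(frozen=True)
class ActivityRatios:
    """CD ON/OFF rate ratios for one cell x frequency."""

    r_s: float
    r_e: float
    rates: dict
    exposures: dict
    counts: dict


def activity_ratios(
    table: pd.DataFrame,
    stimulus_epochs,
    swim_epochs,
    session_length: float,
) -> ActivityRatios:
    """R_S and R_E from exposure-time-normalized spike rates.

    Rates are spikes per second of exposure in each (evoked, CD) cell;
    the ratios divide CD ON by CD OFF.  A zero CD-OFF rate (or zero
    exposure) in either condition is an error, since the ratio would be
    undefined.
    """
    exp = exposure_times(stimulus_epochs, swim_epochs, session_length)
    counts = {
        key: int(((table["evoked"] == key[0]) & (table["cd_on"] == key[1])).sum())
        for key in exp
    }
    rates = {}
    for key in exp:
        if exp[key] <= 0:
            raise ValueError(f"zero exposure time for (evoked={key[0]}, cd_on={key[1]})")
        rates[key] = counts[key] / exp[key]
    for ev in (True, False):
        if rates[(ev, False)] == 0:
            raise ValueError(
                "zero CD-OFF rate in the "
                + ("evoked" if ev else "spontaneous")
                + " condition: ratio undefined"
            )
    return ActivityRatios(
        r_s=rates[(False, True)] / rates[(False, False)],
        r_e=rates[(True, True)] / rates[(True, False)],
        rates=rates,
        exposures=exp,
        counts=counts,
    )


@dataclass(frozen=True)
class AdaptationIndex:
    """Mean count of the first 2 stimulus intervals vs the last 2."""

    first_over_last: float
    last_over_first: float
    defined: bool = True


def adaptation_index(interval_counts: np.ndarray) -> AdaptationIndex:
    """Adaptation from per-interval evoked counts (CD OFF spikes only).

    Requires at least 4 intervals.  A zero mean in the last two intervals
    leaves First/Last undefined (NaN, ``defined=False``).
    """
    c = np.asarray(interval_counts, dtype=float)
    if c.size < 4:
        raise ValueError("adaptation index requires >= 4 stimulus intervals")
    first = c[:2].mean()
    last = c[-2:].mean()
    if last == 0:
        return AdaptationIndex(np.nan, 0.0 if first > 0 else np.nan, defined=False)
    if first == 0:
        return AdaptationIndex(0.0, np.nan, defined=False)
    return AdaptationIndex(first / last, last / first, defined=True)


@dataclass(frozen=True)
class ResponseCluster:
    """k-means response types in the (R_S, R_E) plane.

    ``labels`` are 1-based group numbers in canonical order (ascending
    adaptation: group 1 = weakest adaptation); ``centroids`` are on the
    original (r_s, r_e) scale; ``delta_inhibition`` is the per-group mean
    of r_s - r_e (0 when spontaneous and evoked activity are equally
    suppressed).
    """

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    delta_inhibition: np.ndarray
    inertia: float


def cluster_response_types(
    r_s: np.ndarray,
    r_e: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 50,
    adaptation: np.ndarray | None = None,
) -> ResponseCluster:
    """Cluster cells into response types by k-means on (R_S, R_E).

    Features are standardized to unit variance before clustering; 50
    restarts with a fixed seed make the result reproducible.  Groups are
    relabeled canonically: ascending mean ``adaptation`` (First/Last
    evoked counts) when given, otherwise a heuristic that places the
    divergent group (r_e >> r_s) last and orders the remaining groups by
    ascending r_s.
    """
    pts = np.column_stack([np.asarray(r_s, float), np.asarray(r_e, float)])
    if len(pts) < k:
        raise ValueError(f"need at least k={k} points, got {len(pts)}")
    scale = pts.std(axis=0, ddof=0)
    if np.any(scale == 0):
        if np.all(pts == pts[0]):
            raise ValueError("all points identical: clustering degenerate")
        scale = np.where(scale == 0, 1.0, scale)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(pts / scale)

    if adaptation is not None:
        keyvals = np.asarray(adaptation, dtype=float)
        order = np.argsort(
            [np.nanmean(keyvals[raw == g]) for g in range(k)], kind="stable"
        )
    else:
        div = [np.mean(pts[raw == g, 1] - pts[raw == g, 0]) for g in range(k)]
        rs_mean = [np.mean(pts[raw == g, 0]) for g in range(k)]
        # divergent group (r_e - r_s largest) last, others by ascending r_s
        order = sorted(range(k), key=lambda g: (div[g] > np.mean(div) + 1e-12, rs_mean[g]))
        order = np.asarray(order)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    centroids = np.vstack([pts[labels == g].mean(axis=0) for g in range(1, k + 1)])
    delta = np.array([
        np.mean(pts[labels == g, 0] - pts[labels == g, 1]) for g in range(1, k + 1)
    ])
    return ResponseCluster(
        k=k, labels=labels, centroids=centroids, delta_inhibition=delta,
        inertia=float(km.inertia_),
    )


@dataclass(frozen=True)
class InteractionRegression:
    """OLS fit of R_E on R_S, adaptation and their interaction (no intercept)."""

    coef: dict
    conf_int: dict
    pvalues: dict
    result: object

    def significant(self, name: str, alpha: float = 0.05) -> bool:
        return self.pvalues[name] < alpha


def interaction_regression(
    r_e: np.ndarray, r_s: np.ndarray, adaptation: np.ndarray
) -> InteractionRegression:
    """Least-squares R_E ~ 0 + R_S + adaptation + R_S:adaptation.

    The regression is forced through zero so the approximate 95%
    confidence intervals of the predictors can be compared against 0.
    This is a fixed-effects simplification of a mixed-effects analysis
    (no per-individual or per-frequency random effects).
    """
    y = np.asarray(r_e, dtype=float)
    rs = np.asarray(r_s, dtype=float)
    ad = np.asarray(adaptation, dtype=float)
    if y.size < 10:
        raise ValueError("interaction regression requires >= 10 units")
    X = np.column_stack([rs, ad, rs * ad])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design matrix")
    names = ["r_s", "adaptation", "r_s:adaptation"]
    fit = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    ci = fit.conf_int(alpha=0.05)
    return InteractionRegression(
        coef=dict(fit.params),
        conf_int={n: tuple(ci.loc[n]) for n in names},
        pvalues=dict(fit.pvalues),
        result=fit,
    )


def classify_swims(swim_epochs, stimulus_epochs) -> pd.DataFrame:
    """Tag each swim bout as fully within / outside / straddling a stimulus.

    Returns a DataFrame (start_s, end_s, duration_s, classification);
    straddling swims are excluded from evoked and spontaneous time
    courses alike.
    """
    swim = _as_epochs(swim_epochs)
    stim = _as_epochs(stimulus_epochs)
    rows = []
    for s, e in swim:
        overlap = _total_overlap(np.array([[s, e]]), stim)
        if overlap == 0:
            cls = "outside"
        elif np.any((stim[:, 0] <= s) & (e <= stim[:, 1])):
            cls = "within"
        else:
            cls = "straddling"
        rows.append({"start_s": s, "end_s": e, "duration_s": e - s, "classification": cls})
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s", "classification"])


def swim_normalized_timecourse(
    table: pd.DataFrame,
    swims: pd.DataFrame,
    n_bins: int = 20,
    kind: str = "evoked",
) -> pd.DataFrame:
    """Binned spike activity over swim bouts normalized to unit duration.

    Each eligible swim (fully within a stimulus epoch for ``kind=
    "evoked"``, fully outside for ``"spontaneous"``) is mapped to relative
    time: the bout spans [0, 1] and an equal-duration post-swim window
    spans (1, 2].  Per bin the mean spike count per swim (scale-invariant)
    and the mean rate in spikes/s are reported, together with pooled phase
    quantiles, vector strength and gain for evoked spikes.  Bin estimates
    carry the number of contributing swims as their weight.
    """
    if kind not in ("evoked", "spontaneous"):
        raise ValueError("kind must be 'evoked' or 'spontaneous'")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    want_cls = "within" if kind == "evoked" else "outside"
    eligible = swims[swims["classification"] == want_cls]
    if eligible.empty:
        raise ValueError(f"no eligible swims for kind={kind!r}")
    spikes = table[table["evoked"].astype(bool) == (kind == "evoked")]
    t = spikes["time_s"].to_numpy()
    theta = spikes["theta"].to_numpy() if "theta" in spikes.columns else np.full(t.shape, np.nan)

    edges = np.linspace(0.0, 2.0, n_bins + 1)
    width = 2.0 / n_bins
    counts = np.zeros((len(eligible), n_bins))
    durations = eligible["duration_s"].to_numpy()
    theta_bins: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    for i, (_, swim) in enumerate(eligible.iterrows()):
        s, dur = swim["start_s"], swim["duration_s"]
        in_win = (t >= s) & (t < s + 2 * dur)
        rel = (t[in_win] - s) / dur
        b = np.minimum((rel / width).astype(int), n_bins - 1)
        np.add.at(counts[i], b, 1)
        for bi in np.unique(b):
            theta_bins[bi].append(theta[in_win][b == bi])

    n_swims = len(eligible)
    rate = counts / (width * durations[:, None])  # spikes/s per swim per bin
    rows = []
    if kind == "evoked":
        finite = theta[np.isfinite(theta)]
        ref = reference_median(finite) if finite.size else 0.0
    for b in range(n_bins):
        row = {
            "rel_time": 0.5 * (edges[b] + edges[b + 1]),
            "n_swims": n_swims,
            "count_mean": counts[:, b].mean(),
            "rate": rate[:, b].mean(),
        }
        pooled = (
            np.concatenate(theta_bins[b]) if theta_bins[b] else np.empty(0)
        )
        pooled = pooled[np.isfinite(pooled)]
        if kind == "evoked" and pooled.size:
            centered = center_phases(pooled, ref)
            q10, q50, q90 = phase_quantiles(centered)
            vs = vector_strength(centered)
            row.update(q10=q10, q50=q50, q90=q90, vs=vs,
                       gain=response_gain(counts[:, b].mean(), vs))
        else:
            row.update(q10=np.nan, q50=np.nan, q90=np.nan, vs=np.nan, gain=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
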