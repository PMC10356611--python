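"""ΔF/F computation and event-aligned calcium statistics.

Raw two-photon recordings arrive as per-volume scalars: a pooled cell
fluorescence ``F_cell(t)`` and a pooled non-cell background
``F_background(t)``, stamped at the half-completion time of each volume
scan.  The background is subtracted first,
``F_actual(t) = F_cell(t) - F_background(t)``, which removes
autofluorescence and detector offset; ΔF/F is then
``(F_actual(t) - F0(t)) / F0(t)`` with ``F0(t)`` a centered running mean of
``F_actual`` over a long (20 min) window, truncated at the recording
edges.  For optogenetic sessions, samples within 105 s of each stimulation
onset are masked out of the ``F0`` estimate so stimulation transients do
not contaminate the baseline.  Everything downstream (triggered averages,
cross-correlations, slope statistics) operates on a common 10 Hz grid
filled by previous-neighbour interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import boxcar_smooth

__all__ = [
    "FluorescenceRecording",
    "DffTrace",
    "AlignedEnsemble",
    "compute_dff",
    "resample_previous_neighbour",
    "boxcar",
    "triggered_average",
    "cross_correlate",
    "slope_to_threshold",
    "stim_response_bins",
    "STIM_BIN_EDGES",
]


@dataclass(frozen=True)
class FluorescenceRecording:
    """Per-volume pooled fluorescence (cell and background channels)."""

    volume_t: np.ndarray
    F_cell: np.ndarray
    F_background: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.volume_t, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("volume_t must be strictly increasing")
        object.__setattr__(self, "volume_t", t)
        object.__setattr__(self, "F_cell", np.asarray(self.F_cell, float))
        object.__setattr__(self, "F_background", np.asarray(self.F_background, float))
        if not (len(t) == len(self.F_cell) == len(self.F_background)):
            raise ValueError("channel lengths must match volume_t")


@dataclass
class DffTrace:
    """ΔF/F on the common 10 Hz grid (0.1 s spacing exactly).

    ``dff`` is NaN where F0 was non-positive or before the first volume;
    ``stim_mask`` flags samples inside post-stimulation blanking windows.
    """

    t: np.ndarray
    dff: np.ndarray
    stim_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.dff = np.asarray(self.dff, float)
        if self.stim_mask is None:
            self.stim_mask = np.zeros(len(self.t), dtype=bool)
        if len(self.t) > 1 and not np.allclose(np.diff(self.t), 0.1, atol=1e-9):
            raise ValueError("DffTrace grid spacing must be exactly 0.1 s")


@dataclass
class AlignedEnsemble:
    """Event-aligned traces with per-timepoint mean, s.e.m. and n."""

    rel_t: np.ndarray
    traces: np.ndarray  # (n_events, n_rel) with NaN for unavailable samples
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rel_t_s": self.rel_t, "mean": self.mean, "sem": self.sem, "n": self.n}
        )


def _running_mean_time_window(
    t: np.ndarray, x: np.ndarray, window_s: float
) -> np.ndarray:
    """Centered running mean over a time window, edge-truncated, NaN-aware."""
    half = window_s / 2.0
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(finite.astype(int))))
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    tot = csum[hi] - csum[lo]
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)


def compute_dff(
    rec: FluorescenceRecording,
    window_s: float = 1200.0,
    stim_schedule: np.ndarray | None = None,
    stim_blank_s: float = 105.0,
    grid_hz: float = 10.0,
    fixed_f0: bool = False,
) -> DffTrace:
    """Background-subtracted, baseline-normalised ΔF/F on the 10 Hz grid.

    ``F0`` is the centered running mean of ``F_cell - F_background`` over
    ``window_s`` (default 20 min), truncated at the recording edges.  When
    a ``stim_schedule`` (array of stimulation onset times) is given,
    samples within ``stim_blank_s`` after each onset are excluded from the
    ``F0`` estimate and flagged in the output ``stim_mask``.  With
    ``fixed_f0`` the running mean is replaced by a single whole-recording
    constant baseline (robustness variant).

    Samples where ``F0 <= 0`` become NaN; a recording whose ΔF/F is NaN
    everywhere raises ``ValueError``.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t = rec.volume_t
    if t[-1] - t[0] < 120.0:
        raise ValueError("recording must span at least 2 minutes")
    f_actual = rec.F_cell - rec.F_background

    masked = f_actual.copy()
    stim_flag = np.zeros(len(t), dtype=bool)
    if stim_schedule is not None:
        for onset in np.asarray(stim_schedule, float):
            stim_flag |= (t >= onset) & (t < onset + stim_blank_s)
        masked[stim_flag] = np.nan

    if fixed_f0:
        f0 = np.full(len(t), np.nanmean(masked))
    else:
        f0 = _running_mean_time_window(t, masked, window_s)
    with np.errstate(invalid="ignore", divide="ignore"):
        dff = np.where(f0 > 0, (f_actual - f0) / f0, np.nan)
    if not np.any(np.isfinite(dff)):
        raise ValueError("degenerate recording: F0 non-positive everywhere")

    grid, dff_g = resample_previous_neighbour(dff, t, grid_hz)
    _, mask_g = resample_previous_neighbour(stim_flag.astype(float), t, grid_hz)
    return DffTrace(grid, dff_g, mask_g > 0.5)


def resample_previous_neighbour(
    series: np.ndarray, timestamps: np.ndarray, grid_hz: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Previous-neighbour assignment of a sampled series onto a uniform grid.

    Each grid point takes the value of the latest sample at or before it;
    grid points before the first sample are NaN.  The grid starts at the
    first multiple of the grid step at or after the first timestamp and
    ends at the last timestamp.  Returns ``(grid_t, gridded)``.
    """
    series = np.asarray(series, float)
    timestamps = np.asarray(timestamps, float)
    if len(series) == 0:
        return np.array([]), np.array([])
    step = 1.0 / grid_hz
    start = np.ceil(timestamps[0] / step - 1e-9) * step
    n = int(np.floor((timestamps[-1] - start) / step + 1e-9)) + 1
    if n <= 0:
        return np.array([]), np.array([])
    grid = start + np.arange(n) * step
    idx = np.searchsorted(timestamps, grid + 1e-12, side="right") - 1
    out = np.where(idx >= 0, series[np.maximum(idx, 0)], np.nan)
    return grid, out


def boxcar(series: np.ndarray, width_s: float, dt: float = 0.1) -> np.ndarray:
    """Centered NaN-aware moving average, edge-truncated.

    ``width_s`` is converted to an odd number of samples at spacing
    ``dt``; NaNs are excluded from numerator and denominator alike.
    """
    if width_s <= 0:
        raise ValueError("width_s must be positive")
    n = max(1, int(round(width_s / dt)))
    return boxcar_smooth(np.asarray(series, float), n)


def triggered_average(
    t: np.ndarray,
    trace: np.ndarray,
    event_times: np.ndarray,
    window_s: float,
    exclusion_events: np.ndarray | None = None,
) -> AlignedEnsemble:
    """Event-triggered ensemble of trace segments with mean and s.e.m.

    Each event contributes the trace over ``[-window_s, +window_s]``
    around it (grid-aligned at the sample at or before the event).  When
    ``exclusion_events`` are given — e.g. return transitions back to the
    original substrate — all samples of a contributing segment at or after
    the first exclusion event following that trigger are dropped, so a fly
    returning 20 s after a transition contributes only its first 20 s to
    the post-transition average.  The s.e.m. at each relative time uses
    the count of traces still contributing there.

    Raises ``ValueError`` when no event lies inside the recording.
    """
    t = np.asarray(t, float)
    trace = np.asarray(trace, float)
    event_times = np.asarray(event_times, float)
    dt = t[1] - t[0]
    nw = int(round(window_s / dt))
    rel = np.arange(-nw, nw + 1) * dt
    usable = (event_times >= t[0]) & (event_times <= t[-1])
    events = event_times[usable]
    if len(events) == 0:
        raise ValueError("no usable events inside the recording span")
    excl = (
        np.sort(np.asarray(exclusion_events, float))
        if exclusion_events is not None
        else None
    )
    segs = np.full((len(events), len(rel)), np.nan)
    for k, ev in enumerate(events):
        i0 = int(np.searchsorted(t, ev + 1e-12, side="right") - 1)
        idx = i0 + np.arange(-nw, nw + 1)
        ok = (idx >= 0) & (idx < len(t))
        segs[k, ok] = trace[idx[ok]]
        if excl is not None:
            j = np.searchsorted(excl, ev, side="right")
            if j < len(excl):
                cut = excl[j]
                segs[k, t[np.clip(idx, 0, len(t) - 1)] >= cut - 1e-12] = np.nan
    n = np.sum(np.isfinite(segs), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(np.where(np.isfinite(segs), segs, np.nan), axis=0), np.nan)
        sd = np.full(len(rel), np.nan)
        rows = n > 1
        if np.any(rows):
            sd[rows] = np.nanstd(segs[:, rows], axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return AlignedEnsemble(rel, segs, mean, sem, n)


def cross_correlate(
    t: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    max_lag_s: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of two gridded traces versus lag.

    Sign convention: the correlation at lag ``L`` pairs ``a(t)`` with
    ``b(t + L)``, so if ``b`` is a copy of ``a`` delayed by 3 s
    (``b(t) = a(t - 3)``) the peak sits at lag -3 s.  NaN pairs are
    dropped pairwise; requires at least 10 overlapping finite samples at
    lag zero.

    Returns ``(lags_s, corr)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    t = np.asarray(t, float)
    if len(a) != len(b) or len(a) != len(t):
        raise ValueError("traces must share the grid")
    if np.sum(np.isfinite(a) & np.isfinite(b)) < 10:
        raise ValueError("fewer than 10 overlapping samples")
    dt = t[1] - t[0]
    nlag = int(round(max_lag_s / dt))
    lags = np.arange(-nlag, nlag + 1)
    corr = np.full(len(lags), np.nan)
    for i, L in enumerate(lags):
        if L >= 0:
            x, y = a[: len(a) - L], b[L:]
        else:
            x, y = a[-L:], b[: len(b) + L]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 10:
            xs, ys = x[ok], y[ok]
            sx, sy = xs.std(), ys.std()
            if sx > 0 and sy > 0:
                corr[i] = np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy)
    return lags * dt, corr


def slope_to_threshold(
    dff: DffTrace,
    ovulation_start_s: float,
    bend_complete_s: float,
    smooth_s: float = 5.0,
    end_offset_s: float = 3.3,
) -> float:
    """Net ΔF/F slope from baseline re-crossing to just before the bend.

    The trace is smoothed with a ``smooth_s`` boxcar; the signal minimum
    after ovulation start is located, then the first subsequent time the
    smoothed ΔF/F reaches 0 (``t_start``).  The slope is the smoothed
    value at ``bend_complete_s - end_offset_s`` divided by the time from
    ``t_start`` to that endpoint (the endpoint approximates when the
    abdomen bend begins).  Returns NaN (flagged: excluded from group
    statistics) when the smoothed trace never reaches 0 before the
    endpoint.
    """
    t = dff.t
    y = boxcar(dff.dff, smooth_s, dt=float(t[1] - t[0]))
    te = bend_complete_s - end_offset_s
    ie = int(np.searchsorted(t, te + 1e-12, side="right") - 1)
    i0 = int(np.searchsorted(t, ovulation_start_s - 1e-12, side="left"))
    if ie <= i0 or ie >= len(t):
        return float("nan")
    seg = y[i0 : ie + 1]
    if not np.any(np.isfinite(seg)):
        return float("nan")
    imin = i0 + int(np.nanargmin(seg))
    after = y[imin : ie + 1]
    nonneg = np.flatnonzero(after >= 0)
    if len(nonneg) == 0:
        return float("nan")
    istart = imin + int(nonneg[0])
    t_start = t[istart]
    denom = t[ie] - t_start
    if denom <= 0:
        return float("nan")
    return float(y[ie] / denom)


# Outer catch-all edges 0.02 and 0.52 with five equal 0.10-wide interior bins.
STIM_BIN_EDGES = (0.02, 0.12, 0.22, 0.32, 0.42, 0.52)


def stim_response_bins(
    dff: DffTrace,
    stim_onsets: np.ndarray,
    behaviour: dict[str, np.ndarray] | None = None,
    response_window_s: tuple[float, float] = (1.0, 3.0),
    post_window_s: tuple[float, float] = (2.0, 4.0),
    pre_window_s: tuple[float, float] = (-2.0, 0.0),
    bin_edges=STIM_BIN_EDGES,
) -> pd.DataFrame:
    """Per-stimulation response table binned by evoked ΔF/F.

    Each stimulation is assigned to one of ``len(bin_edges) + 1`` bins by
    the maximum ΔF/F in ``response_window_s`` (default 1-3 s) after onset:
    bin 1 collects responses below the first edge (0.02), the last bin
    collects responses at or above the last edge (0.52), interior bins are
    0.10 wide.  For each behavioural channel the response is the mean over
    ``post_window_s`` (2-4 s after onset) minus the mean over
    ``pre_window_s`` (the 2 s before onset); the sign convention is
    post - pre.  Stimulations whose windows fall off the recording are
    skipped.
    """
    t, y = dff.t, dff.dff
    edges = np.asarray(bin_edges, float)
    rows = []
    for onset in np.asarray(stim_onsets, float):
        lo, hi = onset + response_window_s[0], onset + response_window_s[1]
        if lo < t[0] or onset + post_window_s[1] > t[-1] or onset + pre_window_s[0] < t[0]:
            continue
        sel = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        if not np.any(np.isfinite(y[sel])):
            continue
        m = float(np.nanmax(y[sel]))
        bin_id = int(np.searchsorted(edges, m, side="right")) + 1
        row = {"stim_onset_s": onset, "max_dff": m, "bin": bin_id}
        if behaviour:
            for name, tr in behaviour.items():
                post = (t >= onset + post_window_s[0]) & (t < onset + post_window_s[1])
                pre = (t >= onset + pre_window_s[0]) & (t < onset + pre_window_s[1])
                row[f"delta_{name}"] = float(
                    np.nanmean(tr[post]) - np.nanmean(tr[pre])
                )
        rows.append(row)
    return pd.DataFrame(rows)
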