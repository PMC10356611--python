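"""Quantification of the egg-laying behavioural sequence.

Egg laying in *Drosophila* follows a stereotyped sequence: the fly stands
still while an egg passes from ovary to uterus (ovulation, ~1 min), then
walks around evaluating substrates (the *search period*), and finally bends
its abdomen and deposits the egg.  This module detects and summarises that
sequence from 2 Hz centroid trajectories in two-substrate choice chambers:
per-frame substrate assignment, automated search-onset detection from
locomotor speed, substrate-transition events with boundary-rocking removal,
and pooled choice / leaving statistics with exact binomial confidence
intervals.

Manual annotations (ovulation start, abdomen-bend complete, deposition) are
consumed as given; no pose estimation happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Trajectory",
    "EggLayingSequence",
    "TransitionEvent",
    "BinomialStat",
    "trajectory_speed",
    "assign_substrate",
    "detect_search_start",
    "detect_transitions",
    "binomial_fraction",
    "choice_and_leaving_stats",
    "binary_group_ranksum",
    "per_fly_search_summary",
]


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped positional track of one fly.

    t : seconds, strictly increasing on a uniform grid (2 Hz by default).
    x, y : mm, chamber coordinates.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("trajectory needs at least two frames")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("t must be uniformly sampled")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def speed(self) -> np.ndarray:
        return trajectory_speed(self.t, self.x, self.y)


def trajectory_speed(t: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-frame locomotor speed (mm/s): frame displacement x frame rate.

    The first frame, having no predecessor, gets speed 0.
    """
    t = np.asarray(t, float)
    disp = np.hypot(np.diff(np.asarray(x, float)), np.diff(np.asarray(y, float)))
    speed = np.empty_like(t)
    speed[0] = 0.0
    speed[1:] = disp / np.diff(t)
    return speed


@dataclass(frozen=True)
class EggLayingSequence:
    """Annotated event times (s) for one egg.

    ovulation_start <= search_start <= bend_complete <= deposition.
    ``substrate_at_deposition`` is the label of the half on which the egg
    was deposited; ``fly_id`` groups eggs per animal for cohort summaries.
    """

    ovulation_start_s: float
    search_start_s: float
    bend_complete_s: float
    deposition_s: float
    substrate_at_deposition: str = ""
    fly_id: str = ""

    def __post_init__(self) -> None:
        seq = (
            self.ovulation_start_s,
            self.search_start_s,
            self.bend_complete_s,
            self.deposition_s,
        )
        if any(b < a - 1e-9 for a, b in zip(seq, seq[1:])):
            raise ValueError(f"egg event times out of order: {seq}")

    @property
    def search_duration_s(self) -> float:
        return self.deposition_s - self.search_start_s


@dataclass(frozen=True)
class TransitionEvent:
    """A change of occupied substrate at ``time_s`` (s)."""

    time_s: float
    from_substrate: str
    to_substrate: str

    def __post_init__(self) -> None:
        if self.from_substrate == self.to_substrate:
            raise ValueError("transition requires from != to")


def assign_substrate(traj: Trajectory, chamber) -> pd.DataFrame:
    """Per-frame substrate assignment from the centroid's y position.

    Frames with the centroid above the chamber midline get the upper-half
    label, frames below get the lower-half label.  A frame exactly on the
    midline is assigned to the lower-substrate side (fixed tie-break).  A
    ``on_barrier`` flag marks frames within ``barrier_halfwidth`` of the
    midline; the flag is informational (used by the simulator's
    no-egg-on-plastic rule) and does not alter the assignment.

    Returns a DataFrame with columns ``t_s``, ``substrate``, ``on_barrier``.

    Raises ``ValueError`` (naming the first offending frame) if any
    coordinate lies outside the chamber.
    """
    x, y = traj.x, traj.y
    bad = np.flatnonzero(
        (x < 0) | (x > chamber.width) | (y < 0) | (y > chamber.height)
    )
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"frame {i} out of chamber bounds: ({x[i]:.2f}, {y[i]:.2f}) mm"
        )
    lower, upper = chamber.substrate_labels
    labels = np.where(y > chamber.midline_y, upper, lower)
    on_barrier = np.abs(y - chamber.midline_y) <= chamber.barrier_halfwidth
    return pd.DataFrame(
        {"t_s": traj.t, "substrate": labels, "on_barrier": on_barrier}
    )


def boxcar_smooth(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average over ``n`` samples, truncated at the edges.

    NaN-aware: NaN samples are dropped from both numerator and denominator;
    a window with no finite sample yields NaN.
    """
    x = np.asarray(x, dtype=float)
    half = n // 2
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(finite.astype(int))))
    idx = np.arange(len(x))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, len(x) - 1)
    tot = csum[hi + 1] - csum[lo]
    cnt = ccnt[hi + 1] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return out


def detect_search_start(
    t: np.ndarray,
    speed: np.ndarray,
    deposition_s: float,
    boxcar_s: float = 18.5,
    speed_thresh: float = 0.1,
    min_duration_s: float = 9.0,
) -> tuple[float, str | None]:
    """Automated search-period onset from the locomotor speed trace.

    The speed trace up to egg deposition is smoothed with a centered
    ``boxcar_s`` (default 18.5 s) boxcar, truncated at the trace ends, and
    scanned backward from deposition for the most recent frame at which the
    smoothed speed falls below ``speed_thresh`` (default 0.1 mm/s) — i.e.
    the end of the ovulation standstill.  The returned search duration
    (deposition minus onset) is never below ``min_duration_s`` (default
    9 s, set by the filter length).

    Returns ``(search_start_s, flag)`` where ``flag`` is ``None`` for a
    clean detection, ``"clamped"`` when the raw detection was closer than
    ``min_duration_s`` to deposition, and ``"fallback"`` when no
    sub-threshold frame exists in the trace before deposition (in which
    case the onset is placed ``min_duration_s`` before deposition).
    """
    t = np.asarray(t, float)
    speed = np.asarray(speed, float)
    if len(t) != len(speed):
        raise ValueError("t and speed must align")
    frame_dt = t[1] - t[0]
    pre = t <= deposition_s + 1e-9
    if pre.sum() < 2:
        raise ValueError("speed trace does not cover the pre-deposition window")
    tp, sp = t[pre], speed[pre]
    n = max(1, int(round(boxcar_s / frame_dt)))
    smoothed = boxcar_smooth(sp, n)
    below = np.flatnonzero(smoothed < speed_thresh)
    if len(below) == 0:
        return deposition_s - min_duration_s, "fallback"
    start = float(tp[below[-1]])
    if deposition_s - start < min_duration_s:
        return deposition_s - min_duration_s, "clamped"
    return start, None


def detect_transitions(
    t: np.ndarray, labels: Sequence[str], derock_s: float = 4.0
) -> list[TransitionEvent]:
    """Substrate-transition events with boundary-rocking removal.

    Raw transitions are emitted at every frame whose label differs from the
    previous frame's.  A single de-rocking pass over the raw list (in
    original order) then removes each transition *i* whose neighbours
    *i*-1 and *i*+1 occurred within ``derock_s`` (default 4 s) of each
    other; this prevents a fly rocking on the boundary from being counted
    as repeatedly transitioning.  Removal decisions all reference the raw
    list (the pass is not iterated to a fixed point).
    """
    t = np.asarray(t, float)
    labels = np.asarray(labels)
    if len(t) == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    raw = [
        TransitionEvent(float(t[i]), str(labels[i - 1]), str(labels[i]))
        for i in change
    ]
    if len(raw) < 3:
        return raw
    keep = np.ones(len(raw), dtype=bool)
    for i in range(1, len(raw) - 1):
        if raw[i + 1].time_s - raw[i - 1].time_s < derock_s:
            keep[i] = False
    return [ev for ev, k in zip(raw, keep) if k]


@dataclass(frozen=True)
class BinomialStat:
    """k-of-n count with fraction and exact binomial confidence interval."""

    k: int
    n: int
    level: float = 0.95
    fraction: float = field(init=False)
    ci_lo: float = field(init=False)
    ci_hi: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n == 0:
            object.__setattr__(self, "fraction", float("nan"))
            object.__setattr__(self, "ci_lo", float("nan"))
            object.__setattr__(self, "ci_hi", float("nan"))
            return
        from .rates import clopper_pearson

        lo, hi = clopper_pearson(self.k, self.n, self.level)
        object.__setattr__(self, "fraction", self.k / self.n)
        object.__setattr__(self, "ci_lo", lo)
        object.__setattr__(self, "ci_hi", hi)

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def binomial_fraction(k: int, n: int, level: float = 0.95) -> BinomialStat:
    """Pooled event fraction with Clopper–Pearson CI (k of n)."""
    return BinomialStat(k, n, level)


def _label_at(t: np.ndarray, labels: np.ndarray, time_s: float) -> str:
    idx = int(np.searchsorted(t, time_s + 1e-9) - 1)
    idx = min(max(idx, 0), len(labels) - 1)
    return str(labels[idx])


def choice_and_leaving_stats(
    eggs: Iterable[EggLayingSequence],
    t: np.ndarray,
    labels: Sequence[str],
    level: float = 0.95,
) -> dict[str, BinomialStat]:
    """Pooled choice and leaving statistics for one chamber condition.

    For each substrate label present in ``labels`` the summary reports, as
    k-of-n ``BinomialStat`` entries:

    - ``eggs_on:<label>``        eggs deposited on that half;
    - ``search_started_on:<label>``  search periods that began there;
    - ``left_start:<label>``     searches starting there that left the
      starting substrate before deposition.

    Fractions are pooled over all eggs from all flies, mirroring how
    choice fractions are reported for these chambers.  Substrate at search
    start / deposition is resolved from the frame assignment at (or
    immediately before) the event time.
    """
    t = np.asarray(t, float)
    labels = np.asarray(labels)
    eggs = list(eggs)
    opts = sorted(set(str(v) for v in labels))
    n_eggs_on = {o: 0 for o in opts}
    n_start_on = {o: 0 for o in opts}
    n_left = {o: 0 for o in opts}
    for egg in eggs:
        sub_dep = egg.substrate_at_deposition or _label_at(t, labels, egg.deposition_s)
        sub_start = _label_at(t, labels, egg.search_start_s)
        if sub_dep in n_eggs_on:
            n_eggs_on[sub_dep] += 1
        if sub_start in n_start_on:
            n_start_on[sub_start] += 1
            mask = (t >= egg.search_start_s) & (t <= egg.deposition_s)
            if np.any(labels[mask] != sub_start):
                n_left[sub_start] += 1
    total = len(eggs)
    out: dict[str, BinomialStat] = {}
    for o in opts:
        out[f"eggs_on:{o}"] = BinomialStat(n_eggs_on[o], total, level)
        out[f"search_started_on:{o}"] = BinomialStat(n_start_on[o], total, level)
        out[f"left_start:{o}"] = BinomialStat(n_left[o], n_start_on[o], level)
    return out


def binary_group_ranksum(
    k1: int, n1: int, k2: int, n2: int, exact_max_n: int = 40
) -> float:
    """Two-sided rank-sum p-value comparing two binary (0/1) groups.

    Trials with an event count as 1 and those without as 0; the groups of
    0/1 samples are compared with the Wilcoxon rank-sum test.  Because the
    data are binary, the rank-sum statistic is a monotone function of the
    number of events in group 1, whose exact permutation null is
    hypergeometric; for small samples (``n1 + n2 <= exact_max_n``) the
    exact two-sided permutation p-value is returned.  For larger samples
    the tie-corrected normal approximation is used (identical groups give
    exactly p = 1).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError(f"invalid counts k={k}, n={n}")
    K, N = k1 + k2, n1 + n2
    if K == 0 or K == N:
        return 1.0  # all trials identical: no rank information
    if N <= exact_max_n:
        # Midranks: under H0 the count of events in group 1 is
        # hypergeometric; sum pmf over counts at least as extreme (in
        # rank-sum distance from its mean) as observed.
        mu = n1 * K / N
        obs = abs(k1 - mu)
        m = np.arange(max(0, n1 - (N - K)), min(n1, K) + 1)
        pmf = stats.hypergeom.pmf(m, N, K, n1)
        return float(min(1.0, pmf[np.abs(m - mu) >= obs - 1e-12].sum()))
    a = np.concatenate([np.ones(k1), np.zeros(n1 - k1)])
    b = np.concatenate([np.ones(k2), np.zeros(n2 - k2)])
    p = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    ).pvalue
    return float(min(1.0, p))


def per_fly_search_summary(
    eggs_by_fly: pd.DataFrame,
    trajectories: dict[str, Trajectory] | None = None,
    min_eggs: int = 5,
    walk_thresh_mm_s: float = 1.0,
    non_egg_window_s: float = 600.0,
) -> pd.DataFrame:
    """Per-fly median search duration (and optionally walking fraction).

    ``eggs_by_fly`` needs columns ``fly_id``, ``search_start_s`` and
    ``deposition_s``.  Flies with fewer than ``min_eggs`` eggs are
    excluded.  When trajectories are supplied, the walking fraction is
    computed over *non-egg-laying* frames — frames farther than
    ``non_egg_window_s`` (default 10 min) from every deposition — with
    walking defined as speed above ``walk_thresh_mm_s``.
    """
    rows = []
    for fly_id, grp in eggs_by_fly.groupby("fly_id"):
        if len(grp) < min_eggs:
            continue
        durations = grp["deposition_s"].to_numpy() - grp["search_start_s"].to_numpy()
        row = {
            "fly_id": fly_id,
            "n_eggs": len(grp),
            "median_search_s": float(np.median(durations)),
            "walking_fraction": np.nan,
        }
        if trajectories is not None and fly_id in trajectories:
            traj = trajectories[fly_id]
            far = np.ones(len(traj.t), dtype=bool)
            for dep in grp["deposition_s"]:
                far &= np.abs(traj.t - dep) > non_egg_window_s
            if far.any():
                row["walking_fraction"] = float(
                    np.mean(traj.speed[far] > walk_thresh_mm_s)
                )
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["fly_id", "n_eggs", "median_search_s", "walking_fraction"]
    )
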