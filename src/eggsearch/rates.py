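"""Egg-laying rate as a function of time since the last substrate transition.

The analysis pools all flies in a chamber condition and, for a set of
elapsed-time bins, tallies three quantities per bin: the number of egg
depositions (``n_eggs``), the number of search-period video frames
(``n_frames``) and the number of *visits* — entries of the fly's frame
assignment into that bin (``n_visits``).  The mean rate is
``120 * n_eggs / n_frames`` (2 Hz video, so 120 frames per minute).  The
confidence interval is computed on ``n_eggs / n_visits`` with the exact
(Clopper–Pearson) binomial method at 90% and transformed to eggs/min by
multiplying by ``120 * n_visits / n_frames``; computing the interval on a
per-visit basis keeps it independent of the video frame rate.

Search periods shorter than 30 s are padded to 30 s (the padding extends
the search start earlier; padded frames take the elapsed-time values they
would have had), which stops very brief searches from inflating the rate
numerator without contributing to the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta

from .behavior import EggLayingSequence, TransitionEvent

__all__ = [
    "RateCurve",
    "clopper_pearson",
    "elapsed_since_transition",
    "compute_rate_curve",
    "DEFAULT_BIN_EDGES",
]

# Geometric-ish elapsed-time bins (s); configurable everywhere they are used.
DEFAULT_BIN_EDGES = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0, 480.0, 960.0, 1920.0, 3840.0, 7200.0)


def clopper_pearson(k: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Exact binomial confidence interval for a k-of-n proportion.

    Standard beta-quantile bounds: the lower limit is 0 when ``k == 0``
    and the upper limit is 1 when ``k == n``.
    """
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if n < 1 or not (0 <= k <= n) or k != int(k) or n != int(n):
        raise ValueError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def elapsed_since_transition(
    t: np.ndarray,
    transitions: list[TransitionEvent],
    search_periods: list[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame time since the most recent substrate transition.

    Defined only during search periods (NaN elsewhere).  Transitions
    occurring outside search periods still reset the clock — the elapsed
    time is measured from the most recent transition at or before each
    frame regardless of when it occurred.  Frames preceding the first
    transition carry elapsed time measured from session start and are
    flagged.

    Returns ``(elapsed_s, in_search, since_start_flag)`` arrays aligned to
    ``t``.
    """
    t = np.asarray(t, float)
    trans_t = np.array(sorted(ev.time_s for ev in transitions), dtype=float)
    in_search = np.zeros(len(t), dtype=bool)
    for start, end in search_periods:
        in_search |= (t >= start - 1e-9) & (t <= end + 1e-9)
    t0 = t[0] if len(t) else 0.0
    if len(trans_t) == 0:
        since_start = np.ones(len(t), dtype=bool)
        last = np.full(len(t), t0)
    else:
        idx = np.searchsorted(trans_t, t, side="right") - 1
        since_start = idx < 0
        last = np.where(since_start, t0, trans_t[np.maximum(idx, 0)])
    elapsed = np.where(in_search, t - last, np.nan)
    return elapsed, in_search, since_start & in_search


def pad_search_periods(
    eggs: list[EggLayingSequence], min_duration_s: float = 30.0
) -> list[tuple[float, float]]:
    """Search intervals (start, deposition), short ones padded to 30 s.

    Padding extends the start earlier so the padded frames inherit the
    elapsed-since-transition values they would have had anyway.
    """
    out = []
    for egg in eggs:
        start, dep = egg.search_start_s, egg.deposition_s
        if dep - start < min_duration_s:
            start = dep - min_duration_s
        out.append((start, dep))
    return out


@dataclass
class RateCurve:
    """Per-bin egg-laying rate for one substrate direction.

    ``substrate`` is the option occupied during the binned frames, i.e.
    the *to*-substrate of the most recent transition.  ``rate`` is in
    eggs/min; ``ci_lo``/``ci_hi`` bound ``120 * (n_eggs/n_visits) *
    (n_visits/n_frames)`` at the stated level.
    """

    substrate: str
    bin_edges: np.ndarray
    n_eggs: np.ndarray
    n_frames: np.ndarray
    n_visits: np.ndarray
    rate: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_s": self.bin_edges[:-1],
                "bin_hi_s": self.bin_edges[1:],
                "direction": self.substrate,
                "n_eggs": self.n_eggs,
                "n_frames": self.n_frames,
                "n_visits": self.n_visits,
                "rate_eggs_per_min": self.rate,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


def compute_rate_curve(
    eggs: list[EggLayingSequence],
    t: np.ndarray,
    labels: np.ndarray,
    transitions: list[TransitionEvent],
    bin_edges=DEFAULT_BIN_EDGES,
    level: float = 0.90,
    frames_per_min: float = 120.0,
    pad_s: float = 30.0,
) -> dict[str, RateCurve]:
    """Egg-laying rate versus time since the last substrate transition.

    Returns one :class:`RateCurve` per substrate label.  Per bin and
    substrate:

    - ``n_eggs``: depositions whose elapsed time falls in the bin while
      the fly is on that substrate;
    - ``n_frames``: search-period frames assigned to the bin;
    - ``n_visits``: changes of (substrate, bin) assignment into the bin —
      the counter does not increment while the fly stays in the same bin
      frame to frame, but any change of assignment (elapsed time rolling
      into the next bin, or a new transition resetting the clock) counts.

    Bins with ``n_frames == 0`` get NaN rate but keep their counts.
    Raises if a bin somehow holds eggs but no visits (bookkeeping error).
    """
    t = np.asarray(t, float)
    labels = np.asarray(labels).astype(str)
    edges = np.asarray(bin_edges, float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    nbins = len(edges) - 1
    periods = pad_search_periods(eggs, pad_s)
    elapsed, in_search, _ = elapsed_since_transition(t, transitions, periods)

    opts = sorted(set(labels))
    n_eggs = {o: np.zeros(nbins, int) for o in opts}
    n_frames = {o: np.zeros(nbins, int) for o in opts}
    n_visits = {o: np.zeros(nbins, int) for o in opts}

    bin_idx = np.full(len(t), -1)
    valid = in_search & np.isfinite(elapsed)
    bi = np.searchsorted(edges, elapsed[valid], side="right") - 1
    ok = (bi >= 0) & (bi < nbins)
    if not np.all(ok):
        raise ValueError("bin_edges do not cover all elapsed times")
    bin_idx[valid] = bi

    # A "visit" starts at any frame whose (substrate, bin) assignment
    # differs from the previous frame's, or whose previous frame was not a
    # search frame.
    cur = bin_idx >= 0
    prev_valid = np.concatenate(([False], cur[:-1]))
    prev_bin = np.concatenate(([-1], bin_idx[:-1]))
    prev_lab = np.concatenate(([""], labels[:-1]))
    entry = cur & (~prev_valid | (prev_bin != bin_idx) | (prev_lab != labels))
    for o in opts:
        is_o = labels == o
        n_frames[o] = np.bincount(bin_idx[cur & is_o], minlength=nbins)
        n_visits[o] = np.bincount(bin_idx[entry & is_o], minlength=nbins)

    trans_t = np.array(sorted(ev.time_s for ev in transitions), dtype=float)
    for egg in eggs:
        dep = egg.deposition_s
        j = np.searchsorted(trans_t, dep, side="right") - 1
        last = trans_t[j] if j >= 0 else t[0]
        e = dep - last
        b = int(np.searchsorted(edges, e, side="right") - 1)
        if not (0 <= b < nbins):
            raise ValueError(f"egg at {dep} s has elapsed {e} s outside bins")
        sub = egg.substrate_at_deposition
        if not sub:  # fall back to the frame assignment at deposition
            k = min(max(int(np.searchsorted(t, dep + 1e-9) - 1), 0), len(labels) - 1)
            sub = labels[k]
        if sub not in n_eggs:
            raise ValueError(f"egg substrate {sub!r} not among frame labels")
        n_eggs[sub][b] += 1

    out: dict[str, RateCurve] = {}
    for o in opts:
        ke, kf, kv = n_eggs[o], n_frames[o], n_visits[o]
        if np.any((ke > 0) & (kv == 0)):
            raise ValueError("bin has eggs but no visits; inconsistent inputs")
        rate = np.full(nbins, np.nan)
        lo = np.full(nbins, np.nan)
        hi = np.full(nbins, np.nan)
        for b in range(nbins):
            if kf[b] == 0:
                continue
            rate[b] = frames_per_min * ke[b] / kf[b]
            if kv[b] > 0:
                plo, phi = clopper_pearson(int(ke[b]), int(kv[b]), level)
                scale = frames_per_min * kv[b] / kf[b]
                lo[b], hi[b] = plo * scale, phi * scale
        out[o] = RateCurve(o, edges, ke, kf, kv, rate, lo, hi, level)
    return out
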