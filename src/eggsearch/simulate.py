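"""Value-modulated rise-to-threshold simulator for egg-laying sessions.

The generative model: between eggs the fly walks and pauses in a
two-substrate chamber.  Each egg-laying cycle begins with an ovulation
standstill (~1 min), after which a latent decision variable ``A(t)`` starts
from a reset level and evolves as a drift–diffusion process,

    dA = r(v(substrate(t))) dt + noise_sd dW,

whose drift depends on the *relative value* of the currently occupied
substrate: on the favoured (lower-sucrose) option the drift is
``drift_rate_high``; on the disfavoured option the effective drift starts
at ``drift_rate_low`` and relaxes exponentially toward ``drift_rate_high``
with timescale ``value_adapt_tau`` measured from the fly's last visit to
the favoured option (the option regains value when the better alternative
has not been experienced recently).  When ``A`` crosses
``threshold_level``, the abdomen bend for egg deposition is emitted and the
egg is deposited ``bend_to_deposit_delay`` seconds later — deferred, if
necessary, until the fly is off the plastic barrier strip, on which eggs
are never laid.  ``A`` then resets and an inter-egg refractory period
begins.

Locomotion is a two-state (walk/pause) Markov process with a diffusing
heading and reflective chamber walls; only the substrate-occupancy
statistics it produces matter downstream.

All randomness flows from a single integer seed, so identical
``(params, chamber, duration, seed)`` reproduce a session bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import EggLayingSequence, Trajectory

__all__ = [
    "DriftParams",
    "ChamberSpec",
    "FluorescenceSimSpec",
    "SimSession",
    "SimulationError",
    "simulate_session",
    "simulate_value_trace",
    "simulate_fluorescence",
    "make_synapse_fixture",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DriftParams:
    """Parameters of the rise-to-threshold decision process.

    Latent units are dimensionless; rates are latent units per second and
    ``noise_sd`` is the diffusion coefficient (latent units per sqrt s).
    """

    threshold_level: float = 1.0
    drift_rate_high: float = 0.02
    drift_rate_low: float = -0.03
    noise_sd: float = 0.03
    value_adapt_tau: float = 120.0
    ovulation_duration_mean: float = 60.0
    bend_to_deposit_delay: float = 3.0
    inter_egg_refractory: float = 60.0
    reset_level: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_level <= self.reset_level:
            raise ValueError("threshold_level must exceed reset_level")
        if self.value_adapt_tau <= 0:
            raise ValueError("value_adapt_tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bend_to_deposit_delay < 0:
            raise ValueError("bend_to_deposit_delay must be non-negative")
        if self.ovulation_duration_mean <= 0:
            raise ValueError("ovulation_duration_mean must be positive")

    def scaled(self, factor: float) -> "DriftParams":
        """Uniformly attenuate the input to the decision process.

        Scales both drift rates and the diffusion coefficient by
        ``factor`` — the simulator's model of a gentle hyperpolarization,
        which shrinks the effect of all synaptic input on the latent
        variable alike.
        """
        return replace(
            self,
            drift_rate_high=self.drift_rate_high * factor,
            drift_rate_low=self.drift_rate_low * factor,
            noise_sd=self.noise_sd * factor,
        )


@dataclass(frozen=True)
class ChamberSpec:
    """Two-substrate chamber geometry and substrate identities.

    The chamber is split at ``midline_y`` into a lower and an upper half;
    ``substrate_labels`` and ``sucrose_mm`` are given as (lower, upper).
    A plastic barrier strip of half-width ``barrier_halfwidth`` (default
    1.25 mm, i.e. a ~2.5 mm barrier) straddles the midline; flies walk on
    it but never deposit eggs there.
    """

    width: float = 20.0
    height: float = 40.0
    midline_y: float = 20.0
    barrier_halfwidth: float = 1.25
    substrate_labels: tuple[str, str] = ("0", "500")
    sucrose_mm: tuple[float, float] = (0.0, 500.0)
    frame_rate: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.midline_y < self.height):
            raise ValueError("midline_y must lie inside the chamber")
        if self.barrier_halfwidth < 0:
            raise ValueError("barrier_halfwidth must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if len(set(self.substrate_labels)) != 2:
            raise ValueError("substrate labels must be distinct")

    @property
    def favoured_label(self) -> str | None:
        """Label of the higher-relative-value (lower-sucrose) half.

        None when both halves carry the same concentration (no-choice
        control chambers), in which case both count as favoured.
        """
        lo, hi = self.sucrose_mm
        if lo == hi:
            return None
        return self.substrate_labels[0] if lo < hi else self.substrate_labels[1]


@dataclass(frozen=True)
class FluorescenceSimSpec:
    """Forward model from the latent decision variable to raw fluorescence."""

    gain: float = 1.0
    baseline_F: float = 100.0
    background_F: float = 30.0
    baseline_drift_sd: float = 0.0
    photon_noise_sd: float = 1.0
    volume_rate: float = 1.5

    def __post_init__(self) -> None:
        if self.baseline_F <= 0:
            raise ValueError("baseline_F must be positive")
        if self.volume_rate <= 0:
            raise ValueError("volume_rate must be positive")


@dataclass
class SimSession:
    """One simulated chamber session.

    ``latent`` holds A(t) per frame (reset level outside search periods),
    ``value`` the per-frame effective drift rate, ``labels`` the per-frame
    substrate assignment.
    """

    trajectory: Trajectory
    latent: np.ndarray
    value: np.ndarray
    labels: np.ndarray
    egg_events: list[EggLayingSequence]
    chamber: ChamberSpec
    params: DriftParams
    rng_seed: int

    @property
    def t(self) -> np.ndarray:
        return self.trajectory.t


# Locomotion constants (calibrated once so that half-to-half transitions
# occur every ~30-120 s in the default chamber while occasional long rests
# produce the minutes-long same-substrate residencies real flies show; see
# docs/methods.md).
_WALK_BOUT_MEAN_S = 15.0
_PAUSE_SHORT_MEAN_S = 6.0
_PAUSE_LONG_MEAN_S = 60.0
_PAUSE_LONG_PROB = 0.12
_SPEED_RANGE_MM_S = (2.0, 6.0)
_HEADING_DIFFUSION = 1.1  # rad per sqrt s


def _effective_drift(params: DriftParams, on_favoured: bool, tsf: float) -> float:
    if on_favoured:
        return params.drift_rate_high
    decay = math.exp(-tsf / params.value_adapt_tau)
    return params.drift_rate_high - (params.drift_rate_high - params.drift_rate_low) * decay


def simulate_session(
    params: DriftParams,
    chamber: ChamberSpec,
    duration_s: float,
    seed: int,
    confine_to: str | None = None,
) -> SimSession:
    """Simulate one fly for ``duration_s`` seconds.

    ``confine_to`` optionally restricts the fly to one substrate half
    (an extra reflective wall at the barrier edge), which is how "fly held
    on substrate X" scenarios are produced.

    Raises :class:`SimulationError` when the threshold is unreachable
    (zero noise and no positive drift anywhere).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if params.noise_sd == 0 and params.drift_rate_high <= 0:
        raise SimulationError("unreachable threshold: zero noise and non-positive drift")
    if confine_to is not None and confine_to not in chamber.substrate_labels:
        raise ValueError(f"unknown substrate label {confine_to!r}")

    dt = 1.0 / chamber.frame_rate
    n = int(round(duration_s * chamber.frame_rate))
    rng = np.random.default_rng(seed)

    # Pre-drawn randomness, consumed one value per frame.
    z_head = rng.standard_normal(n)
    z_noise = rng.standard_normal(n) if params.noise_sd > 0 else np.zeros(n)

    def draw_pause() -> float:
        if rng.random() < _PAUSE_LONG_PROB:
            return float(rng.exponential(_PAUSE_LONG_MEAN_S))
        return float(rng.exponential(_PAUSE_SHORT_MEAN_S))

    lower, upper = chamber.substrate_labels
    favoured = chamber.favoured_label
    # Reflective bounds, optionally confined to one half (off the barrier
    # strip so deferred depositions cannot deadlock).
    y_lo, y_hi = 0.0, chamber.height
    if confine_to == lower:
        y_hi = max(chamber.midline_y - chamber.barrier_halfwidth, 1e-6)
    elif confine_to == upper:
        y_lo = min(chamber.midline_y + chamber.barrier_halfwidth, chamber.height - 1e-6)

    sqrt_dt = math.sqrt(dt)
    head_sd = _HEADING_DIFFUSION * sqrt_dt
    noise_step = params.noise_sd * sqrt_dt

    x = float(rng.uniform(0, chamber.width))
    y = float(rng.uniform(y_lo, y_hi))
    heading = float(rng.uniform(0, 2 * math.pi))
    walking = bool(rng.random() < 0.5)
    bout_speed = float(rng.uniform(*_SPEED_RANGE_MM_S))
    bout_timer = float(rng.exponential(_WALK_BOUT_MEAN_S)) if walking else draw_pause()

    t = np.arange(n) * dt
    xs = np.empty(n)
    ys = np.empty(n)
    latent = np.full(n, params.reset_level)
    value = np.empty(n)
    labels_arr = np.empty(n, dtype=object)

    eggs: list[EggLayingSequence] = []
    phase = "refractory"
    timer = params.inter_egg_refractory * 0.5  # first ovulation comes sooner
    A = params.reset_level
    # Time since last favoured visit; initialised so that a session that
    # starts on the disfavoured half has tsf = 0 at frame 0 (clock runs
    # from session start before any favoured visit).
    tsf = -dt
    ovulation_start = math.nan
    search_start = math.nan
    bend_complete = math.nan

    midline = chamber.midline_y
    bhw = chamber.barrier_halfwidth
    thresh = params.threshold_level - 1e-9

    for i in range(n):
        ti = t[i]
        standstill = phase in ("ovulating", "delay")
        if not standstill:
            bout_timer -= dt
            if not walking and phase == "deferred":
                bout_timer = 0.0  # leave the barrier strip promptly
            if bout_timer <= 0:
                walking = not walking
                if walking:
                    bout_timer = float(rng.exponential(_WALK_BOUT_MEAN_S))
                    bout_speed = float(rng.uniform(*_SPEED_RANGE_MM_S))
                else:
                    bout_timer = draw_pause()
            if walking:
                heading += head_sd * z_head[i]
                x += bout_speed * dt * math.cos(heading)
                y += bout_speed * dt * math.sin(heading)
                if x < 0:
                    x, heading = -x, math.pi - heading
                elif x > chamber.width:
                    x, heading = 2 * chamber.width - x, math.pi - heading
                if y < y_lo:
                    y, heading = 2 * y_lo - y, -heading
                elif y > y_hi:
                    y, heading = 2 * y_hi - y, -heading
        xs[i], ys[i] = x, y

        label = upper if y > midline else lower
        labels_arr[i] = label
        on_fav = favoured is None or label == favoured
        if on_fav:
            tsf = 0.0
        else:
            tsf += dt
        r_eff = _effective_drift(params, on_fav, tsf)
        value[i] = r_eff

        if phase == "refractory":
            timer -= dt
            if timer <= 0:
                phase = "ovulating"
                ovulation_start = ti
                shape = 4.0
                timer = float(rng.gamma(shape, params.ovulation_duration_mean / shape))
                walking = False
        elif phase == "ovulating":
            timer -= dt
            if timer <= 0:
                phase = "searching"
                search_start = ti
                A = params.reset_level
        elif phase == "searching":
            A += r_eff * dt + noise_step * z_noise[i]
            latent[i] = A
            if A >= thresh:
                bend_complete = ti
                phase = "delay"
                timer = params.bend_to_deposit_delay
                walking = False
        elif phase == "delay":
            timer -= dt
            if timer <= 0:
                if abs(y - midline) <= bhw:
                    phase = "deferred"  # no eggs on the plastic strip
                else:
                    phase = "refractory"
                    timer = params.inter_egg_refractory
                    eggs.append(
                        EggLayingSequence(
                            ovulation_start, search_start, bend_complete, ti, label
                        )
                    )
                    A = params.reset_level
        elif phase == "deferred":
            if abs(y - midline) > bhw:
                phase = "refractory"
                timer = params.inter_egg_refractory
                eggs.append(
                    EggLayingSequence(
                        ovulation_start, search_start, bend_complete, ti, label
                    )
                )
                A = params.reset_level

    traj = Trajectory(t, xs, ys)
    return SimSession(
        trajectory=traj,
        latent=latent,
        value=value,
        labels=labels_arr.astype(str),
        egg_events=eggs,
        chamber=chamber,
        params=params,
        rng_seed=int(seed),
    )


def simulate_value_trace(
    substrate_track: Sequence[str],
    params: DriftParams,
    favoured_label: str,
    dt: float,
    known_labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-frame effective drift rate implied by a substrate occupancy track.

    On the favoured substrate the drift is ``drift_rate_high`` and the
    adaptation clock resets; on the other substrate the drift relaxes
    exponentially from ``drift_rate_low`` toward ``drift_rate_high`` with
    timescale ``value_adapt_tau``, measured from the last favoured visit.
    Before any favoured visit the clock runs from the start of the track
    (as if the fly had just left the favoured option at t=0).

    ``known_labels`` optionally restricts the accepted label set; an
    unrecognised label raises ``ValueError``.
    """
    labels = np.asarray(substrate_track)
    if len(labels) == 0:
        raise ValueError("substrate_track must be non-empty")
    if known_labels is not None:
        bad = set(map(str, labels)) - set(map(str, known_labels))
        if bad:
            raise ValueError(f"unknown substrate label(s): {sorted(bad)}")
    fav = labels == favoured_label
    idx = np.arange(len(labels))
    last_fav = np.where(fav, idx, -1)
    last_fav = np.maximum.accumulate(last_fav)
    tsf = (idx - last_fav) * dt  # frames since favoured; idx+1 frames when never visited
    tsf = np.where(last_fav < 0, idx * dt, tsf)
    decay = np.exp(-tsf / params.value_adapt_tau)
    r = params.drift_rate_high - (params.drift_rate_high - params.drift_rate_low) * decay
    return np.where(fav, params.drift_rate_high, r)


def simulate_fluorescence(
    latent_t: np.ndarray,
    latent: np.ndarray,
    spec: FluorescenceSimSpec,
    seed: int,
):
    """Render a latent trace as a raw two-channel fluorescence recording.

    Volumes of period ``1/volume_rate`` tile the latent span; each volume
    is stamped at its half-completion time and samples the latent value at
    the most recent latent grid point.  The cell channel is
    ``baseline_F * (1 + gain * A) + background_F`` plus an optional slow
    baseline random walk and photon noise; the background channel is
    ``background_F`` plus photon noise.

    Returns a :class:`~eggsearch.calcium.FluorescenceRecording`.
    """
    from .calcium import FluorescenceRecording

    latent_t = np.asarray(latent_t, float)
    latent = np.asarray(latent, float)
    if len(latent_t) < 2:
        raise ValueError("latent trace too short")
    grid_dt = latent_t[1] - latent_t[0]
    if not np.allclose(np.diff(latent_t), grid_dt, rtol=1e-6, atol=1e-9):
        raise ValueError("latent trace must be on a uniform grid")
    period = 1.0 / spec.volume_rate
    if period < grid_dt - 1e-12:
        raise ValueError("volume_rate exceeds the latent grid rate")
    rng = np.random.default_rng(seed)
    span = latent_t[-1] - latent_t[0]
    n_vol = int(span // period)
    if n_vol < 1:
        raise ValueError("latent trace shorter than one volume")
    vol_t = latent_t[0] + (np.arange(n_vol) + 0.5) * period
    idx = np.minimum(
        np.searchsorted(latent_t, vol_t + 1e-12, side="right") - 1, len(latent) - 1
    )
    a = latent[idx]
    drift = (
        np.cumsum(rng.standard_normal(n_vol)) * spec.baseline_drift_sd * math.sqrt(period)
        if spec.baseline_drift_sd > 0
        else 0.0
    )
    noise_c = rng.standard_normal(n_vol) * spec.photon_noise_sd if spec.photon_noise_sd else 0.0
    noise_b = rng.standard_normal(n_vol) * spec.photon_noise_sd if spec.photon_noise_sd else 0.0
    f_cell = spec.baseline_F * (1.0 + spec.gain * a) + spec.background_F + drift + noise_c
    f_bg = spec.background_F + np.zeros(n_vol) + noise_b
    return FluorescenceRecording(vol_t, f_cell, f_bg)


def make_synapse_fixture(
    seed: int,
    n_distractors: int = 220,
    planted_weight_range: tuple[int, int] = (10, 15),
) -> tuple[pd.DataFrame, dict]:
    """Synthetic synapse table with a planted recurrent motif.

    The planted motif emulates the anatomy of the egg-laying recurrent
    circuit: one seed-class excitatory cell per hemisphere (class
    ``seedEN``), interconnected across hemispheres through one
    intermediary of class ``G`` (right side) and one of class ``U`` (left
    side), each receiving from and projecting back to the seed cells on
    both sides with strong (>= 10 synapse) connections; plus a reciprocal
    inhibitory pair (class ``IN``).  Pure-output-sink cells of class
    ``DN`` receive strong input but send almost nothing back, emulating
    descending neurons, so motif queries seeded on ``DN`` come up empty.
    Distractor edges among ``n_distractors`` random cells all have weight
    <= 9 and therefore vanish at the ten-synapse threshold.

    Returns ``(table, ground_truth)`` where ``ground_truth`` records the
    planted intermediaries, the reciprocal pairs and every planted edge.
    """
    rng = np.random.default_rng(seed)
    wlo, whi = planted_weight_range

    def w() -> int:
        return int(rng.integers(wlo, whi + 1))

    cells = {
        "EN_L": ("seedEN", "L"),
        "EN_R": ("seedEN", "R"),
        "G_R": ("G", "R"),
        "U_L": ("U", "L"),
        "IN_L": ("IN", "L"),
        "IN_R": ("IN", "R"),
        "DN_L": ("DN", "L"),
        "DN_R": ("DN", "R"),
    }
    planted: list[tuple[str, str, int]] = []
    for x in ("G_R", "U_L"):
        for s in ("EN_L", "EN_R"):
            planted.append((s, x, w()))
            planted.append((x, s, w()))
    planted.append(("IN_L", "IN_R", w()))
    planted.append(("IN_R", "IN_L", w()))
    # oviIN-style same-side reciprocity with the seed cells
    planted.append(("EN_L", "IN_L", w()))
    planted.append(("IN_L", "EN_L", w()))
    # strong input onto the descending cells, no strong return path
    planted.append(("EN_L", "DN_L", w()))
    planted.append(("EN_R", "DN_R", w()))

    dist_ids = [f"X{i:04d}" for i in range(n_distractors)]
    for d in dist_ids:
        cells[d] = ("other", "L" if rng.random() < 0.5 else "R")
    all_ids = list(cells)
    seen = {(a, b) for a, b, _ in planted}
    distractor_edges: list[tuple[str, str, int]] = []
    n_edges = 4 * n_distractors
    while len(distractor_edges) < n_edges:
        a, b = rng.choice(all_ids, size=2, replace=False)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        distractor_edges.append((str(a), str(b), int(rng.integers(1, 10))))

    rows = []
    for pre, post, weight in planted + distractor_edges:
        rows.append(
            {
                "pre_id": pre,
                "post_id": post,
                "pre_class": cells[pre][0],
                "post_class": cells[post][0],
                "pre_side": cells[pre][1],
                "post_side": cells[post][1],
                "n_synapses": weight,
            }
        )
    table = pd.DataFrame(rows)
    ground_truth = {
        "seed_class": "seedEN",
        "intermediaries": {"G_R", "U_L"},
        "reciprocal_pairs": {frozenset(("IN_L", "IN_R")), frozenset(("EN_L", "IN_L"))},
        "planted_edges": {(a, b): c for a, b, c in planted},
    }
    return table, ground_truth
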