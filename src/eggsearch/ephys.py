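"""Spike-train utilities and the spike-rate-to-fluorescence forward model.

Whole-cell recordings are digitised at 10 kHz; spikes are identified by
high-pass filtering the membrane potential and taking threshold-crossing
peaks separated by more than 1 ms.  Spike rate is a sliding count (5 s
window by default, stepped at 0.1 ms) assigned to the middle of the
counting interval.  A de-spiked membrane potential is obtained by blanking
150 ms around each spike peak.  The forward model that links spike rate to
a fluorescence proxy convolves the rate with a causal exponential kernel
(tau = 300 ms, the indicator off-kinetics) and then a centered boxcar
(2.8 s, the slowest volumetric frame period); both kernels have unit mass
so a constant rate maps to itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .behavior import boxcar_smooth

__all__ = [
    "VoltageRecording",
    "SpikeTrain",
    "RateTrace",
    "detect_spikes",
    "spike_rate",
    "despike_vm",
    "gcamp_forward_model",
    "half_decay_time",
    "correct_junction_potential",
]


@dataclass(frozen=True)
class VoltageRecording:
    """Membrane potential sampled at 10 kHz (0.1 ms steps)."""

    t: np.ndarray
    vm_mV: np.ndarray
    junction_corrected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        v = np.asarray(self.vm_mV, float)
        if len(t) != len(v):
            raise ValueError("t and vm must align")
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "vm_mV", v)

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def correct_junction_potential(
    rec: VoltageRecording, junction_mV: float = 13.0
) -> VoltageRecording:
    """Subtract the liquid-junction potential (13 mV) exactly once.

    A second application refuses (the ``junction_corrected`` flag makes
    the correction idempotent at the API level).
    """
    if rec.junction_corrected:
        raise ValueError("recording is already junction-corrected")
    return VoltageRecording(rec.t, rec.vm_mV - junction_mV, junction_corrected=True)


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (s), consecutive spikes > 1 ms apart."""

    spike_times: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, float)
        if len(st) > 1:
            gaps = np.diff(st)
            if np.any(gaps <= 0):
                raise ValueError("spike times must be strictly increasing")
            if np.any(gaps <= 1e-3):
                raise ValueError("consecutive spikes must be > 1 ms apart")
        object.__setattr__(self, "spike_times", st)

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class RateTrace:
    """Sliding-window spike rate; values sit at window centres."""

    t: np.ndarray
    rate: np.ndarray
    window_s: float


def detect_spikes(
    rec: VoltageRecording,
    highpass_hz: float = 100.0,
    thresh_mV: float | None = None,
    thresh_sds: float = 5.0,
    min_separation_s: float = 1e-3,
) -> SpikeTrain:
    """Spike detection by high-pass filtering and thresholded peak-picking.

    The trace is zero-phase high-pass filtered (2nd-order Butterworth at
    ``highpass_hz``); peaks above threshold separated by more than
    ``min_separation_s`` are kept — of any violating pair the larger peak
    survives.  When ``thresh_mV`` is not given, the threshold defaults to
    ``thresh_sds`` (default 5) times a robust (median absolute deviation) estimate of
    the filtered trace's noise s.d.; real recordings vary, so both knobs
    are exposed.
    """
    fs = rec.fs
    sos = signal.butter(2, highpass_hz, btype="highpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, rec.vm_mV)
    if thresh_mV is None:
        sigma = 1.4826 * np.median(np.abs(filt - np.median(filt)))
        thresh_mV = thresh_sds * sigma
    distance = int(np.floor(min_separation_s * fs)) + 1
    peaks, _ = signal.find_peaks(filt, height=thresh_mV, distance=distance)
    return SpikeTrain(rec.t[peaks])


def spike_rate(
    train: SpikeTrain,
    span: tuple[float, float],
    window_s: float = 5.0,
    step_s: float = 1e-4,
) -> RateTrace:
    """Sliding spike count divided by the window, at the window centre.

    Counts spikes in every ``window_s`` interval stepped by ``step_s``
    across ``span``; each count/`window` value is assigned to the middle
    of its counting interval.  Interval membership is half-open
    ``[centre - w/2, centre + w/2)``.
    """
    t0, t1 = span
    if window_s > t1 - t0:
        raise ValueError("window longer than the requested span")
    centres = np.arange(t0 + window_s / 2, t1 - window_s / 2 + step_s / 2, step_s)
    st = train.spike_times
    counts = np.searchsorted(st, centres + window_s / 2) - np.searchsorted(
        st, centres - window_s / 2
    )
    return RateTrace(centres, counts / window_s, window_s)


def despike_vm(
    rec: VoltageRecording, train: SpikeTrain, blank_s: float = 0.150
) -> np.ndarray:
    """Membrane potential with ``blank_s`` (150 ms) gaps centred on spikes.

    Overlapping blanking windows merge naturally.  Returns a copy of the
    voltage trace with NaN gaps.
    """
    out = rec.vm_mV.copy()
    half = blank_s / 2
    t = rec.t
    for s in train.spike_times:
        i0 = np.searchsorted(t, s - half, side="left")
        i1 = np.searchsorted(t, s + half, side="right")
        out[i0:i1] = np.nan
    return out


def gcamp_forward_model(
    rate: RateTrace, tau_s: float = 0.300, boxcar_s: float = 2.8
) -> RateTrace:
    """Fluorescence proxy for a spike-rate trace.

    Causal exponential convolution (``tau_s``, the indicator's off
    kinetics) followed by a centered boxcar (``boxcar_s``, the slowest
    volumetric frame period).  Both kernels are normalised to unit mass,
    so the model is linear and maps a constant rate to itself.
    """
    if tau_s <= 0 or boxcar_s <= 0:
        raise ValueError("tau_s and boxcar_s must be positive")
    t, r = rate.t, np.asarray(rate.rate, float)
    dt = float(t[1] - t[0])
    # Exponential kernel out to 8 tau captures > 99.96% of the mass.
    k = np.exp(-np.arange(0, 8 * tau_s, dt) / tau_s)
    k /= k.sum()
    exp_out = signal.fftconvolve(r, k)[: len(r)]
    n_box = max(1, int(round(boxcar_s / dt)))
    out = boxcar_smooth(exp_out, n_box)
    return RateTrace(t, out, rate.window_s)


def half_decay_time(
    t: np.ndarray,
    trace: np.ndarray,
    stim_end_s: float,
    pre_window_s: float = 5.0,
    stim_onset_s: float | None = None,
) -> float:
    """Time after stimulation offset to decay half-way back to baseline.

    The baseline is the trace mean over the ``pre_window_s`` seconds of
    pre-stimulation data (before ``stim_onset_s`` when given, otherwise
    before ``stim_end_s``).  The half-decay time is the first time after
    ``stim_end_s`` at which the trace crosses the midpoint between its
    value at stimulation end and that baseline, linearly interpolated
    between samples.  Returns NaN (flagged: no crossing in the available
    tail) when the trace never reaches the midpoint.
    """
    t = np.asarray(t, float)
    y = np.asarray(trace, float)
    ref = stim_end_s if stim_onset_s is None else stim_onset_s
    pre = (t >= ref - pre_window_s) & (t < ref)
    if not np.any(pre & np.isfinite(y)):
        raise ValueError("trace does not cover the pre-stimulation window")
    baseline = float(np.nanmean(y[pre]))
    i_end = int(np.searchsorted(t, stim_end_s + 1e-12, side="right") - 1)
    if i_end < 0 or i_end >= len(t) - 1:
        return float("nan")
    y_end = y[i_end]
    mid = 0.5 * (y_end + baseline)
    decaying = y_end > baseline
    for i in range(i_end + 1, len(t)):
        crossed = y[i] <= mid if decaying else y[i] >= mid
        if np.isfinite(y[i]) and crossed:
            y0, y1 = y[i - 1], y[i]
            if np.isfinite(y0) and y1 != y0:
                frac = (mid - y0) / (y1 - y0)
                frac = min(max(frac, 0.0), 1.0)
                return float(t[i - 1] + frac * (t[i] - t[i - 1]) - stim_end_s)
            return float(t[i] - stim_end_s)
    return float("nan")
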