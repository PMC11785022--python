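"""Triggered responses, neurovascular slope, state-conditioned summaries,
bilateral comparisons, and transition dynamics.

These are the quantities exported per animal x hemisphere x state for group
statistics (which are outside this package): evoked window means, resting
variance, state-mean dHbT, peak cross-correlation, band-mean coherence,
Pearson r, and the through-origin neural-to-vascular slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import pearsonr

from . import signal_processing as sp
from .errors import ParameterError
from .sleep_scoring import ArousalLabels, Segment

SAVGOL_WINDOW = 17  # samples at 30 Hz (~0.57 s)
SAVGOL_ORDER = 3
BASELINE_PRE_S = 2.0


@dataclass
class EvokedResponse:
    time_s: np.ndarray  # relative to onset
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    n_dropped: int
    window_stats: dict = field(default_factory=dict)  # name -> (t0, t1, mean)

    def window_mean(self, t0: float, t1: float, name: str | None = None) -> float:
        sel = (self.time_s >= t0) & (self.time_s <= t1)
        if not sel.any():
            raise ParameterError(f"window ({t0}, {t1}) outside response support")
        val = float(np.mean(self.mean[sel]))
        if name:
            self.window_stats[name] = (t0, t1, val)
        return val


def triggered_average(
    trace: np.ndarray,
    fs: float,
    onsets_s,
    pre_s: float = BASELINE_PRE_S,
    post_s: float = 10.0,
    smooth: bool = True,
) -> EvokedResponse:
    """Event-triggered average with per-trial baseline subtraction.

    Each trial is baselined to the mean of the 2 s preceding onset, smoothed
    with a 3rd-order Savitzky-Golay filter, then averaged; trials that run
    off either end of the trace are dropped and counted.
    """
    trace = np.asarray(trace, dtype=float)
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    trials = []
    n_dropped = 0
    for t0 in np.atleast_1d(onsets_s):
        i = int(round(t0 * fs))
        if i - n_pre < 0 or i + n_post > trace.size:
            n_dropped += 1
            continue
        snip = trace[i - n_pre : i + n_post].copy()
        snip -= snip[:n_pre].mean()
        if smooth and snip.size >= SAVGOL_WINDOW:
            snip = savgol_filter(snip, SAVGOL_WINDOW, SAVGOL_ORDER)
        trials.append(snip)
    if not trials:
        raise ParameterError("no usable trials")
    arr = np.stack(trials)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros_like(mean)
    time_s = (np.arange(mean.size) - n_pre) / fs
    return EvokedResponse(time_s=time_s, mean=mean, sem=sem, n_trials=arr.shape[0], n_dropped=n_dropped)


def neurovascular_slope(neural, hbt) -> float:
    """Through-origin least-squares slope: ``sum(x*y) / sum(x*x)``."""
    x = np.asarray(neural, dtype=float).ravel()
    y = np.asarray(hbt, dtype=float).ravel()
    if x.size != y.size:
        raise ParameterError("paired window means must have equal length")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ParameterError("all-zero neural window means; slope undefined")
    return float(np.sum(x * y)) / sxx


def _event_slices(events: list[Segment], fs: float, n: int):
    for ev in events:
        a, b = int(round(ev.start_s * fs)), int(round(ev.stop_s * fs))
        if 0 <= a < b <= n:
            yield a, b


def state_summaries(
    hbt: np.ndarray,
    fs: float,
    labels: ArousalLabels,
    lowpass_hz: float = 1.0,
) -> dict:
    """Per-state summaries of a dHbT trace (single hemisphere).

    Each event is zero-phase lowpassed (< 1 Hz, 4th order) before taking its
    mean (state means) or variance (rest events); event-level values are then
    averaged. States with no events are omitted.
    """
    hbt = np.asarray(hbt, dtype=float)
    n = hbt.size
    out: dict[str, float] = {}

    rest_vars, rest_means = [], []
    for a, b in _event_slices(labels.rest_events, fs, n):
        seg = sp.lowpass(hbt[a:b], fs, lowpass_hz)
        rest_vars.append(float(np.var(seg)))
        rest_means.append(float(np.mean(seg)))
    if rest_vars:
        out["rest_variance"] = float(np.mean(rest_vars))
        out["rest_mean"] = float(np.mean(rest_means))

    for key, events in (("nrem_mean", labels.nrem_events), ("rem_mean", labels.rem_events)):
        means = [
            float(np.mean(sp.lowpass(hbt[a:b], fs, lowpass_hz)))
            for a, b in _event_slices(events, fs, n)
        ]
        if means:
            out[key] = float(np.mean(means))
    return out


def bilateral_comparison(
    left: np.ndarray,
    right: np.ndarray,
    fs: float,
    labels: ArousalLabels,
    coherence_band: tuple[float, float] = (0.1, 0.5),
    nw: float = 3.0,
    k: int = 5,
) -> dict:
    """Rest-event Pearson r and band-mean coherence between hemispheres.

    Traces are mean-subtracted and lowpassed (< 1 Hz) per event before the
    Pearson correlation, matching the cross-correlation convention.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size != right.size:
        raise ParameterError("hemisphere traces must have equal length")
    n = left.size

    rs = []
    events = []
    min_len = None
    for a, b in _event_slices(labels.rest_events, fs, n):
        l = sp.lowpass(left[a:b] - left[a:b].mean(), fs, 1.0)
        r = sp.lowpass(right[a:b] - right[a:b].mean(), fs, 1.0)
        if np.std(l) > 0 and np.std(r) > 0:
            rs.append(float(pearsonr(l, r)[0]))
        length = b - a
        min_len = length if min_len is None else min(min_len, length)
        events.append((a, b))
    out: dict[str, float] = {}
    if rs:
        out["rest_pearson_r"] = float(np.mean(rs))
    if events and min_len is not None and min_len >= 8:
        trimmed = [(a, a + min_len) for a, b in events]
        est = sp.coherence(left, right, fs, nw=nw, k=k, events=trimmed)
        out["rest_coherence"] = est.band_mean(coherence_band)
    return out


def transition_delta(
    trace: np.ndarray,
    fs: float,
    transitions,
    lowpass_hz: float = 1.0,
) -> pd.DataFrame:
    """Pre/post difference around each state transition.

    Difference of the mean over [+10, +30] s minus the mean over [-30, -10] s
    relative to the transition zero point, on the < 1 Hz lowpassed trace.
    Transitions with truncated windows are dropped.
    """
    x = sp.lowpass(np.asarray(trace, dtype=float), fs, lowpass_hz)
    rows = []
    for tr in transitions:
        a_pre = int(round((tr.time_s - 30.0) * fs))
        b_pre = int(round((tr.time_s - 10.0) * fs))
        a_post = int(round((tr.time_s + 10.0) * fs))
        b_post = int(round((tr.time_s + 30.0) * fs))
        if a_pre < 0 or b_post > x.size:
            continue
        rows.append(
            {
                "time_s": tr.time_s,
                "from_state": tr.from_state,
                "to_state": tr.to_state,
                "delta": float(np.mean(x[a_post:b_post]) - np.mean(x[a_pre:b_pre])),
            }
        )
    return pd.DataFrame(rows, columns=["time_s", "from_state", "to_state", "delta"])


def summary_table(rows: list[dict]) -> pd.DataFrame:
    """Stack per-animal/hemisphere/state summary dicts into the export table."""
    return pd.DataFrame(rows)
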