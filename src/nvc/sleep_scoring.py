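"""Arousal-state classification (Awake / NREM / REM per 5-s bin) and session
segmentation into analysis epochs.

Features per bin: cortical delta, beta, and gamma power; hippocampal theta
power; EMG log-power; heart rate; whisking duration. Classification uses a
bagged random forest validated with the out-of-bag error. Segmentation
produces Alert/Asleep 15-min blocks, awake rest events (>= 10 s, no motion),
NREM events (>= 30 s), REM events (>= 60 s), and state transitions (30 s of
one pure state followed by 30 s of another).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import signal_processing as sp
from .errors import ParameterError
from .session import RecordingSession

FEATURE_COLUMNS = [
    "cortical_delta",
    "cortical_beta",
    "cortical_gamma",
    "hippocampal_theta",
    "emg_power",
    "heart_rate",
    "whisking_duration",
]

BIN_S = 5.0
BLOCK_S = 900.0
ALERT_FRACTION = 0.8
REST_MIN_S = 10.0
NREM_MIN_S = 30.0
REM_MIN_S = 60.0
TRANSITION_HALF_S = 30.0
N_TREES_DEFAULT = 128

AWAKE, NREM, REM = 0, 1, 2


@dataclass
class Segment:
    start_s: float
    stop_s: float
    kind: str

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class Transition:
    time_s: float  # zero point
    from_state: int
    to_state: int


@dataclass
class ArousalLabels:
    bin_labels: np.ndarray  # 0/1/2 per 5-s bin
    bin_s: float
    blocks: list[str]  # "Alert" | "Asleep" | "Neither" per block
    block_s: float
    rest_events: list[Segment]
    nrem_events: list[Segment]
    rem_events: list[Segment]
    transitions: list[Transition]


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _bin_band_powers(x: np.ndarray, fs: float, bands: dict, bin_s: float) -> dict:
    """Mean multitaper power per band per bin (5-s windows, 5-s step)."""
    est = sp.multitaper_spectrogram(x, fs, window_s=bin_s, step_s=bin_s, nw=3.0, k=5)
    out = {}
    for name, band in bands.items():
        selm = (est.freqs >= band[0]) & (est.freqs <= band[1])
        out[name] = est.values[:, selm].mean(axis=1)
    return out


def extract_features(session: RecordingSession, bin_s: float = BIN_S) -> pd.DataFrame:
    """FeatureTable: one row per 5-s bin, columns per FEATURE_COLUMNS."""
    for ch in ("lfp_cortexL", "lfp_hipp", "emg", "whisker"):
        if ch not in session.channels:
            raise ParameterError(f"missing channel {ch!r}")
    fs_n = session.fs("lfp_cortexL")
    cort = _bin_band_powers(
        session.channels["lfp_cortexL"], fs_n,
        {"delta": sp.BANDS["delta"], "beta": sp.BANDS["beta"], "gamma": sp.BANDS["gamma"]},
        bin_s,
    )
    hipp = _bin_band_powers(
        session.channels["lfp_hipp"], fs_n, {"theta": sp.BANDS["theta"]}, bin_s
    )
    n_bins = min(cort["delta"].size, hipp["theta"].size)

    emg_env = sp.emg_envelope(session.channels["emg"], session.fs("emg"))
    emg_bins = _bin_means(emg_env.values, emg_env.fs, bin_s, n_bins)

    if "reflectance_530_L" in session.channels:
        hr = sp.heart_rate_estimate(
            session.channels["reflectance_530_L"], session.fs("reflectance_530_L"), bin_s
        )
        hr = _pad_to(hr, n_bins)
    else:
        hr = np.full(n_bins, np.nan)

    whisk = np.asarray(session.channels["whisker"], dtype=float)
    fs_w = session.fs("whisker")
    thr = whisking_threshold(whisk)
    above = whisk > thr
    whisk_dur = _bin_means(above.astype(float), fs_w, bin_s, n_bins) * bin_s

    table = pd.DataFrame(
        {
            "cortical_delta": cort["delta"][:n_bins],
            "cortical_beta": cort["beta"][:n_bins],
            "cortical_gamma": cort["gamma"][:n_bins],
            "hippocampal_theta": hipp["theta"][:n_bins],
            "emg_power": emg_bins,
            "heart_rate": hr,
            "whisking_duration": whisk_dur,
        }
    )
    return table


def _bin_means(x: np.ndarray, fs: float, bin_s: float, n_bins: int) -> np.ndarray:
    reps = int(round(bin_s * fs))
    m = x.size // reps
    out = x[: m * reps].reshape(m, reps).mean(axis=1)
    return _pad_to(out, n_bins)


def _pad_to(x: np.ndarray, n: int) -> np.ndarray:
    if x.size >= n:
        return x[:n]
    return np.concatenate([x, np.full(n - x.size, np.nan)])


def whisking_threshold(whisker: np.ndarray, n_iter: int = 2, k: float = 3.0) -> float:
    """Threshold = k * SD of the whisker signal during detected quiescence,
    iterated ``n_iter`` times starting from the whole-trace SD."""
    w = np.abs(np.asarray(whisker, dtype=float))
    thr = k * w.std()
    for _ in range(n_iter):
        quiet = w[w < thr]
        if quiet.size < 10:
            break
        thr = k * quiet.std() + quiet.mean()
    return float(thr)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class SleepModel:
    forest: RandomForestClassifier
    oob_error: float
    feature_columns: list[str]
    degenerate: bool = False

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = _feature_matrix(features, self.feature_columns)
        return self.forest.predict(X)

    def save(self, path) -> None:
        import joblib

        from . import __version__

        joblib.dump({"model": self, "nvc_version": __version__}, path)

    @classmethod
    def load(cls, path) -> "SleepModel":
        import joblib

        return joblib.load(path)["model"]


def _feature_matrix(features: pd.DataFrame, columns) -> np.ndarray:
    X = np.asarray(features[list(columns)], dtype=float)
    # heart rate may be missing in some bins; impute with the column median
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.all():
            col[:] = 0.0
        elif bad.any():
            col[bad] = np.nanmedian(col)
    return X


def train_classifier(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_trees: int = N_TREES_DEFAULT,
    seed: int = 0,
) -> SleepModel:
    """Bagged random forest with out-of-bag validation.

    Class imbalance is handled with per-bootstrap balanced class weights.
    A single-class input yields a flagged degenerate model (OOB error 0).
    """
    labels = np.asarray(labels)
    if features.shape[0] != labels.size:
        raise ParameterError("features and labels must have equal length")
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    X = _feature_matrix(features, cols)
    classes = np.unique(labels)
    degenerate = classes.size < 2
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=not degenerate,
        bootstrap=True,
        class_weight=None if degenerate else "balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, labels)
    oob_error = 0.0 if degenerate else 1.0 - float(forest.oob_score_)
    return SleepModel(forest=forest, oob_error=oob_error, feature_columns=cols, degenerate=degenerate)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray):
    """Yield (start_idx, stop_idx, value) for maximal constant runs."""
    edges = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], edges])
    stops = np.concatenate([edges, [labels.size]])
    for a, b in zip(starts, stops):
        yield int(a), int(b), labels[a]


def segment_periods(
    bin_labels: np.ndarray,
    whisker: np.ndarray | None = None,
    force: np.ndarray | None = None,
    motion_fs: float = 30.0,
    bin_s: float = BIN_S,
    block_s: float = BLOCK_S,
    exclude_first_s: float = 0.0,
) -> ArousalLabels:
    """Deterministic segmentation of per-bin labels into analysis epochs.

    ``exclude_first_s`` drops the leading stimulation period from block,
    rest, and sleep-event segmentation (labels themselves are kept).
    """
    labels = np.asarray(bin_labels)
    n_bins = labels.size
    first_bin = int(round(exclude_first_s / bin_s))

    # 15-minute Alert/Asleep/Neither blocks
    bins_per_block = int(round(block_s / bin_s))
    blocks = []
    for a in range(first_bin, n_bins - bins_per_block + 1, bins_per_block):
        chunk = labels[a : a + bins_per_block]
        frac_awake = np.mean(chunk == AWAKE)
        frac_sleep = np.mean((chunk == NREM) | (chunk == REM))
        if frac_awake > ALERT_FRACTION:
            blocks.append("Alert")
        elif frac_sleep > ALERT_FRACTION:
            blocks.append("Asleep")
        else:
            blocks.append("Neither")

    # motion mask at the bin level (any supra-threshold motion in the bin)
    moving = np.zeros(n_bins, dtype=bool)
    for trace in (whisker, force):
        if trace is None:
            continue
        trace = np.asarray(trace, dtype=float)
        thr = whisking_threshold(trace)
        above = trace > thr
        reps = int(round(bin_s * motion_fs))
        m = min(n_bins, above.size // reps)
        moving[:m] |= above[: m * reps].reshape(m, reps).any(axis=1)

    rest_events: list[Segment] = []
    nrem_events: list[Segment] = []
    rem_events: list[Segment] = []
    rest_state = np.where((labels == AWAKE) & ~moving, 0, 1)
    for a, b, v in _runs(rest_state):
        if v == 0 and a >= first_bin and (b - a) * bin_s >= REST_MIN_S:
            rest_events.append(Segment(a * bin_s, b * bin_s, "rest"))
    for a, b, v in _runs(labels):
        if a < first_bin:
            continue
        dur = (b - a) * bin_s
        if v == NREM and dur >= NREM_MIN_S:
            nrem_events.append(Segment(a * bin_s, b * bin_s, "nrem"))
        elif v == REM and dur >= REM_MIN_S:
            rem_events.append(Segment(a * bin_s, b * bin_s, "rem"))

    # transitions: 30 s of one pure state immediately followed by 30 s of another
    half = int(round(TRANSITION_HALF_S / bin_s))
    transitions: list[Transition] = []
    for a, b, v in _runs(labels):
        if b >= n_bins or (b - a) < half:
            continue
        nxt_stop = b
        nxt_val = labels[b]
        # length of the following run
        c = b
        while c < n_bins and labels[c] == nxt_val:
            c += 1
        if (c - b) >= half and nxt_val != v and b >= first_bin:
            transitions.append(Transition(time_s=b * bin_s, from_state=int(v), to_state=int(nxt_val)))

    return ArousalLabels(
        bin_labels=labels,
        bin_s=bin_s,
        blocks=blocks,
        block_s=block_s,
        rest_events=rest_events,
        nrem_events=nrem_events,
        rem_events=rem_events,
        transitions=transitions,
    )
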