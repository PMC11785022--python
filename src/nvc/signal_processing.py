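"""Filtering, envelope, multitaper-spectral, coherence and correlation primitives.

Every filter here is zero-phase (forward-backward, second-order sections), so
envelopes and lowpassed traces carry no group delay: a symmetric pulse stays
symmetric and peak latencies are unshifted.

Band conventions (Hz): delta 1-4, theta 4-10, beta 13-30, gamma 30-100.
Power envelopes are emitted at 30 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal

from .errors import ParameterError

#: Canonical LFP band definitions in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 10.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}

#: Output rate of all power envelopes.
ENVELOPE_FS = 30.0

#: EMG band (Hz); truncated at 0.9 Nyquist with a warning when fs is too low.
EMG_BAND = (300.0, 3000.0)

#: Floor applied before the log10 in the EMG envelope.
EMG_LOG_FLOOR = 1e-12


@dataclass
class BandEnvelope:
    """Power envelope of one frequency band, resampled to 30 Hz."""

    values: np.ndarray
    band: tuple[float, float]
    fs: float = ENVELOPE_FS
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SpectralEstimate:
    """A multitaper spectrum, spectrogram, or coherence estimate."""

    freqs: np.ndarray
    values: np.ndarray
    kind: str  # "spectrum" | "spectrogram" | "coherence"
    taper_params: tuple[float, int]
    window_s: float | None = None
    step_s: float | None = None
    times: np.ndarray | None = None

    def band_mean(self, band: tuple[float, float]) -> float:
        """Mean of the estimate over ``band[0] <= f <= band[1]``."""
        sel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not sel.any():
            raise ParameterError(f"band {band} outside estimated frequency range")
        vals = self.values[..., sel] if self.values.ndim > 1 else self.values[sel]
        return float(np.mean(vals))


# ---------------------------------------------------------------------------
# filtering / resampling helpers
# ---------------------------------------------------------------------------

def butter_sos(fs: float, cutoff, btype: str, order: int = 3) -> np.ndarray:
    nyq = fs / 2.0
    hi = np.max(np.atleast_1d(cutoff))
    if hi >= nyq:
        raise ParameterError(f"cutoff {cutoff} Hz at or above Nyquist ({nyq} Hz)")
    return signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")


def zero_phase_filter(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def lowpass(x: np.ndarray, fs: float, cutoff: float = 1.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth lowpass (default < 1 Hz, 4th order)."""
    return zero_phase_filter(x, butter_sos(fs, cutoff, "lowpass", order))


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased resampling from ``fs_in`` to ``fs_out``."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(int(round(fs_out * 1000)), int(round(fs_in * 1000)))
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def band_power_envelope(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    out_fs: float = ENVELOPE_FS,
    source: str = "",
) -> BandEnvelope:
    """Band-limited power envelope.

    Zero-phase 3rd-order Butterworth bandpass, square, zero-phase lowpass
    below 1 Hz, polyphase resample to ``out_fs``. Output is clipped at zero
    (the final filters can leave tiny negative excursions).
    """
    if band[1] >= fs / 2.0:
        raise ParameterError(f"band {band} exceeds Nyquist for fs={fs}")
    y = zero_phase_filter(x, butter_sos(fs, band, "bandpass", order=3))
    p = zero_phase_filter(y * y, butter_sos(fs, 1.0, "lowpass", order=3))
    env = np.clip(resample_to(p, fs, out_fs), 0.0, None)
    return BandEnvelope(values=env, band=(float(band[0]), float(band[1])), fs=out_fs, source=source)


def emg_envelope(
    x: np.ndarray,
    fs: float,
    out_fs: float = ENVELOPE_FS,
    smooth_sigma_s: float = 0.5,
    log_floor: float = EMG_LOG_FLOOR,
) -> BandEnvelope:
    """Log-power EMG envelope.

    Bandpass 300-3000 Hz (truncated when fs is too low), square, Gaussian
    smooth (sigma 0.5 s), log10 with floor, at 30 Hz. The anti-aliased
    resampling is applied to the smoothed power rather than to its log so a
    silent trace stays exactly at the floor (resampling in the log domain
    rings around discontinuities); the two orders are otherwise equivalent
    for the slowly varying envelopes this produces.
    """
    lo, hi = EMG_BAND
    nyq = fs / 2.0
    if hi >= nyq:
        hi = 0.9 * nyq
        warnings.warn(f"EMG band truncated to ({lo}, {hi:.1f}) Hz for fs={fs}", stacklevel=2)
    if lo >= hi:
        lo = 0.3 * hi
        warnings.warn(f"EMG band floor lowered to {lo:.1f} Hz for fs={fs}", stacklevel=2)
    y = zero_phase_filter(x, butter_sos(fs, (lo, hi), "bandpass", order=3))
    p = ndimage.gaussian_filter1d(y * y, sigma=smooth_sigma_s * fs)
    p = resample_to(p, fs, out_fs)
    env = np.log10(np.maximum(p, log_floor))
    return BandEnvelope(values=env, band=(lo, hi), fs=out_fs, source="emg")


# ---------------------------------------------------------------------------
# multitaper estimation
# ---------------------------------------------------------------------------

_TAPER_CACHE: dict[tuple[int, float, int], np.ndarray] = {}


def _dpss_tapers(n: int, nw: float, k: int) -> np.ndarray:
    key = (n, float(nw), k)
    cached = _TAPER_CACHE.get(key)
    if cached is None:
        tapers = signal.windows.dpss(n, nw, Kmax=k)
        # unit-energy tapers -> integrated PSD approximates the variance
        cached = tapers / np.sqrt(np.sum(tapers**2, axis=1, keepdims=True))
        if len(_TAPER_CACHE) > 32:
            _TAPER_CACHE.clear()
        _TAPER_CACHE[key] = cached
    return cached


def _check_tapers(nw: float, k: int) -> None:
    if k < 1 or k > int(2 * nw - 1):
        raise ParameterError(f"taper count K={k} must satisfy 1 <= K <= 2*NW-1 (NW={nw})")


def multitaper_spectrum(
    x: np.ndarray,
    fs: float,
    nw: float = 3.0,
    k: int | None = None,
    detrend: bool = True,
) -> SpectralEstimate:
    """Average of K DPSS-tapered one-sided periodograms.

    Parseval holds: ``sum(values) * df`` approximates the variance of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if k is None:
        k = int(2 * nw - 1)
    _check_tapers(nw, k)
    n = x.size
    if n < 8:
        raise ParameterError("segment too short for spectral estimation")
    if detrend:
        x = signal.detrend(x, type="linear")
    tapers = _dpss_tapers(n, nw, k)
    X = np.fft.rfft(tapers * x[None, :], axis=1)
    psd = (np.abs(X) ** 2).mean(axis=0) / fs
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectralEstimate(freqs=freqs, values=psd, kind="spectrum", taper_params=(nw, k))


def _frame(x: np.ndarray, nwin: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, x.size - nwin + 1, step)
    return np.lib.stride_tricks.sliding_window_view(x, nwin)[starts], starts


def multitaper_spectrogram(
    x: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    step_s: float = 0.2,
    nw: float = 5.0,
    k: int = 9,
    detrend: bool = True,
) -> SpectralEstimate:
    """Sliding-window multitaper spectrogram (default 5 s window, 1/5 s step,
    NW=5 with 9 tapers). ``values`` has shape (n_windows, n_freq)."""
    x = np.asarray(x, dtype=float)
    _check_tapers(nw, k)
    nwin = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    if x.size < nwin:
        raise ParameterError("trace shorter than one spectrogram window")
    frames, starts = _frame(x, nwin, step)
    if detrend:
        frames = signal.detrend(frames, axis=1, type="linear")
    tapers = _dpss_tapers(nwin, nw, k)
    # (n_windows, K, n_freq)
    X = np.fft.rfft(frames[:, None, :] * tapers[None, :, :], axis=2)
    psd = (np.abs(X) ** 2).mean(axis=1) / fs
    psd[:, 1:] *= 2.0
    if nwin % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    times = (starts + nwin / 2.0) / fs
    return SpectralEstimate(
        freqs=freqs, values=psd, kind="spectrogram", taper_params=(nw, k),
        window_s=window_s, step_s=step_s, times=times,
    )


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    nw: float = 3.0,
    k: int = 5,
    events: list[tuple[int, int]] | None = None,
    detrend: bool = True,
) -> SpectralEstimate:
    """Magnitude coherence ``|Sxy| / sqrt(Sxx * Syy)``.

    Cross- and auto-spectra are averaged over the K tapers and, when
    ``events`` (sample-index pairs of equal length) are given, over events.
    Each event is linearly detrended before tapering.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("coherence inputs must have equal length")
    _check_tapers(nw, k)
    if events is None:
        events = [(0, x.size)]
    lengths = {b - a for a, b in events}
    if len(lengths) != 1:
        raise ParameterError("all events must have equal length")
    n = lengths.pop()
    if n < 8:
        raise ParameterError("events too short for spectral estimation")
    tapers = _dpss_tapers(n, nw, k)
    sxx = syy = 0.0
    sxy = 0.0
    for a, b in events:
        xs, ys = x[a:b], y[a:b]
        if detrend:
            xs = signal.detrend(xs, type="linear")
            ys = signal.detrend(ys, type="linear")
        X = np.fft.rfft(tapers * xs[None, :], axis=1)
        Y = np.fft.rfft(tapers * ys[None, :], axis=1)
        sxx = sxx + (np.abs(X) ** 2).sum(axis=0)
        syy = syy + (np.abs(Y) ** 2).sum(axis=0)
        sxy = sxy + (X * np.conj(Y)).sum(axis=0)
    denom = np.sqrt(sxx * syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) / denom
    coh = np.clip(np.nan_to_num(coh, nan=0.0), 0.0, 1.0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectralEstimate(freqs=freqs, values=coh, kind="coherence", taper_params=(nw, k))


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def cross_correlation(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    max_lag_s: float = 5.0,
    prefilter: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation over lags in ``[-max_lag_s, +max_lag_s]``.

    Convention: a peak at **positive** lag means ``y`` follows ``x``.
    Both inputs are mean-subtracted and (by default) zero-phase lowpassed
    below 1 Hz with a 4th-order Butterworth before correlating. The
    normalization makes the zero-lag autocorrelation exactly 1.

    Returns ``(lags_s, r)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("cross_correlation inputs must have equal length")
    max_lag = int(round(max_lag_s * fs))
    if max_lag >= x.size:
        raise ParameterError("max_lag longer than trace")
    if prefilter:
        x = lowpass(x - x.mean(), fs, 1.0, order=4)
        y = lowpass(y - y.mean(), fs, 1.0, order=4)
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt(np.sum(x * x) * np.sum(y * y))
    if denom == 0.0:
        raise ParameterError("zero-variance input to cross_correlation")
    full = signal.correlate(y, x, mode="full", method="fft") / denom
    mid = x.size - 1
    lags = np.arange(-max_lag, max_lag + 1)
    return lags / fs, full[mid - max_lag : mid + max_lag + 1]


# ---------------------------------------------------------------------------
# heart rate
# ---------------------------------------------------------------------------

def heart_rate_estimate(
    reflectance: np.ndarray,
    fs: float,
    bin_s: float = 5.0,
    band: tuple[float, float] = (5.0, 14.0),
    min_band_fraction: float = 1e-3,
    peak_ratio: float = 5.0,
) -> np.ndarray:
    """Per-bin heart rate from the pulsatile component of 530-nm reflectance.

    For each 5-s bin the multitaper spectrum is searched for its peak within
    5-14 Hz. A bin is marked missing (NaN) when the in-band power is a
    negligible fraction of total power or the peak does not stand above the
    in-band median.
    """
    if fs < 2 * band[1]:
        raise ParameterError(f"fs={fs} too low to resolve {band[1]} Hz pulsation")
    x = np.asarray(reflectance, dtype=float)
    nbin = int(round(bin_s * fs))
    n_bins = x.size // nbin
    rates = np.full(n_bins, np.nan)
    for i in range(n_bins):
        seg = x[i * nbin : (i + 1) * nbin]
        est = multitaper_spectrum(seg, fs, nw=2.0, k=3)
        sel = (est.freqs >= band[0]) & (est.freqs <= band[1])
        in_band = est.values[sel]
        total = est.values[1:].sum()  # exclude DC
        if total <= 0 or in_band.sum() / total < min_band_fraction:
            continue
        med = np.median(in_band)
        peak_idx = int(np.argmax(in_band))
        if med > 0 and in_band[peak_idx] / med < peak_ratio:
            continue
        rates[i] = est.freqs[sel][peak_idx]
    return rates
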