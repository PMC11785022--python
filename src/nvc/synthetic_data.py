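"""Synthetic multimodal sessions with known ground truth.

Generates arousal-state-structured sessions: a Markov chain of 5-s
Awake/NREM/REM bins; band-limited LFP and EMG noise whose per-band variance
is set by the active state (EMG atonia in REM); hemodynamics built from the
gamma-band power envelope convolved with a gamma-variate kernel, plus
state-dependent blood-volume offsets, band-limited vasomotion, and
stimulus-evoked transients with an optional post-stimulus undershoot; a
forward Beer-Lambert render to per-wavelength reflectance with attenuated
fluorescence; and vessel cross-section frames with known diameter.

Everything is reproducible: identical parameters and seed give bit-identical
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import signal_processing as sp
from .errors import AlignmentError, ParameterError
from .hrf import gamma_variate
from .session import RecordingSession
from .spectroscopy import SpectroscopyConstants, forward_absorbance

AWAKE, NREM, REM = 0, 1, 2
STATE_NAMES = ("Awake", "NREM", "REM")

_DEFAULT_TRANSITIONS = np.array(
    [
        [0.96, 0.04, 0.00],  # Awake -> (REM unreachable from Awake)
        [0.04, 0.90, 0.06],
        [0.12, 0.00, 0.88],
    ]
)

_DEFAULT_BAND_POWER = {
    # (Awake, NREM, REM), arbitrary units of variance
    "delta": (1.0, 4.0, 1.0),
    "beta": (1.0, 1.3, 0.8),
    "gamma": (1.0, 0.7, 1.4),
    "theta": (1.0, 1.2, 3.5),  # hippocampal
}


@dataclass
class GenParams:
    """Generative parameters for one synthetic session."""

    state_transition_matrix: np.ndarray = field(
        default_factory=lambda: _DEFAULT_TRANSITIONS.copy()
    )
    band_power_by_state: dict = field(default_factory=lambda: dict(_DEFAULT_BAND_POWER))
    emg_power_by_state: tuple = (1.0, 0.25, 0.01)
    hrf_true: tuple = (8.0, 1.0, 2.0)  # (amplitude, time-to-peak s, shape)
    undershoot_gain: float = 1.0
    vasomotion_sigma: float = 6.0  # uM
    bilateral_shared_fraction: float = 0.8
    neural_shared_fraction: float = 0.3
    hbt_offset_by_state: tuple = (0.0, 24.0, 75.0)  # uM
    oxy_ratio: float = 1.3  # dHbO = oxy_ratio * dHbT (dHbR = (1 - oxy_ratio) * dHbT)
    stim_times: np.ndarray = field(default_factory=lambda: np.array([]))
    stim_amp: float = 15.0  # uM, positive lobe
    stim_t_peak: float = 1.0
    stim_shape: float = 2.0
    undershoot_amp: float = 9.0  # uM, scaled by undershoot_gain
    undershoot_t_peak: float = 1.5
    undershoot_delay: float = 1.0  # s after onset
    heart_amp: float = 0.0  # fractional 530-nm pulsation; 0 = noiseless render
    heart_rate_by_state: tuple = (10.0, 7.5, 8.5)  # Hz
    dff_gain: float = 0.05
    baseline_diameter_um: float = 20.0
    diameter_per_uM: float = 0.002  # fractional diameter change per uM dHbT
    bin_s: float = 5.0
    fs_neural: float = 1000.0
    fs_optical: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.state_transition_matrix, dtype=float)
        if P.shape != (3, 3) or (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
            raise ParameterError("state_transition_matrix must be 3x3 row-stochastic")
        if P[AWAKE, REM] != 0.0:
            raise ParameterError("REM must only be reachable from NREM (Awake->REM must be 0)")
        self.state_transition_matrix = P
        if self.vasomotion_sigma < 0:
            raise ParameterError("vasomotion_sigma must be >= 0")
        if not 0.0 <= self.bilateral_shared_fraction <= 1.0:
            raise ParameterError("bilateral_shared_fraction must lie in [0, 1]")
        self.stim_times = np.asarray(self.stim_times, dtype=float)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class NeuralTraces:
    cortex_left: np.ndarray
    cortex_right: np.ndarray
    hippocampus: np.ndarray
    emg: np.ndarray
    fs: float


@dataclass
class HemoTruth:
    hbt: np.ndarray  # (2, nt) uM, rows = (left, right)
    hbo: np.ndarray
    hbr: np.ndarray
    diameter_um: np.ndarray
    kernel: np.ndarray  # discrete kernel actually convolved
    fs: float


@dataclass
class GroundTruth:
    """Generative truth for every downstream stage of one session."""

    params: GenParams
    state_sequence: np.ndarray  # per-bin labels
    true_kernel: np.ndarray
    true_hbt: np.ndarray
    true_hbo: np.ndarray
    true_hbr: np.ndarray
    true_diameter_um: np.ndarray
    true_band_envelopes: dict
    gamma_envelope: np.ndarray
    dff_true: np.ndarray
    neural: NeuralTraces

    def states_per_optical_sample(self) -> np.ndarray:
        reps = int(round(self.params.bin_s * self.params.fs_optical))
        return np.repeat(self.state_sequence, reps)


# ---------------------------------------------------------------------------
# state sequence
# ---------------------------------------------------------------------------

def simulate_state_sequence(
    params: GenParams, n_bins: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Markov-chain arousal states, one label per 5-s bin, starting Awake."""
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    rng = params.rng() if rng is None else rng
    P = params.state_transition_matrix
    cum = np.cumsum(P, axis=1)
    states = np.empty(n_bins, dtype=np.int64)
    s = AWAKE
    u = rng.random(n_bins)
    for i in range(n_bins):
        states[i] = s
        s = int(np.searchsorted(cum[s], u[i], side="right"))
        s = min(s, 2)
    return states


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix with eigenvalue 1."""
    w, v = np.linalg.eig(np.asarray(P, dtype=float).T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# neural traces
# ---------------------------------------------------------------------------

def _band_noise(n: int, fs: float, band, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    white = rng.standard_normal(n)
    y = sp.zero_phase_filter(white, sp.butter_sos(fs, band, "bandpass", order=3))
    sd = y.std()
    return y / sd if sd > 0 else y


def _per_sample_power(states: np.ndarray, powers, reps: int) -> np.ndarray:
    lut = np.asarray(powers, dtype=float)
    return np.repeat(lut[states], reps)


def synthesize_neural(
    states: np.ndarray, params: GenParams, rng: np.random.Generator | None = None
) -> NeuralTraces:
    """Band-structured LFP/EMG noise following ``band_power_by_state``.

    Cortical traces are sums of delta/beta/gamma band-limited noise whose
    per-sample variance tracks the active state; left and right hemispheres
    share ``neural_shared_fraction`` of each band's variance. The hippocampal
    trace carries the theta band; EMG power is lowest in REM (atonia).
    """
    states = np.asarray(states)
    if states.size == 0:
        raise ParameterError("state sequence is empty")
    rng = params.rng() if rng is None else rng
    fs = params.fs_neural
    reps = int(round(params.bin_s * fs))
    n = states.size * reps

    f_sh = params.neural_shared_fraction
    cortex = {"left": np.zeros(n), "right": np.zeros(n)}
    for band_name in ("delta", "beta", "gamma"):
        band = sp.BANDS[band_name]
        gain = np.sqrt(_per_sample_power(states, params.band_power_by_state[band_name], reps))
        shared = _band_noise(n, fs, band, rng)
        for side in ("left", "right"):
            own = _band_noise(n, fs, band, rng)
            mixed = np.sqrt(f_sh) * shared + np.sqrt(1.0 - f_sh) * own
            cortex[side] += gain * mixed

    theta_gain = np.sqrt(_per_sample_power(states, params.band_power_by_state["theta"], reps))
    hippocampus = theta_gain * _band_noise(n, fs, sp.BANDS["theta"], rng)

    lo, hi = sp.EMG_BAND
    if hi >= fs / 2.0:
        hi = 0.9 * fs / 2.0
    if lo >= hi:
        lo = 0.3 * hi
    emg_gain = np.sqrt(_per_sample_power(states, params.emg_power_by_state, reps))
    emg = emg_gain * _band_noise(n, fs, (lo, hi), rng)

    return NeuralTraces(
        cortex_left=cortex["left"],
        cortex_right=cortex["right"],
        hippocampus=hippocampus,
        emg=emg,
        fs=fs,
    )


def true_band_envelopes(states: np.ndarray, params: GenParams) -> dict:
    """Ground-truth per-band power at the optical rate (step per 5-s bin)."""
    reps = int(round(params.bin_s * params.fs_optical))
    return {
        name: _per_sample_power(states, powers, reps)
        for name, powers in params.band_power_by_state.items()
    }


# ---------------------------------------------------------------------------
# hemodynamics
# ---------------------------------------------------------------------------

def stimulus_response_kernel(params: GenParams) -> np.ndarray:
    """Evoked transient: positive lobe plus delayed, scaled negative lobe."""
    fs = params.fs_optical
    t = np.arange(0.0, 12.0, 1.0 / fs)
    pos = gamma_variate(t, params.stim_amp, params.stim_t_peak, params.stim_shape)
    neg = gamma_variate(
        t - params.undershoot_delay,
        params.undershoot_amp,
        params.undershoot_t_peak,
        params.stim_shape,
    )
    return pos - params.undershoot_gain * neg


def synthesize_hemodynamics(
    gamma_envelope: np.ndarray,
    states: np.ndarray,
    params: GenParams,
    rng: np.random.Generator | None = None,
) -> HemoTruth:
    """Ground-truth hemodynamics for both hemispheres.

    dHbT = conv(gamma envelope, true kernel) + state-dependent offset
         + vasomotion (0.05-0.3 Hz, SD = vasomotion_sigma)
         + stimulus transients (with optional undershoot).

    Hemispheres share ``bilateral_shared_fraction`` of the vasomotion
    variance (the convolved neural drive and evoked transients are common).
    dHbO/dHbR follow the fixed oxygenation split so dHbT = dHbO + dHbR
    exactly; the vessel diameter trace is an affine map of left dHbT.
    """
    rng = params.rng() if rng is None else rng
    fs = params.fs_optical
    env = np.asarray(gamma_envelope, dtype=float)
    reps = int(round(params.bin_s * fs))
    nt = np.asarray(states).size * reps
    if env.size != nt:
        raise AlignmentError(
            f"gamma envelope length {env.size} does not match {nt} optical samples"
        )

    t_k = np.arange(0.0, 5.0, 1.0 / fs)
    kernel = gamma_variate(t_k, *params.hrf_true) / fs
    drive = np.convolve(env - env.mean(), kernel, mode="full")[:nt]

    offsets = _per_sample_power(np.asarray(states), params.hbt_offset_by_state, reps)
    offsets = ndimage.gaussian_filter1d(offsets, sigma=fs)  # 1-s ramp at bin edges

    sigma = params.vasomotion_sigma
    f_sh = params.bilateral_shared_fraction
    if sigma > 0:
        shared = sigma * _band_noise(nt, fs, (0.05, 0.3), rng)
        vas = [
            np.sqrt(f_sh) * shared + np.sqrt(1.0 - f_sh) * sigma * _band_noise(nt, fs, (0.05, 0.3), rng)
            for _ in range(2)
        ]
    else:
        # consume the same number of draws for seed stability across sigma
        vas = [np.zeros(nt), np.zeros(nt)]

    stim = np.zeros(nt)
    resp = stimulus_response_kernel(params)
    for t0 in params.stim_times:
        a = int(round(t0 * fs))
        if a >= nt:
            continue
        b = min(a + resp.size, nt)
        stim[a:b] += resp[: b - a]

    hbt = np.stack([drive + offsets + v + stim for v in vas])
    hbo = params.oxy_ratio * hbt
    hbr = hbt - hbo
    diameter = params.baseline_diameter_um * (1.0 + params.diameter_per_uM * hbt[0])
    return HemoTruth(hbt=hbt, hbo=hbo, hbr=hbr, diameter_um=diameter, kernel=kernel, fs=fs)


# ---------------------------------------------------------------------------
# behavioral traces
# ---------------------------------------------------------------------------

def _behavior_trace(
    states: np.ndarray,
    params: GenParams,
    rng: np.random.Generator,
    bout_prob: float,
    amplitude: float = 1.0,
    noise_sd: float = 0.01,
) -> np.ndarray:
    """Motion-magnitude trace: quiet floor plus bouts in random Awake bins."""
    reps = int(round(params.bin_s * params.fs_optical))
    nt = states.size * reps
    x = np.abs(noise_sd * rng.standard_normal(nt))
    for i, s in enumerate(states):
        if s == AWAKE and rng.random() < bout_prob:
            a = i * reps + rng.integers(0, reps // 2)
            b = min(a + rng.integers(reps // 4, reps), nt)
            x[a:b] += amplitude * np.abs(rng.standard_normal(b - a))
    return x


# ---------------------------------------------------------------------------
# forward render
# ---------------------------------------------------------------------------

def render_session(
    truth: GroundTruth,
    constants: SpectroscopyConstants,
    params: GenParams,
    i0: float = 2000.0,
    f0: float = 1000.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    vessel_fs: float = 5.0,
    vessel_shape: tuple[int, int] = (64, 64),
    vessel_pixel_size_um: float = 0.5,
    max_vessel_frames: int | None = 2000,
) -> RecordingSession:
    """Forward-model a GroundTruth into a RecordingSession.

    Per-wavelength reflectance follows the forward Beer-Lambert model
    ``I = I0 * exp(-dA)``; fluorescence is the true calcium signal attenuated
    by the normalized 530-nm reflectance; vessel cross-section frames are
    blurred discs of the true diameter.
    """
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    fs = params.fs_optical
    nt = truth.true_hbt.shape[1]
    tvec = np.arange(nt) / fs

    channels: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    sides = ("L", "R")
    for h, side in enumerate(sides):
        dA = forward_absorbance(truth.true_hbo[h], truth.true_hbr[h], constants)
        for w, wl in enumerate(constants.wavelengths):
            I = i0 * np.exp(-dA[w])
            if params.heart_amp > 0:
                f_hr = _per_sample_power(
                    truth.state_sequence, params.heart_rate_by_state, int(round(params.bin_s * fs))
                )
                phase = 2.0 * np.pi * np.cumsum(f_hr) / fs
                I = I * (1.0 + params.heart_amp * np.sin(phase))
            if noise_sd > 0:
                I = I + noise_sd * i0 * rng.standard_normal(nt)
            if (I <= 0).any():
                raise ParameterError("rendered reflectance is non-positive")
            channels[f"reflectance_{int(wl)}_{side}"] = I
            rates[f"reflectance_{int(wl)}_{side}"] = fs
        g = channels[f"reflectance_530_{side}"]
        F = f0 * (1.0 + truth.dff_true) * (g / i0)
        if noise_sd > 0:
            F = F + noise_sd * f0 * rng.standard_normal(nt)
        channels[f"fluorescence_{side}"] = F
        rates[f"fluorescence_{side}"] = fs

    for name, trace in (
        ("lfp_cortexL", truth.neural.cortex_left),
        ("lfp_cortexR", truth.neural.cortex_right),
        ("lfp_hipp", truth.neural.hippocampus),
        ("emg", truth.neural.emg),
    ):
        channels[name] = trace
        rates[name] = truth.neural.fs

    channels["whisker"] = _behavior_trace(truth.state_sequence, params, rng, bout_prob=0.45)
    rates["whisker"] = fs
    channels["force"] = _behavior_trace(truth.state_sequence, params, rng, bout_prob=0.15)
    rates["force"] = fs

    events = pd.DataFrame(
        {
            "onset_s": params.stim_times,
            "type": ["stim_contra"] * params.stim_times.size,
            "duration_s": [0.1] * params.stim_times.size,
            "side": ["left"] * params.stim_times.size,
        }
    )

    step = max(1, int(round(fs / vessel_fs)))
    diam = truth.true_diameter_um
    if max_vessel_frames is not None:
        diam = diam[: max_vessel_frames * step]
    vessel_frames = render_vessel_frames(
        diam, fs, vessel_fs, vessel_shape, vessel_pixel_size_um,
        noise_sd=noise_sd, rng=rng,
    )
    meta = {
        "fs_neural": params.fs_neural,
        "fs_optical": fs,
        "bin_s": params.bin_s,
        "seed": params.seed,
        "vessel_fs": vessel_fs,
        "vessel_pixel_size_um": vessel_pixel_size_um,
        "i0": i0,
        "f0": f0,
    }
    return RecordingSession(
        channels=channels, rates=rates, events=events, meta=meta, vessel_frames=vessel_frames
    )


def render_vessel_frames(
    diameter_um: np.ndarray,
    fs_in: float,
    fs_out: float,
    shape: tuple[int, int],
    pixel_size_um: float,
    blur_sigma_px: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Disc cross-section frames with the true diameter, blur, and noise."""
    rng = np.random.default_rng(0) if rng is None else rng
    step = max(1, int(round(fs_in / fs_out)))
    diam = np.asarray(diameter_um, dtype=float)[::step]
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # center on the projection rotation-center convention (n // 2)
    r_grid = np.sqrt((yy - h // 2) ** 2 + (xx - w // 2) ** 2)
    radius_px = diam[:, None, None] / 2.0 / pixel_size_um
    frames = np.clip(radius_px + 0.5 - r_grid[None], 0.0, 1.0)  # anti-aliased edge
    frames = ndimage.gaussian_filter(frames, (0.0, blur_sigma_px, blur_sigma_px))
    if noise_sd > 0:
        frames = np.abs(frames + noise_sd * rng.standard_normal(frames.shape))
    return frames


# ---------------------------------------------------------------------------
# one-call generation
# ---------------------------------------------------------------------------

def generate_session(
    params: GenParams,
    duration_s: float | None = None,
    n_bins: int | None = None,
    constants: SpectroscopyConstants | None = None,
    noise_sd: float = 0.0,
) -> tuple[RecordingSession, GroundTruth]:
    """Generate a complete session plus its GroundTruth.

    The hemodynamic drive is the *measured* gamma-band power envelope of the
    left cortical LFP, so downstream kernel estimation on the rendered data
    is well-posed by construction.
    """
    if n_bins is None:
        if duration_s is None:
            raise ParameterError("give duration_s or n_bins")
        n_bins = int(round(duration_s / params.bin_s))
    constants = SpectroscopyConstants.default() if constants is None else constants
    rng = params.rng()
    states = simulate_state_sequence(params, n_bins, rng)
    neural = synthesize_neural(states, params, rng)
    env = sp.band_power_envelope(
        neural.cortex_left, params.fs_neural, sp.BANDS["gamma"], out_fs=params.fs_optical
    ).values
    hemo = synthesize_hemodynamics(env, states, params, rng)
    dff = params.dff_gain * (env - env.mean()) / (env.std() if env.std() > 0 else 1.0)
    truth = GroundTruth(
        params=params,
        state_sequence=states,
        true_kernel=hemo.kernel,
        true_hbt=hemo.hbt,
        true_hbo=hemo.hbo,
        true_hbr=hemo.hbr,
        true_diameter_um=hemo.diameter_um,
        true_band_envelopes=true_band_envelopes(states, params),
        gamma_envelope=env,
        dff_true=dff,
        neural=neural,
    )
    session = render_session(truth, constants, params, noise_sd=noise_sd, rng=rng)
    return session, truth
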