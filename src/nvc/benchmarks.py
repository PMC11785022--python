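"""End-to-end experiment drivers used by the acceptance checks.

These run the full pipeline on synthetic ground truth at desk scale:
sleep-scoring parameter recovery, and the control-vs-ablated contrast
experiment (reduced delta power, no post-stimulus undershoot, reduced
vasomotion, reduced bilateral sharing) whose qualitative signs mirror the
headline in-vivo contrasts.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import norm

from . import event_analysis as ea
from . import signal_processing as sp
from . import sleep_scoring as ss
from . import synthetic_data as sd
from . import vessel_diametry as vd
from .session import RecordingSession
from .spectroscopy import SpectroscopyConstants, delta_absorbance, invert_beer_lambert


def power_analysis_n_per_group(d: float = 1.3, alpha: float = 0.05, power: float = 0.80) -> float:
    """Per-group sample size for a two-sided two-sample t-test, normal
    approximation: ``n = 2 * ((z_{1-alpha/2} + z_{power}) / d)^2``."""
    za = norm.ppf(1.0 - alpha / 2.0)
    zb = norm.ppf(power)
    return 2.0 * ((za + zb) / d) ** 2


# ---------------------------------------------------------------------------
# sleep-scoring recovery
# ---------------------------------------------------------------------------

def _scoring_session(params: sd.GenParams, n_bins: int) -> tuple[RecordingSession, np.ndarray]:
    """Lightweight session for scoring: neural + behavior + 530-nm pulsation
    only (no full optical render), to keep 10^4-bin runs cheap."""
    rng = params.rng()
    states = sd.simulate_state_sequence(params, n_bins, rng)
    neural = sd.synthesize_neural(states, params, rng)
    fs = params.fs_optical
    reps = int(round(params.bin_s * fs))
    nt = n_bins * reps
    f_hr = np.repeat(np.asarray(params.heart_rate_by_state)[states], reps)
    phase = 2.0 * np.pi * np.cumsum(f_hr) / fs
    reflect = 2000.0 * (1.0 + 0.004 * np.sin(phase))
    channels = {
        "lfp_cortexL": neural.cortex_left,
        "lfp_cortexR": neural.cortex_right,
        "lfp_hipp": neural.hippocampus,
        "emg": neural.emg,
        "whisker": sd._behavior_trace(states, params, rng, bout_prob=0.45),
        "force": sd._behavior_trace(states, params, rng, bout_prob=0.15),
        "reflectance_530_L": reflect,
    }
    rates = {k: (neural.fs if k.startswith(("lfp", "emg")) else fs) for k in channels}
    session = RecordingSession(channels=channels, rates=rates, meta={"seed": params.seed})
    return session, states


def sleep_scoring_recovery(
    n_bins: int = 10000, seed: int = 0, fs_neural: float = 500.0
) -> dict:
    """Train on the first half of a default synthetic session, report held-out
    bin accuracy, OOB error, and the label-permutation OOB null."""
    params = sd.GenParams(seed=seed, fs_neural=fs_neural)
    session, states = _scoring_session(params, n_bins)
    features = ss.extract_features(session)
    labels = states[: len(features)]
    half = len(features) // 2
    model = ss.train_classifier(features.iloc[:half], labels[:half], seed=seed)
    pred = model.predict(features.iloc[half:])
    accuracy = float(np.mean(pred == labels[half:]))

    rng = np.random.default_rng(seed)
    n_perm = min(3000, half)
    shuffled = rng.permutation(labels[:n_perm])
    perm_model = ss.train_classifier(features.iloc[:n_perm], shuffled, seed=seed)
    chance = 1.0 - float(np.max(np.bincount(shuffled) / shuffled.size))
    return {
        "accuracy": accuracy,
        "oob_error": model.oob_error,
        "oob_error_shuffled": perm_model.oob_error,
        "chance_error": chance,
        "n_bins": n_bins,
    }


# ---------------------------------------------------------------------------
# control vs ablated pipeline contrast
# ---------------------------------------------------------------------------

def control_params(seed: int = 0, fs_neural: float = 250.0) -> sd.GenParams:
    return sd.GenParams(seed=seed, fs_neural=fs_neural, vasomotion_sigma=6.4)


def ablated_params(seed: int = 0, fs_neural: float = 250.0) -> sd.GenParams:
    """Reduced delta power (~70%), no undershoot, ~40% less vasomotion,
    halved bilateral sharing."""
    p = control_params(seed, fs_neural)
    bands = dict(p.band_power_by_state)
    bands["delta"] = tuple(0.3 * v for v in sd._DEFAULT_BAND_POWER["delta"])
    return replace(
        p,
        band_power_by_state=bands,
        undershoot_gain=0.0,
        vasomotion_sigma=6.4 * 0.6,
        bilateral_shared_fraction=0.4,
    )


def _sleep_state_layout() -> np.ndarray:
    """Deterministic 2700-s layout: one alert block then two asleep blocks
    containing long NREM runs and REM bouts of scorable length."""
    states = np.full(540, sd.NREM, dtype=np.int64)
    states[:180] = sd.AWAKE
    states[250:266] = sd.REM  # 80 s
    states[300:302] = sd.AWAKE  # brief waking, block stays >80% asleep
    states[420:438] = sd.REM  # 90 s
    return states


def _invert_hbt(session: RecordingSession, constants: SpectroscopyConstants, side: str = "L"):
    i0 = session.meta["i0"]
    dA = np.stack(
        [
            delta_absorbance(session.channels[f"reflectance_{int(w)}_{side}"], i0)
            for w in constants.wavelengths
        ]
    )
    return invert_beer_lambert(dA, constants).dhbt


def _build_session(params: sd.GenParams, states: np.ndarray) -> tuple[RecordingSession, sd.GroundTruth]:
    """generate_session with an externally supplied state sequence."""
    constants = SpectroscopyConstants.default()
    rng = params.rng()
    neural = sd.synthesize_neural(states, params, rng)
    env = sp.band_power_envelope(
        neural.cortex_left, params.fs_neural, sp.BANDS["gamma"], out_fs=params.fs_optical
    ).values
    hemo = sd.synthesize_hemodynamics(env, states, params, rng)
    dff = params.dff_gain * (env - env.mean()) / (env.std() if env.std() > 0 else 1.0)
    truth = sd.GroundTruth(
        params=params,
        state_sequence=states,
        true_kernel=hemo.kernel,
        true_hbt=hemo.hbt,
        true_hbo=hemo.hbo,
        true_hbr=hemo.hbr,
        true_diameter_um=hemo.diameter_um,
        true_band_envelopes=sd.true_band_envelopes(states, params),
        gamma_envelope=env,
        dff_true=dff,
        neural=neural,
    )
    session = sd.render_session(truth, constants, params, rng=rng)
    return session, truth


def pipeline_contrast(seed: int, ablated: bool, measure_vessels: bool = True) -> dict:
    """One seed of the control-vs-ablated experiment; returns headline metrics.

    Two sessions per condition: a 900-s awake stimulation session (evoked
    response) and a 2700-s rest/sleep session (spectra, coherence, variance,
    state means, vessel diametry).
    """
    make = ablated_params if ablated else control_params
    constants = SpectroscopyConstants.default()
    fs_opt = 30.0
    out: dict[str, float] = {}

    # --- stimulation session: post-stimulus undershoot window -------------
    stim_times = np.arange(20.0, 870.0, 35.0)
    p_stim = replace(make(seed), stim_times=stim_times)
    stim_states = np.zeros(180, dtype=np.int64)
    stim_session, _ = _build_session(p_stim, stim_states)
    hbt_stim = _invert_hbt(stim_session, constants)
    resp = ea.triggered_average(hbt_stim, fs_opt, stim_times, post_s=10.0)
    out["evoked_2_4_uM"] = resp.window_mean(2.0, 4.0)

    # --- rest/sleep session ----------------------------------------------
    p_rest = make(seed + 1000)
    states = _sleep_state_layout()
    session, truth = _build_session(p_rest, states)

    # delta-band LFP power by 15-min block category; the LFP is decimated to
    # 100 Hz first (the delta band sits far below that Nyquist and the taper
    # solve scales with segment length)
    fs_dec = 100.0
    lfp = sp.resample_to(session.channels["lfp_cortexL"], p_rest.fs_neural, fs_dec)
    block_len = int(900 * fs_dec)
    delta_by_block = []
    for b in range(3):
        est = sp.multitaper_spectrum(lfp[b * block_len : (b + 1) * block_len], fs_dec, nw=5.0, k=9)
        delta_by_block.append(est.band_mean(sp.BANDS["delta"]))
    out["delta_power_alert"] = delta_by_block[0]
    out["delta_power_asleep"] = float(np.mean(delta_by_block[1:]))
    out["delta_power_all"] = float(np.mean(delta_by_block))

    # arousal segmentation from ground-truth labels (scoring is validated
    # separately); motionless awake period = rest
    labels = ss.segment_periods(
        states,
        whisker=np.zeros(states.size * 150),
        force=np.zeros(states.size * 150),
        motion_fs=fs_opt,
    )

    hbt_l = _invert_hbt(session, constants, "L")
    hbt_r = _invert_hbt(session, constants, "R")
    summaries = ea.state_summaries(hbt_l, fs_opt, labels)
    out["rest_hbt_variance_uM2"] = summaries["rest_variance"]
    out["nrem_hbt_mean_uM"] = summaries["nrem_mean"]
    out["rem_hbt_mean_uM"] = summaries["rem_mean"]

    bilat = ea.bilateral_comparison(hbt_l, hbt_r, fs_opt, labels, coherence_band=(0.01, 0.5))
    out["bilateral_rest_coherence"] = bilat["rest_coherence"]
    out["bilateral_rest_pearson_r"] = bilat["rest_pearson_r"]

    # single-arteriole resting diameter variance via TiRS on rendered frames
    if measure_vessels:
        px = session.meta["vessel_pixel_size_um"]
        vfs = session.meta["vessel_fs"]
        frames = session.vessel_frames[::12]  # ~0.42 Hz over the awake period
        diam = np.full(frames.shape[0], np.nan)
        for i, fr in enumerate(frames):
            try:
                diam[i] = vd.tirs_diameter(fr, pixel_size_um=px)
            except Exception:
                pass
        trace = vd.summarize_trace(
            diam, fs=vfs / 12.0, rest_events=[(0.0, diam.size * 12.0 / vfs)]
        )
        out["rest_diameter_variance_pct2"] = trace.resting_variance
    return out


def contrast_experiment(seeds=range(10), measure_vessels: bool = True) -> dict:
    """Mean metrics across seeds for control and ablated parameter sets."""
    results = {"control": [], "ablated": []}
    for seed in seeds:
        results["control"].append(pipeline_contrast(seed, ablated=False, measure_vessels=measure_vessels))
        results["ablated"].append(pipeline_contrast(seed, ablated=True, measure_vessels=measure_vessels))
    means = {
        cond: {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
        for cond, rows in results.items()
    }
    means["per_seed"] = results
    return means
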