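import numpy as np
import pytest

from nvc import signal_processing as sp
from nvc import synthetic_data as sd
from nvc.errors import AlignmentError, ParameterError
from nvc.spectroscopy import SpectroscopyConstants, delta_absorbance, invert_beer_lambert


class TestStateSequence:
    def test_absorbing_identity_matrix_stays_awake(self):
        p = sd.GenParams(state_transition_matrix=np.eye(3))
        states = sd.simulate_state_sequence(p, 500)
        assert (states == sd.AWAKE).all()

    def test_forbidden_awake_to_rem(self):
        p = sd.GenParams(seed=11)
        states = sd.simulate_state_sequence(p, 100000)
        pairs = set(zip(states[:-1], states[1:]))
        assert (sd.AWAKE, sd.REM) not in pairs

    def test_occupancy_matches_stationary_distribution(self):
        P = np.array([[0.8, 0.2, 0.0], [0.1, 0.8, 0.1], [0.3, 0.0, 0.7]])
        p = sd.GenParams(state_transition_matrix=P, seed=2)
        states = sd.simulate_state_sequence(p, 100000)
        pi = sd.stationary_distribution(P)
        occ = np.bincount(states, minlength=3) / states.size
        np.testing.assert_allclose(occ, pi, atol=0.02)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ParameterError):
            sd.GenParams(state_transition_matrix=np.full((3, 3), 0.5))

    def test_awake_to_rem_probability_rejected(self):
        P = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.3, 0.0, 0.7]])
        with pytest.raises(ParameterError):
            sd.GenParams(state_transition_matrix=P)

    def test_seed_reproducibility(self):
        a = sd.simulate_state_sequence(sd.GenParams(seed=5), 2000)
        b = sd.simulate_state_sequence(sd.GenParams(seed=5), 2000)
        np.testing.assert_array_equal(a, b)


class TestSynthesizeNeural:
    def test_gamma_power_ratio(self):
        # all-Awake with awake gamma power = 2x the NREM setting
        bands = dict(sd._DEFAULT_BAND_POWER)
        bands["gamma"] = (2.0, 1.0, 1.0)
        p = sd.GenParams(band_power_by_state=bands, seed=3)
        awake = sd.synthesize_neural(np.zeros(40, dtype=int), p)
        nrem = sd.synthesize_neural(np.ones(40, dtype=int), p)
        fs = p.fs_neural

        def gamma_var(x):
            y = sp.zero_phase_filter(x, sp.butter_sos(fs, (30.0, 100.0), "bandpass", 3))
            return np.var(y)

        ratio = gamma_var(awake.cortex_left) / gamma_var(nrem.cortex_left)
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_zero_power_gives_zero_traces(self):
        bands = {k: (0.0, 0.0, 0.0) for k in sd._DEFAULT_BAND_POWER}
        p = sd.GenParams(band_power_by_state=bands, emg_power_by_state=(0.0, 0.0, 0.0))
        out = sd.synthesize_neural(np.zeros(10, dtype=int), p)
        assert np.allclose(out.cortex_left, 0) and np.allclose(out.emg, 0)
        assert np.allclose(out.hippocampus, 0)

    def test_emg_atonia_in_rem(self):
        p = sd.GenParams(seed=4)
        nrem = sd.synthesize_neural(np.ones(30, dtype=int), p)
        rem = sd.synthesize_neural(np.full(30, 2, dtype=int), p)
        assert np.var(nrem.emg) > np.var(rem.emg)

    def test_empty_states_rejected(self):
        with pytest.raises(ParameterError):
            sd.synthesize_neural(np.array([], dtype=int), sd.GenParams())


class TestSynthesizeHemodynamics:
    def _flat_envelope(self, n_bins, p):
        return np.zeros(int(n_bins * p.bin_s * p.fs_optical))

    def test_undershoot_zero_gives_nonnegative_post_stim(self):
        p = sd.GenParams(
            undershoot_gain=0.0, vasomotion_sigma=0.0,
            stim_times=np.array([20.0]), seed=0,
        )
        states = np.zeros(12, dtype=int)
        hemo = sd.synthesize_hemodynamics(self._flat_envelope(12, p), states, p)
        fs = p.fs_optical
        post = hemo.hbt[0, int(20 * fs) : int(30 * fs)]
        assert post.min() >= -1e-12

    def test_undershoot_gain_makes_window_negative(self):
        p = sd.GenParams(vasomotion_sigma=0.0, stim_times=np.array([20.0]), seed=0)
        states = np.zeros(12, dtype=int)
        hemo = sd.synthesize_hemodynamics(self._flat_envelope(12, p), states, p)
        fs = p.fs_optical
        window = hemo.hbt[0, int(22 * fs) : int(24 * fs)]
        assert window.mean() < 0

    def test_full_shared_fraction_identical_hemispheres(self):
        p = sd.GenParams(bilateral_shared_fraction=1.0, seed=1)
        states = np.zeros(12, dtype=int)
        hemo = sd.synthesize_hemodynamics(self._flat_envelope(12, p), states, p)
        np.testing.assert_allclose(hemo.hbt[0], hemo.hbt[1], atol=1e-12)

    def test_vasomotion_sigma_sets_resting_sd(self):
        p = sd.GenParams(vasomotion_sigma=6.0, seed=6)
        states = np.zeros(240, dtype=int)  # 20 min awake, no stimuli
        hemo = sd.synthesize_hemodynamics(self._flat_envelope(240, p), states, p)
        assert np.std(hemo.hbt[0]) == pytest.approx(6.0, rel=0.10)

    def test_hbt_equals_hbo_plus_hbr_exactly(self):
        p = sd.GenParams(seed=2, stim_times=np.array([10.0]))
        states = sd.simulate_state_sequence(p, 24)
        env = np.abs(np.random.default_rng(0).standard_normal(int(24 * 5 * 30)))
        hemo = sd.synthesize_hemodynamics(env, states, p)
        np.testing.assert_array_equal(hemo.hbt, hemo.hbo + hemo.hbr)

    def test_monotone_variance_in_vasomotion_sigma(self):
        states = np.zeros(120, dtype=int)
        sds = []
        for sigma in (2.0, 4.0, 8.0):
            p = sd.GenParams(vasomotion_sigma=sigma, seed=9)
            env = self._flat_envelope(120, p)
            sds.append(np.std(sd.synthesize_hemodynamics(env, states, p).hbt[0]))
        assert sds[0] < sds[1] < sds[2]

    def test_misaligned_envelope_rejected(self):
        p = sd.GenParams()
        with pytest.raises(AlignmentError):
            sd.synthesize_hemodynamics(np.zeros(10), np.zeros(12, dtype=int), p)

    def test_diameter_is_affine_in_hbt(self):
        p = sd.GenParams(seed=3)
        states = np.zeros(24, dtype=int)
        hemo = sd.synthesize_hemodynamics(self._flat_envelope(24, p), states, p)
        expected = p.baseline_diameter_um * (1 + p.diameter_per_uM * hemo.hbt[0])
        np.testing.assert_allclose(hemo.diameter_um, expected)


class TestRenderAndRoundTrip:
    def test_zero_concentrations_give_i0(self):
        p = sd.GenParams(vasomotion_sigma=0.0, hbt_offset_by_state=(0.0, 0.0, 0.0), seed=0)
        states = np.zeros(6, dtype=int)
        nt = int(6 * 5 * 30)
        env = np.zeros(nt)
        hemo = sd.synthesize_hemodynamics(env, states, p)
        truth = _make_truth(p, states, hemo, env)
        session = sd.render_session(truth, SpectroscopyConstants.default(), p, i0=2000.0)
        np.testing.assert_allclose(session.channels["reflectance_530_L"], 2000.0, atol=1e-9)

    def test_spectroscopy_inversion_recovers_truth(self, small_session):
        params, session, truth = small_session
        constants = SpectroscopyConstants.default()
        i0 = session.meta["i0"]
        dA = np.stack(
            [
                delta_absorbance(session.channels[f"reflectance_{int(w)}_L"], i0)
                for w in constants.wavelengths
            ]
        )
        hemo = invert_beer_lambert(dA, constants)
        # heart pulsation is the only deviation from the noiseless forward model
        assert np.abs(hemo.dhbt - truth.true_hbt[0]).std() < 2.0
        p2 = sd.GenParams(seed=21)  # heart_amp = 0: exact round trip
        sess2, truth2 = sd.generate_session(p2, duration_s=120.0)
        dA2 = np.stack(
            [
                delta_absorbance(sess2.channels[f"reflectance_{int(w)}_L"], sess2.meta["i0"])
                for w in constants.wavelengths
            ]
        )
        hemo2 = invert_beer_lambert(dA2, constants)
        assert np.abs(hemo2.dhbt - truth2.true_hbt[0]).max() < 1e-6
        assert np.abs(hemo2.dhbo - truth2.true_hbo[0]).max() < 1e-6

    def test_seed_determinism_bit_identical(self):
        p = sd.GenParams(seed=33, stim_times=np.array([15.0, 50.0]))
        s1, t1 = sd.generate_session(p, duration_s=120.0)
        s2, t2 = sd.generate_session(
            sd.GenParams(seed=33, stim_times=np.array([15.0, 50.0])), duration_s=120.0
        )
        np.testing.assert_array_equal(t1.true_hbt, t2.true_hbt)
        for name in s1.channels:
            np.testing.assert_array_equal(s1.channels[name], s2.channels[name])

    def test_tirs_recovers_rendered_diameter(self, small_session):
        from nvc.vessel_diametry import tirs_diameter

        params, session, truth = small_session
        px = session.meta["vessel_pixel_size_um"]
        d = tirs_diameter(session.vessel_frames[0], pixel_size_um=px)
        step = int(round(params.fs_optical / session.meta["vessel_fs"]))
        assert d == pytest.approx(truth.true_diameter_um[0], rel=0.05)

    def test_event_log_matches_stim_times(self, small_session):
        params, session, truth = small_session
        np.testing.assert_allclose(session.stim_onsets(), params.stim_times)


def _make_truth(p, states, hemo, env):
    return sd.GroundTruth(
        params=p,
        state_sequence=states,
        true_kernel=hemo.kernel,
        true_hbt=hemo.hbt,
        true_hbo=hemo.hbo,
        true_hbr=hemo.hbr,
        true_diameter_um=hemo.diameter_um,
        true_band_envelopes=sd.true_band_envelopes(states, p),
        gamma_envelope=env,
        dff_true=np.zeros_like(env),
        neural=sd.synthesize_neural(states, p),
    )


def test_invariant_conservation_on_generated_session(small_session):
    _, _, truth = small_session
    np.testing.assert_array_equal(truth.true_hbt, truth.true_hbo + truth.true_hbr)


def test_genparams_validation():
    with pytest.raises(ParameterError):
        sd.GenParams(vasomotion_sigma=-1.0)
    with pytest.raises(ParameterError):
        sd.GenParams(bilateral_shared_fraction=1.5)
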