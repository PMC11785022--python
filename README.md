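# nvc

Analysis pipeline for widefield hemodynamic imaging of mouse cortex across
arousal states, with a synthetic multimodal-session generator that provides
ground truth for every stage.

The package covers the full chain used in neurovascular-coupling studies:

- **`nvc.synthetic_data`** — generates complete synthetic sessions: a Markov
  chain of 5-s Awake/NREM/REM bins, state-dependent band-limited LFP and EMG
  (atonia in REM), hemodynamics built from the gamma-band power envelope
  convolved with a gamma-variate kernel plus vasomotion, state offsets, and
  stimulus transients with an optional post-stimulus undershoot, a forward
  Beer-Lambert render to per-wavelength reflectance with attenuated
  fluorescence, and vessel cross-section frames with known diameters.
- **`nvc.spectroscopy`** — modified Beer-Lambert inversion of 480/530/630 nm
  reflectance to Δ[HbT]/Δ[HbO]/Δ[HbR] (μM) and hemodynamic-attenuation
  correction of fluorescence.
- **`nvc.vessel_diametry`** — FWHM diametry for surface vessels and
  thresholding-in-Radon-space (TiRS) for penetrating arterioles, with rigid
  frame registration, percent-change traces, and resting variance.
- **`nvc.signal_processing`** — zero-phase band-power envelopes (30 Hz),
  EMG log-power envelope, multitaper spectra/spectrograms (DPSS), magnitude
  coherence, normalized cross-correlation, heart-rate estimation.
- **`nvc.sleep_scoring`** — per-5-s-bin Awake/NREM/REM classification with a
  bagged random forest (OOB-validated) from LFP band powers, EMG, heart rate
  and whisking; segmentation into Alert/Asleep blocks, rest events (≥ 10 s),
  NREM (≥ 30 s) / REM (≥ 60 s) events, and 30 s + 30 s state transitions.
- **`nvc.event_analysis`** — stimulus-triggered averages with baseline
  subtraction and Savitzky-Golay smoothing, through-origin neurovascular
  slope, state-conditioned means and resting variance, bilateral Pearson /
  coherence summaries, and transition pre/post differences.
- **`nvc.hrf`** — hemodynamic response function by ridge-stabilized
  deconvolution on the training half, gamma-variate fitting, and held-out
  prediction R².

## CLI

```bash
# generate a synthetic session (HDF5 + events CSV + ground-truth JSON + vessel TIFF)
nvc generate --config gen.yaml --out session.h5 --seed 1

# extract sleep-scoring features (and score against the ground-truth sidecar)
nvc score session.h5

# run analysis stages and export summaries
nvc analyze session.h5 --stages spectroscopy,scoring,evoked,coherence,hrf --out results/
```

`gen.yaml` may set any generator field plus `duration_s`, e.g.:

```yaml
duration_s: 1800
vasomotion_sigma: 6.4
bilateral_shared_fraction: 0.8
stim_times: [20, 55, 90]
```

## Session layout (HDF5)

```
/raw/reflectance_{530,480,630}_{L,R}, fluorescence_{L,R}   30 Hz optical
/raw/lfp_cortexL, lfp_cortexR, lfp_hipp, emg               neural rate (fs attr)
/raw/whisker, force                                        behavior, 30 Hz
/events/{onset_s,type,duration_s,side}
/vessels/frames                                            cross-section stack
```
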