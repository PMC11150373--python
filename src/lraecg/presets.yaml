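# Synthetic beat morphologies and rhythm specs.
#
# Each beat class is a sum of Gaussian bumps (amplitude mV, center s relative
# to the R peak, width = Gaussian sigma in s).  The four classes mimic the
# discriminative morphology of their clinical counterparts without claiming
# physiological fidelity:
#   N - normal sinus beat: P wave, narrow dominant R, upright T
#   L - left-bundle-branch-block-like: wide notched QRS, discordant T
#   R - right-bundle-branch-block-like: rsR' double peak
#   V - premature-ventricular-like: no P wave, QRS >= 1.5x wider than N
beats:
  N:
    noise_sd: 0.04
    bumps:  # [amplitude_mV, center_s, width_s]
      - [0.15, -0.20, 0.025]   # P
      - [-0.10, -0.030, 0.010] # Q
      - [1.00, 0.000, 0.012]   # R
      - [-0.25, 0.035, 0.012]  # S
      - [0.35, 0.250, 0.060]   # T
  L:
    noise_sd: 0.04
    bumps:
      - [0.12, -0.20, 0.025]   # P
      - [0.85, -0.020, 0.028]  # broad R (first hump)
      - [-0.35, 0.012, 0.010]  # notch
      - [0.70, 0.045, 0.028]   # broad R (second hump)
      - [-0.30, 0.280, 0.070]  # discordant T
  R:
    noise_sd: 0.04
    bumps:
      - [0.12, -0.20, 0.025]   # P
      - [0.45, -0.035, 0.010]  # r
      - [-0.50, 0.000, 0.014]  # s
      - [0.95, 0.045, 0.020]   # R'
      - [-0.25, 0.270, 0.060]  # inverted T
  V:
    noise_sd: 0.04
    bumps:
      - [-0.30, -0.070, 0.022] # deep broad Q
      - [1.10, 0.000, 0.045]   # wide R (>=1.5x N width)
      - [-0.45, 0.090, 0.035]  # broad S
      - [-0.40, 0.300, 0.080]  # discordant T

# Rhythm-strip specs for 2017-style single-lead records.
rhythms:
  N:
    duration_s: 30.0
    fs: 300
    mean_rr_s: 0.8
    rr_jitter: {model: gaussian, sd_s: 0.02}
    beat: N
    noise_sd: 0.03
  AF:
    duration_s: 30.0
    fs: 300
    mean_rr_s: 0.8
    rr_jitter: {model: uniform, low_s: 0.40, high_s: 1.20}
    beat: N
    p_amplitude_scale: 0.0   # absent P waves
    noise_sd: 0.05
  Other:
    duration_s: 30.0
    fs: 300
    mean_rr_s: 1.25          # marked bradycardia with ectopic morphology
    rr_jitter: {model: gaussian, sd_s: 0.08}
    beat: V
    noise_sd: 0.03
  Noisy:
    duration_s: 30.0
    fs: 300
    mean_rr_s: 0.8
    rr_jitter: {model: gaussian, sd_s: 0.02}
    beat: N
    noise_sd: 0.60           # drives empirical SNR below 0 dB
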