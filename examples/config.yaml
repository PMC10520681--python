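# Reference configuration: soft-gel cantilever paced at 0.5 Hz with five
# preload levels.  Values accept unit tags; SI assumed for bare numbers.

beam:
  length: 10 mm        # free (unclamped) length
  width: 10 mm
  thickness: 200 um
  modulus: 12 kPa
  poisson: 0.5
  viscosity: 1 mPa*s   # surrounding medium; raise for an effective value

protocol:
  period: 2 s          # 0.5 Hz pacing
  pulse_width: 5 ms
  hold: 500 ms         # preload hold before release + stimulus
  fps: 240
  n_twitches: 8
  preload_levels: [0.0, 1.6e-5, 3.2e-5, 4.8e-5, 6.4e-5]   # N/m magnetic load

twitch:
  F0: 10 uN            # baseline peak twitch force
  s_FL: 1.0            # force-length gain (inotropy knob)
  t_rise: 30 ms
  t_decay: 150 ms
  eps_ref: 1.0e-3      # strain normalization for s_FL
  noise_sd: 2 um       # measurement noise on tip deflection

render:
  enabled: false       # set true to write silhouette TIFF stacks
  px_per_mm: 20
  shape: [96, 240]
  clamp_px: 24
  noise_sd: 2          # per-pixel grayscale noise (uint8 counts)

tracking:
  px_per_mm: 20
  threshold: otsu
  clamp_px: 24
  fit_window: 1.0
  smooth_window: 7     # frames, Savitzky-Golay

# Optional: analyze and compare two conditions with `cardiobeam all`
conditions:
  - {label: untreated, s_FL: 1.0}
  - {label: inotrope, s_FL: 3.0}
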