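"""Glue between stages: ground truth -> traces -> measurements -> FL.

Two routes from a synthetic experiment to per-level measurements:

- :func:`measurements_from_truth` — invert the (optionally noisy) simulated
  deflection directly; used for fast statistical runs.
- :func:`measurements_from_videos` — render each level as a silhouette
  video, track it, then invert; the full end-to-end path.
"""

from __future__ import annotations

from scipy.signal import savgol_filter

from .analysis import measurement_from_trace
from .beam import DeflectionTrace
from .synth import GroundTruth, force_density_schedule, render_video
from .tracking import TrackingConfig, track

__all__ = ["trace_from_level", "measurements_from_truth",
           "measurements_from_videos"]


def trace_from_level(level, beam, exact: bool = False,
                     smooth_window: int = 7) -> DeflectionTrace:
    """Build a DeflectionTrace from a simulated level.

    ``exact=True`` uses the clean deflection and the exact ODE velocity
    (algebraically exact inversion); otherwise the noisy ``W`` is used with
    Savitzky-Golay differentiation, as for tracked data.
    """
    if exact:
        W, Wdot = level.W_clean, level.Wdot
    else:
        W = level.W
        dt = level.t[1] - level.t[0]
        win = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
        # cubic kernel for the derivative: the quadratic one biases Wdot on
        # the exponential preload-release decay, tilting the FL relation
        Wdot = savgol_filter(W, win, 3, deriv=1, delta=dt)
    return DeflectionTrace(
        t=level.t, W=W, Wdot=Wdot, c=2.0 * W / beam.L0**2, beam=beam,
        provenance="simulated",
        meta={"p_m0": level.p_m0, "stim_times": level.stim_times,
              "level_id": level.level_id})


def measurements_from_truth(truth: GroundTruth, exact: bool = False,
                            smooth_window: int = 7):
    """Invert each level of a synthetic experiment into a TwitchMeasurement."""
    out = []
    for lv in truth.levels:
        trace = trace_from_level(lv, truth.beam, exact=exact,
                                 smooth_window=smooth_window)
        out.append(measurement_from_trace(
            trace, lv.p_m, lv.stim_times, level_id=lv.level_id,
            smooth_window=None if exact else smooth_window,
            label=truth.protocol.label))
    return out


def measurements_from_videos(truth: GroundTruth, tracking_config: TrackingConfig,
                             px_per_mm: float = 20.0,
                             shape: tuple[int, int] = (96, 240),
                             clamp_px: int = 24,
                             pixel_noise_sd: float = 0.0,
                             seed: int = 0,
                             return_traces: bool = False):
    """Render, track and invert every level of a synthetic experiment.

    The reference frame (zero deflection) is the first frame of each level,
    which the protocol guarantees starts at rest.  The magnetic force
    density fed to the inversion is the known protocol schedule, as it
    would be in a calibrated physical experiment.
    """
    measurements, traces = [], []
    for lv in truth.levels:
        frames = render_video(
            lv.W, truth.beam, px_per_mm=px_per_mm, shape=shape,
            clamp_px=clamp_px, noise_sd=pixel_noise_sd,
            seed=seed * 1000 + lv.level_id)
        trace = track(frames, tracking_config, truth.beam,
                      reference_index=0, fps=truth.protocol.fps)
        p_m = force_density_schedule(truth.protocol, lv.p_m0, trace.t)
        m = measurement_from_trace(
            trace, p_m, lv.stim_times, level_id=lv.level_id,
            smooth_window=tracking_config.smooth_window,
            label=truth.protocol.label)
        measurements.append(m)
        trace.meta.update({"p_m0": lv.p_m0, "stim_times": lv.stim_times,
                           "level_id": lv.level_id})
        traces.append(trace)
    return (measurements, traces) if return_traces else measurements
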