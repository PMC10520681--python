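"""Synthetic ground-truth experiments: twitch trains, preload schedules,
forward-simulated deflections and rendered silhouette videos.

Every downstream stage (tracking, force inversion, force-length analysis)
is exercised against data produced here, where the cell-generated force is
known exactly.  The per-cycle protocol mirrors the physical rig: the magnet
steps in and holds the film pre-deflected for ``hold`` seconds, releases,
and an electrical stimulus fires at release, producing a twitch whose peak
force grows with the preload strain reached at the end of the hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beam import BeamSpec, cell_layer_strain, relaxation_time, simulate_deflection
from .errors import RenderError

__all__ = ["TwitchProtocol", "TwitchModel", "LevelRun", "GroundTruth",
           "twitch_waveform", "run_protocol", "force_density_schedule",
           "render_video"]


@dataclass(frozen=True)
class TwitchProtocol:
    """Stimulation and preload schedule.

    ``preload_levels`` are magnetic force densities (N/m) applied during the
    hold of each cycle, or magnet distances (m) when a calibration curve is
    supplied to :func:`run_protocol` with ``levels_are_distances=True``.
    """

    period: float = 2.0          # pacing period (s): 0.5 Hz
    pulse_width: float = 0.005   # stimulus pulse width (s); timing marker only
    hold: float = 0.5            # preload hold before release + stimulus (s)
    preload_levels: tuple = (0.0,)
    fps: float = 240.0
    n_twitches: int = 8
    label: str = ""

    def __post_init__(self) -> None:
        if self.hold >= self.period:
            raise ValueError("preload hold must be shorter than the pacing period")
        if self.fps <= 0 or self.period <= 0 or self.pulse_width <= 0:
            raise ValueError("period, pulse_width and fps must be > 0")
        if self.n_twitches < 1:
            raise ValueError("need at least one twitch per level")
        object.__setattr__(self, "preload_levels", tuple(float(v) for v in self.preload_levels))


@dataclass(frozen=True)
class TwitchModel:
    """Twitch-force waveform parameters with preload-dependent peak.

    The waveform is a double exponential normalized to unit peak; the peak
    force is ``F0 * (1 + s_FL * eps_pre / eps_ref)``, so ``s_FL`` is the
    dimensionless force-length gain (inotropy knob) and ``eps_ref`` the
    strain normalization that keeps it unitless.
    """

    F0: float = 2e-5
    s_FL: float = 1.0
    t_rise: float = 0.03
    t_decay: float = 0.15
    eps_ref: float = 1e-3
    noise_sd: float = 2e-6   # additive Gaussian noise on W (m); ~40 dB SNR
                             # against typical sub-millimetre deflections

    def __post_init__(self) -> None:
        if self.F0 <= 0:
            raise ValueError("F0 must be > 0")
        if self.s_FL < 0:
            raise ValueError("s_FL must be >= 0")
        if not (0 < self.t_rise < self.t_decay):
            raise ValueError("need 0 < t_rise < t_decay")
        if self.eps_ref <= 0:
            raise ValueError("eps_ref must be > 0")

    @property
    def peak_time(self) -> float:
        """Time of the waveform peak after stimulus onset."""
        tr, td = self.t_rise, self.t_decay
        return tr * td / (td - tr) * math.log(td / tr)

    def peak_force(self, eps_pre: float) -> float:
        return self.F0 * (1.0 + self.s_FL * eps_pre / self.eps_ref)


def twitch_waveform(model: TwitchModel, eps_pre: float, t):
    """Twitch force at time ``t`` (s) since stimulus onset.

    Zero at onset, single-peaked, decays towards zero well before a 0.5 Hz
    pacing period; peak value ``F0 (1 + s_FL eps_pre / eps_ref)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (time since stimulus)")
    tr, td = model.t_rise, model.t_decay
    shape = np.exp(-t / td) - np.exp(-t / tr)
    tp = model.peak_time
    shape /= math.exp(-tp / td) - math.exp(-tp / tr)
    return model.peak_force(eps_pre) * shape


def force_density_schedule(protocol: TwitchProtocol, p_m0: float, t):
    """Magnetic force density at times ``t`` for one preload level.

    ``p_m0`` during the first ``hold`` seconds of each pacing cycle, zero
    afterwards (instantaneous release).
    """
    t = np.asarray(t, dtype=float)
    phase = np.mod(t, protocol.period)
    return np.where(phase < protocol.hold, p_m0, 0.0)


@dataclass
class LevelRun:
    """Ground truth for one preload level."""

    level_id: int
    p_m0: float
    eps_pre: float              # mean end-of-hold preload strain over cycles
    eps_pre_cycles: np.ndarray  # per-cycle end-of-hold strain
    t: np.ndarray               # frame times (s), starting at 0
    W: np.ndarray               # noisy tip deflection (m)
    W_clean: np.ndarray
    Wdot: np.ndarray            # exact ODE velocity at frame times (m/s)
    F_cell: np.ndarray          # true cell force at frame times (N)
    p_m: np.ndarray             # applied force density at frame times (N/m)
    stim_times: np.ndarray      # stimulus onsets (s)
    peaks_true: np.ndarray      # per-twitch true peak active force (N)


@dataclass
class GroundTruth:
    """Full synthetic experiment: one :class:`LevelRun` per preload level."""

    levels: list
    protocol: TwitchProtocol
    model: TwitchModel
    beam: BeamSpec
    seed: int
    meta: dict = field(default_factory=dict)


def run_protocol(protocol: TwitchProtocol, model: TwitchModel, beam: BeamSpec,
                 calibration=None, seed: int = 0,
                 levels_are_distances: bool = False) -> GroundTruth:
    """Simulate the full preload/stimulation protocol.

    For each preload level the magnet load steps on for the hold, steps off
    at stimulus onset, and the twitch force is the waveform evaluated with
    the preload strain reached at the end of the hold.  The deflection is
    forward-integrated through the beam ODE on a sub-frame grid (at least 20
    steps per relaxation time) and sampled at ``protocol.fps``; Gaussian
    measurement noise (``model.noise_sd``) is added to the sampled ``W``.

    Regeneration from the same parameters and seed is bit-identical.
    """
    if levels_are_distances and calibration is None:
        raise ValueError("distance levels require a calibration curve")
    if protocol.fps < 2.0 / model.t_rise:
        raise ValueError(
            f"fps = {protocol.fps} undersamples the twitch rise time {model.t_rise}"
        )
    tau = relaxation_time(beam)
    dt_frame = 1.0 / protocol.fps
    m = max(1, math.ceil(dt_frame / (tau / 20.0)))
    dt = dt_frame / m
    n_cycle = round(protocol.period / dt)
    n_hold = round(protocol.hold / dt)
    rng = np.random.default_rng(seed)

    levels = []
    for lvl, level in enumerate(protocol.preload_levels):
        p_m0 = float(calibration(level)) if levels_are_distances else float(level)
        W0 = 0.0
        W_parts, F_parts, p_parts, Wdot_parts = [], [], [], []
        eps_cycles = np.empty(protocol.n_twitches)
        for cyc in range(protocol.n_twitches):
            # hold phase: passive film under magnetic load
            hold_tr = simulate_deflection(
                np.zeros(n_hold + 1), np.full(n_hold + 1, p_m0), beam, W0=W0, dt=dt)
            eps_cycles[cyc] = cell_layer_strain(hold_tr.W[-1], beam)[1]
            # release + stimulus: magnet off, twitch force on
            n_rest = n_cycle - n_hold
            t_rest = np.arange(n_rest + 1) * dt
            F_rest = twitch_waveform(model, eps_cycles[cyc], t_rest)
            rest_tr = simulate_deflection(
                F_rest, np.zeros(n_rest + 1), beam, W0=hold_tr.W[-1], dt=dt)
            W0 = rest_tr.W[-1]
            W_parts.append(np.concatenate([hold_tr.W[:-1], rest_tr.W[:-1]]))
            Wdot_parts.append(np.concatenate([hold_tr.Wdot[:-1], rest_tr.Wdot[:-1]]))
            F_parts.append(np.concatenate([np.zeros(n_hold), F_rest[:-1]]))
            p_parts.append(np.concatenate([np.full(n_hold, p_m0), np.zeros(n_rest)]))
        W_fine = np.concatenate(W_parts)
        t_fine = np.arange(len(W_fine)) * dt
        sel = slice(0, None, m)
        t_fr = t_fine[sel]
        W_clean = W_fine[sel]
        noise = rng.normal(0.0, model.noise_sd, size=len(W_clean)) if model.noise_sd > 0 \
            else np.zeros(len(W_clean))
        levels.append(LevelRun(
            level_id=lvl,
            p_m0=p_m0,
            eps_pre=float(np.mean(eps_cycles)),
            eps_pre_cycles=eps_cycles,
            t=t_fr,
            W=W_clean + noise,
            W_clean=W_clean,
            Wdot=np.concatenate(Wdot_parts)[sel],
            F_cell=np.concatenate(F_parts)[sel],
            p_m=np.concatenate(p_parts)[sel],
            stim_times=np.arange(protocol.n_twitches) * protocol.period + protocol.hold,
            peaks_true=model.peak_force(eps_cycles),
        ))
    return GroundTruth(levels=levels, protocol=protocol, model=model,
                       beam=beam, seed=seed,
                       meta={"eps_ref": model.eps_ref, "dt_sim": dt})


def render_video(W, beam: BeamSpec, px_per_mm: float = 20.0,
                 shape: tuple[int, int] = (96, 240), clamp_px: int = 24,
                 y0_row: float | None = None, fg: int = 230, bg: int = 20,
                 noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Render a tip-deflection series as a grayscale side-view silhouette.

    Each frame shows a beam of thickness ``h`` bent along
    ``w(x) = W x^2 / L0^2``, preceded by a static clamped segment occupying
    the first ``clamp_px`` columns.  Edges are anti-aliased by exact
    pixel-coverage integration; optional per-pixel Gaussian intensity noise
    is seeded.  Returns a ``(n_frames, H, W)`` uint8 stack.
    """
    W = np.atleast_1d(np.asarray(W, dtype=float))
    H, Wd = shape
    scale = px_per_mm * 1000.0  # px per metre
    beam_px = beam.L0 * scale
    if y0_row is None:
        y0_row = H / 3.0
    half_h = beam.h * scale / 2.0
    n_free = int(round(beam_px))
    if clamp_px + n_free > Wd:
        raise RenderError(
            f"beam needs {clamp_px + n_free} columns but frame is {Wd} wide")
    # column centre positions along the free beam, metres from the clamp edge
    x = (np.arange(n_free) + 0.5) / scale
    x_frac2 = (x / beam.L0) ** 2
    yc_max = y0_row + np.max(W, initial=0.0) * scale
    yc_min = y0_row + np.min(W, initial=0.0) * scale
    if yc_min - half_h < 0 or yc_max + half_h > H:
        raise RenderError("beam leaves the frame at the requested deflections")

    rng = np.random.default_rng(seed)
    rows = np.arange(H, dtype=float)[:, None]
    frames = np.empty((len(W), H, Wd), dtype=np.uint8)
    yc_cols = np.empty(clamp_px + n_free)
    for i, w_tip in enumerate(W):
        yc_cols[:clamp_px] = y0_row
        yc_cols[clamp_px:] = y0_row + w_tip * scale * x_frac2
        top = yc_cols[None, :] - half_h
        bot = yc_cols[None, :] + half_h
        cover = np.clip(np.minimum(bot, rows + 1.0) - np.maximum(top, rows), 0.0, 1.0)
        img = np.full((H, Wd), float(bg))
        img[:, :clamp_px + n_free] += cover * (fg - bg)
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return frames
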