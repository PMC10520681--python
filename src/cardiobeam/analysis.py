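"""Force-length contractility readouts.

Per preload level, invert a deflection trace into a cell-force series,
extract per-twitch peak active forces, normalize dynamic stress to the
no-preload baseline peak, assemble stress-strain loops, and fit the
force-length (FL) relation: percentage increase in average peak active
force versus relative preload.  The FL slope is the contractility index;
conditions are compared by bootstrap resampling of twitches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .beam import BeamSpec, DeflectionTrace, cell_force, cell_layer_strain
from .errors import AnalysisError

__all__ = ["TwitchMeasurement", "FLRelation", "ComparisonReport", "Loop",
           "recover_force", "active_force", "normalize_stress",
           "measurement_from_trace", "build_loops", "fl_relation",
           "compare_conditions"]

#: peak-search window after stimulus onset: skip the release transient,
#: search up to this long after the stimulus
PEAK_SEARCH = (0.02, 1.0)
#: reference window (s, relative to stimulus onset) for the active-force
#: baseline; ends just before the release transient enters the smoothing
#: kernel
REF_WINDOW = (-0.05, -0.02)


@dataclass
class TwitchMeasurement:
    """Per-preload-level force measurement."""

    level_id: int
    eps_pre: float
    t: np.ndarray
    eps: np.ndarray
    F_cell: np.ndarray
    peaks: np.ndarray            # per-twitch peak active force (N)
    peak_passive: float          # force at the reference window (N)
    sigma_hat: np.ndarray | None = None
    label: str = ""

    @property
    def peak_active(self) -> float:
        return float(np.mean(self.peaks))


@dataclass
class FLRelation:
    """Fitted force-length relation for one condition.

    ``points`` holds (relative preload, % increase in average peak active
    force); the zero-preload point maps to 0% by construction.  ``slope``
    is the contractility index; ``boot_slopes`` the seeded bootstrap
    distribution used for its CI.
    """

    points: np.ndarray           # (n_levels, 2)
    eps_pre: np.ndarray          # raw preload strains, same order as points
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    slope_se: float
    boot_slopes: np.ndarray
    peaks_by_level: list         # per-level per-twitch peak arrays
    r2: float
    label: str = ""
    seed: int = 0


@dataclass
class ComparisonReport:
    """Bootstrap comparison of two FL relations (b minus a)."""

    dslope: float
    ci: tuple[float, float]
    p_value: float
    verdict: str                 # "steeper" or "not distinguishable"
    label_a: str = ""
    label_b: str = ""


@dataclass
class Loop:
    """Phase-averaged normalized stress-strain loop for one preload level."""

    level_id: int
    eps_pre: float
    eps: np.ndarray
    sigma_hat: np.ndarray
    area: float                  # signed shoelace area (work surrogate)


def recover_force(trace: DeflectionTrace, p_m, beam: BeamSpec | None = None,
                  smooth_window: int | None = None) -> np.ndarray:
    """Invert a deflection trace into a cell-force series.

    Uses the trace's own ``Wdot``.  When ``smooth_window`` is given, ``W``
    is Savitzky-Golay smoothed (order 2) before the elastic term is formed,
    which helps on noisy tracked data; ``Wdot`` is left as provided.
    """
    beam = beam or trace.beam
    W = trace.W
    if smooth_window and smooth_window >= 5 and len(W) > smooth_window:
        W = savgol_filter(W, smooth_window, 2)
    return cell_force(W, trace.Wdot, p_m, beam)


def active_force(t: np.ndarray, F: np.ndarray, stim_times,
                 search: tuple[float, float] = PEAK_SEARCH,
                 ref_window: tuple[float, float] = REF_WINDOW):
    """Per-twitch peak active forces from a force series.

    Active force is the series minus its value at stimulus onset (estimated
    as the mean over ``ref_window`` before the stimulus, which avoids the
    preload-release kink that differentiation smears across a few frames).
    The peak is the maximum over ``(stim + search[0], stim + search[1])``.
    Only twitch windows fully inside the trace are used.

    Returns ``(peaks, mean, sd, refs)``.
    """
    t = np.asarray(t, dtype=float)
    F = np.asarray(F, dtype=float)
    peaks, refs = [], []
    for ts in np.atleast_1d(np.asarray(stim_times, dtype=float)):
        lo, hi = ts + search[0], ts + search[1]
        r0, r1 = ts + ref_window[0], ts + ref_window[1]
        if r0 < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            continue
        ref_sel = (t >= r0) & (t <= r1)
        ref = float(np.mean(F[ref_sel])) if ref_sel.any() else float(
            F[np.searchsorted(t, ts)])
        win = (t >= lo) & (t <= hi)
        if not win.any():
            continue
        peaks.append(float(np.max(F[win]) - ref))
        refs.append(ref)
    if not peaks:
        raise AnalysisError("no twitch window fully inside the trace")
    peaks = np.array(peaks)
    return peaks, float(np.mean(peaks)), float(np.std(peaks, ddof=0)), np.array(refs)


def normalize_stress(F_cell, baseline_peak: float, beam: BeamSpec | None = None):
    """Normalize a force series to the no-preload baseline peak.

    The cell-layer cross-section cancels in the ratio, so normalized stress
    equals normalized force; the baseline run's own maximum active force
    maps to exactly 1.
    """
    if not np.isfinite(baseline_peak) or baseline_peak <= 0:
        raise AnalysisError(f"baseline peak must be > 0, got {baseline_peak!r}")
    return np.asarray(F_cell, dtype=float) / baseline_peak


def measurement_from_trace(trace: DeflectionTrace, p_m, stim_times,
                           level_id: int = 0, eps_pre: float | None = None,
                           smooth_window: int | None = None,
                           label: str = "",
                           search: tuple[float, float] = PEAK_SEARCH,
                           ref_window: tuple[float, float] = REF_WINDOW) -> TwitchMeasurement:
    """Invert one per-level trace and extract its twitch peaks."""
    F = recover_force(trace, p_m, smooth_window=smooth_window)
    peaks, _, _, refs = active_force(trace.t, F, stim_times,
                                     search=search, ref_window=ref_window)
    _, eps = cell_layer_strain(trace.W, trace.beam)
    if eps_pre is None:
        # strain just before the first usable stimulus
        ts = float(np.atleast_1d(stim_times)[0])
        sel = (trace.t >= ts - 0.03) & (trace.t < ts)
        eps_pre = float(np.mean(eps[sel])) if sel.any() else 0.0
    return TwitchMeasurement(
        level_id=level_id, eps_pre=float(eps_pre), t=trace.t, eps=eps,
        F_cell=F, peaks=peaks, peak_passive=float(np.mean(refs)), label=label)


def build_loops(measurements, period: float, baseline_peak: float | None = None):
    """Phase-averaged normalized stress-strain loops, one per preload level.

    Each loop is the closed ``(eps(t), sigma_hat(t))`` trajectory over one
    pacing cycle (preload hold plus twitch), phase-averaged over the
    complete cycles in the trace.  The signed shoelace area is a work
    surrogate.
    """
    measurements = list(measurements)
    if not measurements:
        raise AnalysisError("no measurements")
    if baseline_peak is None:
        base = min(measurements, key=lambda m: m.eps_pre)
        baseline_peak = base.peak_active
    loops = []
    for m in measurements:
        dt = m.t[1] - m.t[0]
        n_cycle = int(round(period / dt))
        n_full = len(m.t) // n_cycle
        if n_full < 1:
            raise AnalysisError("trace shorter than one pacing cycle")
        sig = normalize_stress(m.F_cell, baseline_peak)
        m.sigma_hat = sig
        eps_c = m.eps[: n_full * n_cycle].reshape(n_full, n_cycle).mean(axis=0)
        sig_c = sig[: n_full * n_cycle].reshape(n_full, n_cycle).mean(axis=0)
        # close the polygon for the area
        x = np.append(eps_c, eps_c[0])
        y = np.append(sig_c, sig_c[0])
        area = 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        loops.append(Loop(level_id=m.level_id, eps_pre=m.eps_pre,
                          eps=eps_c, sigma_hat=sig_c, area=area))
    return loops


def _wls_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line; returns (slope, intercept)."""
    sw = np.sum(w)
    xb = np.sum(w * x) / sw
    yb = np.sum(w * y) / sw
    den = np.sum(w * (x - xb) ** 2)
    if den <= 0:
        raise AnalysisError("degenerate preload grid: no spread in x")
    slope = np.sum(w * (x - xb) * (y - yb)) / den
    return slope, yb - slope * xb


def fl_relation(measurements, seed: int = 0, n_boot: int = 1000,
                label: str = "") -> FLRelation:
    """Fit the force-length relation across preload levels.

    Points are (relative preload, percentage increase in average peak
    active force over the zero-preload baseline), with relative preload =
    preload strain normalized to the largest tested level.  A weighted
    least-squares line (weights from per-level twitch scatter, floored so
    noiseless data degrades to an ordinary fit) gives the contractility
    index; a seeded bootstrap over twitches gives its CI.
    """
    measurements = sorted(measurements, key=lambda m: m.eps_pre)
    if len(measurements) < 3:
        raise AnalysisError("need at least 3 preload levels (including zero)")
    eps_pre = np.array([m.eps_pre for m in measurements])
    peaks = [np.asarray(m.peaks, dtype=float) for m in measurements]
    P = np.array([np.mean(p) for p in peaks])
    if P[0] <= 0:
        raise AnalysisError("baseline (no preload) peak active force must be > 0")
    eps_max = eps_pre.max()
    if eps_max <= 0:
        raise AnalysisError("all preload strains are zero")
    x = eps_pre / eps_max
    y = 100.0 * (P - P[0]) / P[0]

    se2 = np.array([np.var(p, ddof=1) / len(p) if len(p) > 1 else 0.0
                    for p in peaks])
    scale = (100.0 / P[0]) ** 2
    se2_pct = se2 * scale
    pos = se2_pct[se2_pct > 0]
    floor = max(float(np.median(pos)) if len(pos) else 0.0, 1e-12)
    w = 1.0 / (se2_pct + floor)
    slope, intercept = _wls_slope(x, y, w)
    pred = slope * x + intercept
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        Pb = np.array([np.mean(rng.choice(p, size=len(p), replace=True))
                       for p in peaks])
        if Pb[0] <= 0:
            boot[i] = np.nan
            continue
        yb = 100.0 * (Pb - Pb[0]) / Pb[0]
        boot[i] = _wls_slope(x, yb, w)[0]
    boot = boot[np.isfinite(boot)]
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return FLRelation(
        points=np.column_stack([x, y]), eps_pre=eps_pre,
        slope=float(slope), intercept=float(intercept),
        slope_ci=ci, slope_se=float(np.std(boot, ddof=1)),
        boot_slopes=boot, peaks_by_level=peaks, r2=float(r2),
        label=label, seed=seed)


def compare_conditions(fl_a: FLRelation, fl_b: FLRelation, seed: int = 0,
                       n_boot: int = 2000, alpha: float = 0.05) -> ComparisonReport:
    """Compare two FL relations: is condition b steeper than condition a?

    Bootstrap (resampling twitches within levels) distribution of
    ``slope_b - slope_a``; the verdict is "steeper" when the two-sided CI
    excludes zero and the difference is positive.  Mismatched preload grids
    trigger a warning and the comparison is restricted to common relative
    preload levels.
    """
    xa = fl_a.points[:, 0]
    xb = fl_b.points[:, 0]
    peaks_a, peaks_b = fl_a.peaks_by_level, fl_b.peaks_by_level
    grid_tol = 0.05  # relative-preload units; grids are noisy estimates
    if len(xa) == len(xb) and np.all(np.abs(xa - xb) <= grid_tol):
        x_common = 0.5 * (xa + xb)  # symmetric in the two arguments
    else:
        warnings.warn("mismatched preload grids; using common levels", stacklevel=2)
        ia, ib = [], []
        for i, xv in enumerate(xa):
            j = int(np.argmin(np.abs(xb - xv)))
            if abs(xb[j] - xv) <= grid_tol:
                ia.append(i)
                ib.append(j)
        if len(ia) < 3:
            raise AnalysisError("fewer than 3 common preload levels")
        peaks_a = [peaks_a[i] for i in ia]
        peaks_b = [peaks_b[j] for j in ib]
        x_common = 0.5 * (xa[ia] + xb[ib])

    rng = np.random.default_rng(seed)

    def boot_slopes(x, peaks, n):
        out = np.empty(n)
        w = np.ones_like(x)
        for i in range(n):
            P = np.array([np.mean(rng.choice(p, size=len(p), replace=True))
                          for p in peaks])
            out[i] = np.nan if P[0] <= 0 else _wls_slope(
                x, 100.0 * (P - P[0]) / P[0], w)[0]
        return out[np.isfinite(out)]

    def point_slope(x, peaks):
        P = np.array([np.mean(p) for p in peaks])
        return _wls_slope(x, 100.0 * (P - P[0]) / P[0], np.ones_like(x))[0]

    ba = boot_slopes(x_common, peaks_a, n_boot)
    bb = boot_slopes(x_common, peaks_b, n_boot)
    n = min(len(ba), len(bb))
    diff = bb[:n] - ba[:n]
    dslope = float(point_slope(x_common, peaks_b) - point_slope(x_common, peaks_a))
    ci = (float(np.percentile(diff, 100 * alpha / 2)),
          float(np.percentile(diff, 100 * (1 - alpha / 2))))
    p_lo = (np.sum(diff <= 0) + 1) / (n + 1)
    p_hi = (np.sum(diff >= 0) + 1) / (n + 1)
    p = float(min(1.0, 2.0 * min(p_lo, p_hi)))
    verdict = "steeper" if (dslope > 0 and ci[0] > 0) else "not distinguishable"
    return ComparisonReport(dslope=dslope, ci=ci, p_value=p, verdict=verdict,
                            label_a=fl_a.label, label_b=fl_b.label)
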