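"""Side-view silhouette tracking: binarize, midline, quadratic fit.

Frames are binarized (automatic inter-class-variance threshold by default),
the largest connected component touching the clamp region is kept, and a
midline point is extracted per occupied column.  A second-order polynomial
fit per frame provides the curvature (``2 a2``) and the tip position; tip
deflection ``W`` is reported relative to a reference frame, downward
positive (image row 0 is the top row).  Tip velocity is obtained by
smoothed polynomial (Savitzky-Golay) differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu

from .beam import BeamSpec, DeflectionTrace
from .errors import FitError, InsufficientExtentError, TrackingLostError

__all__ = ["TrackingConfig", "FrameFit", "binarize", "extract_midline",
           "fit_parabola", "track"]


@dataclass(frozen=True)
class TrackingConfig:
    """Tracking parameters.

    ``px_per_mm`` must be supplied by the user (pixel scale is never
    inferred from the video).  ``clamp_px`` columns at the left edge are
    treated as the fixed clamp and excluded from the fit; the x origin sits
    at the clamp edge.  ``fit_window`` is the fraction of the detected beam
    (from the clamp) used in the quadratic fit.
    """

    px_per_mm: float
    threshold: str | float = "otsu"
    clamp_px: int = 0
    fit_window: float = 1.0
    smooth_window: int = 7
    subpixel: bool = True
    max_lost_fraction: float = 0.05
    residual_gate_px: float = 1.0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if not (0.0 < self.fit_window <= 1.0):
            raise ValueError("fit_window must be in (0, 1]")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 3")

    @property
    def m_per_px(self) -> float:
        return 1e-3 / self.px_per_mm


@dataclass
class FrameFit:
    """Quadratic fit of one frame's midline, in physical units (metres)."""

    coeffs: tuple[float, float, float]   # (a2, a1, a0) of w(x) = a2 x^2 + a1 x + a0
    residual_rms: float
    tip_x: float
    tip_y: float
    curvature: float                     # 2 * a2
    n_points: int
    ok: bool = True


def binarize(frame: np.ndarray, clamp_px: int | None = None,
             threshold: str | float = "otsu", keep_largest: bool = True) -> np.ndarray:
    """Threshold a single-channel frame into a boolean foreground mask.

    With ``keep_largest`` the largest connected component is retained —
    restricted to components intersecting the first ``clamp_px`` columns
    when a clamp region is given, so detached debris cannot win.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("binarize expects a single-channel 2D frame")
    if threshold == "otsu":
        if np.ptp(frame) == 0:
            raise TrackingLostError("flat frame: no silhouette to threshold")
        thr = threshold_otsu(frame)
    else:
        thr = float(threshold)
    mask = frame > thr
    if not mask.any():
        raise TrackingLostError("empty mask after thresholding")
    if not keep_largest:
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        if clamp_px and clamp_px > 0:
            touching = np.unique(labels[:, :clamp_px])
            touching = touching[touching > 0]
            if len(touching) == 0:
                raise TrackingLostError("no component intersects the clamp region")
            candidates = touching
        else:
            candidates = np.arange(1, n + 1)
        sizes = ndimage.sum_labels(mask, labels, candidates)
        mask = labels == candidates[int(np.argmax(sizes))]
    return mask


def extract_midline(mask: np.ndarray, clamp_px: int = 0,
                    frame: np.ndarray | None = None) -> np.ndarray:
    """Midline points ``(x_px, y_px)`` of the beam silhouette.

    One point per occupied column beyond the clamp region, at the midpoint
    between the upper and lower beam edges.  Columns whose occupancy is not
    vertically contiguous (holes) are skipped.  When the grayscale ``frame``
    is supplied the midline is refined to sub-pixel precision with an
    intensity-weighted centroid across the silhouette's vertical extent.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InsufficientExtentError("empty mask")
    H, Wd = mask.shape
    cols = np.arange(clamp_px, Wd)
    sub = mask[:, clamp_px:]
    counts = sub.sum(axis=0)
    occupied = counts > 0
    top = np.argmax(sub, axis=0)
    bot = H - 1 - np.argmax(sub[::-1, :], axis=0)
    contiguous = occupied & (bot - top + 1 == counts)
    keep = np.flatnonzero(contiguous)
    if len(keep) < 10:
        raise InsufficientExtentError(
            f"only {len(keep)} usable columns (need >= 10)")
    x = cols[keep].astype(float)
    y = (top[keep] + bot[keep]) / 2.0

    if frame is not None:
        frame = np.asarray(frame, dtype=float)
        y_ref = np.empty_like(y)
        for i, k in enumerate(keep):
            r0 = max(top[k] - 1, 0)
            r1 = min(bot[k] + 2, H)
            col = frame[r0:r1, clamp_px + k]
            wgt = col - col.min()
            s = wgt.sum()
            y_ref[i] = (np.arange(r0, r1) @ wgt) / s if s > 0 else y[i]
        y = y_ref
    return np.column_stack([x, y])


def fit_parabola(points: np.ndarray, config: TrackingConfig) -> FrameFit:
    """Least-squares quadratic fit of midline points, in physical units.

    ``x`` is measured from the clamp edge, ``y`` downward positive.  The tip
    is the fit evaluated at the furthest detected column (not extrapolated
    to the nominal free length).  Curvature is ``2 a2`` under the
    small-slope convention.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 10:
        raise InsufficientExtentError("need >= 10 (x, y) midline points")
    s = config.m_per_px
    x = (points[:, 0] - config.clamp_px) * s
    y = points[:, 1] * s
    if config.fit_window < 1.0:
        x_max_all = x.max()
        sel = x <= config.fit_window * x_max_all
        if sel.sum() >= 10:
            x_fit, y_fit = x[sel], y[sel]
        else:
            x_fit, y_fit = x, y
    else:
        x_fit, y_fit = x, y
    if np.ptp(x_fit) <= 0:
        raise FitError("collinear x: cannot fit a quadratic")
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            coeffs = np.polyfit(x_fit, y_fit, 2)
        except np.exceptions.RankWarning as exc:  # pragma: no cover - defensive
            raise FitError("ill-conditioned quadratic fit") from exc
    a2, a1, a0 = coeffs
    resid = y_fit - np.polyval(coeffs, x_fit)
    rms = float(np.sqrt(np.mean(resid**2)))
    tip_x = float(x.max())
    tip_y = float(np.polyval(coeffs, tip_x))
    ok = rms <= config.residual_gate_px * s
    return FrameFit(coeffs=(float(a2), float(a1), float(a0)), residual_rms=rms,
                    tip_x=tip_x, tip_y=tip_y, curvature=float(2.0 * a2),
                    n_points=len(x_fit), ok=ok)


def track(frames, config: TrackingConfig, beam: BeamSpec,
          reference_index: int = 0, fps: float = 240.0) -> DeflectionTrace:
    """Track a frame stack into a :class:`~cardiobeam.beam.DeflectionTrace`.

    ``W`` per frame is the fitted tip y minus the reference frame's tip y
    (downward positive); curvature comes from the per-frame quadratic;
    ``Wdot`` from Savitzky-Golay differentiation of the (lightly smoothed)
    ``W`` series.  Per-frame quality flags and the small-angle diagnostic
    (``alpha = W / L`` vs ``W`` linearity) land in ``trace.meta``.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("need a (n_frames, H, W) stack with >= 2 frames")
    n = len(frames)
    if not (0 <= reference_index < n):
        raise ValueError("reference_index out of range")

    tip_y = np.full(n, np.nan)
    tip_x = np.full(n, np.nan)
    curv = np.full(n, np.nan)
    resid = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    lost: list[int] = []
    for i, fr in enumerate(frames):
        try:
            mask = binarize(fr, clamp_px=config.clamp_px, threshold=config.threshold)
            pts = extract_midline(mask, clamp_px=config.clamp_px,
                                  frame=fr if config.subpixel else None)
            fit = fit_parabola(pts, config)
        except (TrackingLostError, InsufficientExtentError, FitError):
            lost.append(i)
            continue
        tip_y[i], tip_x[i] = fit.tip_y, fit.tip_x
        curv[i] = fit.curvature
        resid[i] = fit.residual_rms
        ok[i] = fit.ok
    if len(lost) > config.max_lost_fraction * n:
        raise TrackingLostError(
            f"tracking lost on {len(lost)}/{n} frames (indices {lost[:20]}...)")
    if np.isnan(tip_y[reference_index]):
        raise TrackingLostError("tracking lost on the reference frame")
    if lost:  # interpolate isolated losses so the timebase stays uniform
        good = np.flatnonzero(~np.isnan(tip_y))
        for arr in (tip_y, tip_x, curv, resid):
            arr[lost] = np.interp(lost, good, arr[good])

    W = tip_y - tip_y[reference_index]
    dt = 1.0 / fps
    win = min(config.smooth_window, n if n % 2 == 1 else n - 1)
    if win >= 5:
        W_smooth = savgol_filter(W, win, 2)
        # cubic kernel for the derivative: unbiased to third order, which
        # matters on the exponential relaxation right after preload release
        Wdot = savgol_filter(W, win, 3, deriv=1, delta=dt)
    else:
        W_smooth = W
        Wdot = np.gradient(W, dt)

    # small-angle diagnostic: alpha = W / L should be linear in W
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = W / tip_x
    finite = np.isfinite(alpha)
    if finite.sum() >= 3 and np.ptp(W[finite]) > 0:
        coef = np.polyfit(W[finite], alpha[finite], 1)
        pred = np.polyval(coef, W[finite])
        ss_res = np.sum((alpha[finite] - pred) ** 2)
        ss_tot = np.sum((alpha[finite] - np.mean(alpha[finite])) ** 2)
        alpha_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        alpha_r2 = float("nan")

    t = np.arange(n) * dt
    return DeflectionTrace(
        t=t, W=W, Wdot=Wdot, c=curv, beam=beam, provenance="tracked",
        meta={
            "W_smooth": W_smooth, "tip_x": tip_x, "residual_rms": resid,
            "quality_ok": ok, "lost_frames": lost,
            "alpha": alpha, "alpha_r2": alpha_r2,
            "reference_index": reference_index, "fps": fps,
        },
    )
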