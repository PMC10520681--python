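"""Semi-analytic model of stacked block-magnet actuation.

The distributed magnetic load on the nanoparticle-laden film is controlled
by moving a stack of cuboid permanent magnets towards the film.  We use the
standard closed-form axial field of a rectangular block magnet; a stack of
``n`` identical magnets magnetized along the axis telescopes into a single
block of ``n``-fold thickness.  The induced body-force density on a
superparamagnetic film scales as ``B * dB/dd`` with a single calibratable
gain, since the film's magnetization per unit length is not known a priori.

Empirical calibration (cell-free deflection vs. magnet distance) is the
authoritative route in practice and is implemented by
:func:`build_calibration`; the field model exists to generate realistic
synthetic calibrations and to check far-field physics (dipole ``d^-3``
field decay, ``d^-7`` force decay).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .beam import BeamSpec, magnetic_density_from_static_deflection
from .errors import CalibrationError

__all__ = ["MagnetStack", "CalibrationCurve", "axial_field",
           "force_density_model", "far_field_slope", "build_calibration"]


@dataclass(frozen=True)
class MagnetStack:
    """A stack of identical cuboid magnets magnetized along the stack axis.

    ``dims = (edge_x, edge_y, thickness)`` of one magnet in metres; the
    defaults follow a 7 x (10 mm x 10 mm x 5 mm) stack with ~1.2 T
    surface flux scale.
    """

    n: int = 7
    dims: tuple[float, float, float] = (0.010, 0.010, 0.005)
    remanence: float = 1.2

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("MagnetStack.n must be >= 1")
        if any(d <= 0 for d in self.dims) or len(self.dims) != 3:
            raise ValueError("MagnetStack.dims must be three positive lengths")
        if self.remanence <= 0:
            raise ValueError("MagnetStack.remanence must be > 0")

    @property
    def total_thickness(self) -> float:
        return self.n * self.dims[2]

    @property
    def max_edge(self) -> float:
        return max(self.dims)

    @property
    def max_extent(self) -> float:
        """Largest dimension of the whole stack (edge or total thickness)."""
        return max(self.dims[0], self.dims[1], self.total_thickness)


def axial_field(stack: MagnetStack, d):
    """Axial flux density (T) at distance ``d`` from the stack's near face.

    Closed form for a cuboid magnet (half-edges ``a``, ``b``, thickness
    ``t``)::

        B(d) = Br/pi * [atan(ab / (d sqrt(a^2+b^2+d^2)))
                        - atan(ab / ((d+t) sqrt(a^2+b^2+(d+t)^2)))]

    Strictly decreasing in ``d`` with a dipole ``d^-3`` far field.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("axial_field requires d > 0 (measured from the near face)")
    a = stack.dims[0] / 2.0
    b = stack.dims[1] / 2.0
    t = stack.total_thickness
    ab = a * b
    s2 = a**2 + b**2

    def term(z):
        return np.arctan(ab / (z * np.sqrt(s2 + z**2)))

    return stack.remanence / np.pi * (term(d) - term(d + t))


def _axial_field_gradient(stack: MagnetStack, d):
    """Analytic dB/dd of :func:`axial_field` (negative for d > 0)."""
    d = np.asarray(d, dtype=float)
    a = stack.dims[0] / 2.0
    b = stack.dims[1] / 2.0
    t = stack.total_thickness
    ab = a * b
    s2 = a**2 + b**2

    def u(z):
        return ab / (z * np.sqrt(s2 + z**2))

    def uprime(z):
        return -ab * (s2 + 2.0 * z**2) / (z**2 * (s2 + z**2) ** 1.5)

    def dterm(z):
        return uprime(z) / (1.0 + u(z) ** 2)

    return stack.remanence / np.pi * (dterm(d) - dterm(d + t))


def force_density_model(stack: MagnetStack, d, gain: float):
    """Synthetic magnetic force density (N/m) at magnet distance ``d``.

    ``p_m = gain * B * (-dB/dd)``: the superparamagnetic body-force form
    with one calibratable gain (units fold the film magnetization per unit
    length into ``gain``).  Non-negative, strictly decreasing, with a
    ``d^-7`` dipole far field.
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    B = axial_field(stack, d)
    dB = _axial_field_gradient(stack, d)
    return gain * B * (-dB)


def far_field_slope(stack: MagnetStack, d_center, quantity: str = "field",
                    rel_step: float = 0.01) -> float:
    """Numeric log-log decay slope at distance ``d_center`` from the stack
    *center*.

    The dipole limit is ``-3`` for the field and ``-7`` for the
    ``B * dB/dd`` force density.  The slope is taken against the
    center-referenced distance because the leading correction to the
    face-referenced slope decays only as thickness/distance (the effective
    dipole sits at the stack's center), which would mask the dipole law.
    """
    t2 = stack.total_thickness / 2.0
    z = np.array([d_center, d_center * (1.0 + rel_step)])
    if quantity == "field":
        y = axial_field(stack, z - t2)
    elif quantity == "force":
        y = force_density_model(stack, z - t2, 1.0)
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return float(np.diff(np.log(y))[0] / np.diff(np.log(z))[0])


@dataclass
class CalibrationCurve:
    """Monotone map from magnet distance to magnetic force density.

    Built from cell-free static deflections; evaluation outside the sampled
    range clamps to the end values with a warning.
    """

    d: np.ndarray
    W_m: np.ndarray
    p_m: np.ndarray
    mode: str
    beam: BeamSpec

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.W_m = np.asarray(self.W_m, dtype=float)
        self.p_m = np.asarray(self.p_m, dtype=float)
        self._interp = PchipInterpolator(self.d, self.p_m, extrapolate=False)

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        if np.any(d < self.d[0]) or np.any(d > self.d[-1]):
            warnings.warn(
                "calibration evaluated outside the sampled distance range; "
                "clamping to end values",
                stacklevel=2,
            )
        dc = np.clip(d, self.d[0], self.d[-1])
        out = self._interp(dc)
        return float(out) if np.isscalar(d) or d.ndim == 0 else out


def build_calibration(pairs, beam: BeamSpec, mode: str = "energy_consistent",
                      noise_tol: float = 0.02) -> CalibrationCurve:
    """Build a calibration curve from cell-free ``(d, W_m)`` measurements.

    Parameters
    ----------
    pairs : sequence of (float, float)
        Magnet distance (m) and static cell-free tip deflection (m).
    beam : BeamSpec
    mode : str
        Static-inversion convention, see
        :func:`~cardiobeam.beam.magnetic_density_from_static_deflection`.
    noise_tol : float
        Allowed non-monotone wiggle in ``W_m`` vs ``d``, relative to the
        full ``W_m`` range; violations beyond it raise ``CalibrationError``.
    """
    pairs = sorted((float(d), float(w)) for d, w in pairs)
    if len(pairs) < 3:
        raise CalibrationError("need at least 3 distance points")
    d = np.array([p[0] for p in pairs])
    W_m = np.array([p[1] for p in pairs])
    if np.any(np.diff(d) <= 0):
        raise CalibrationError("magnet distances must be strictly increasing (no repeats)")
    span = np.ptp(W_m)
    if span > 0 and np.any(np.diff(W_m) > noise_tol * span):
        raise CalibrationError(
            "cell-free deflection increases with magnet distance beyond the "
            "noise tolerance; check the measurement"
        )
    if np.any(W_m < -noise_tol * max(span, np.max(np.abs(W_m), initial=0.0))):
        raise CalibrationError("cell-free deflections must be non-negative")

    p_m = magnetic_density_from_static_deflection(W_m, beam, mode=mode)
    # enforce the monotone, non-negative invariant before interpolating
    p_m = np.maximum.accumulate(np.maximum(p_m, 0.0)[::-1])[::-1]
    return CalibrationCurve(d=d, W_m=W_m, p_m=p_m, mode=mode, beam=beam)
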