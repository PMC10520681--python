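"""Unit-tagged configuration parsing.

All internal quantities are SI (m, s, N, Pa, T).  Config files may tag values
with common lab units (``"200 um"``, ``"12 kPa"``); conversion happens here,
at the boundary, and nowhere else.
"""

from __future__ import annotations

import re
from typing import Any

import yaml

# multiplier to SI base unit
_UNITS: dict[str, float] = {
    # length
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    # time
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "min": 60.0,
    # pressure / modulus
    "Pa": 1.0, "kPa": 1e3, "MPa": 1e6, "GPa": 1e9,
    # dynamic viscosity
    "Pa*s": 1.0, "Pa.s": 1.0, "mPa*s": 1e-3, "mPa.s": 1e-3, "cP": 1e-3,
    # force
    "N": 1.0, "mN": 1e-3, "uN": 1e-6, "µN": 1e-6, "nN": 1e-9,
    # force per unit length
    "N/m": 1.0, "mN/m": 1e-3, "uN/m": 1e-6, "µN/m": 1e-6,
    # flux density
    "T": 1.0, "mT": 1e-3,
    # frequency
    "Hz": 1.0,
    # dimensionless
    "": 1.0,
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]*)\s*$")


def parse_quantity(value: Any) -> float:
    """Convert a possibly unit-tagged scalar to SI.

    Numbers pass through unchanged (assumed SI already); strings must look
    like ``"<number> [unit]"`` with a known unit tag.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise TypeError(f"cannot interpret quantity {value!r}")
    m = _QTY_RE.match(value)
    if m is None:
        raise ValueError(f"malformed quantity {value!r}")
    num, unit = m.groups()
    if unit not in _UNITS:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(num) * _UNITS[unit]


def load_config(path: str) -> dict:
    """Load a YAML config file into a plain dict (no unit conversion yet)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def beam_from_config(cfg: dict):
    """Build a :class:`~cardiobeam.beam.BeamSpec` from a ``beam:`` section."""
    from .beam import BeamSpec

    return BeamSpec(
        L0=parse_quantity(cfg["length"]),
        b=parse_quantity(cfg["width"]),
        h=parse_quantity(cfg["thickness"]),
        E=parse_quantity(cfg["modulus"]),
        nu=float(cfg.get("poisson", 0.5)),
        mu=parse_quantity(cfg.get("viscosity", 1e-3)),
    )


def protocol_from_config(cfg: dict):
    from .synth import TwitchProtocol

    levels = [parse_quantity(v) for v in cfg["preload_levels"]]
    return TwitchProtocol(
        period=parse_quantity(cfg.get("period", 2.0)),
        pulse_width=parse_quantity(cfg.get("pulse_width", 0.005)),
        hold=parse_quantity(cfg.get("hold", 0.5)),
        preload_levels=levels,
        fps=float(cfg.get("fps", 240.0)),
        n_twitches=int(cfg.get("n_twitches", 8)),
        label=str(cfg.get("label", "")),
    )


def twitch_model_from_config(cfg: dict):
    from .synth import TwitchModel

    return TwitchModel(
        F0=parse_quantity(cfg["F0"]),
        s_FL=float(cfg.get("s_FL", 1.0)),
        t_rise=parse_quantity(cfg.get("t_rise", 0.03)),
        t_decay=parse_quantity(cfg.get("t_decay", 0.15)),
        eps_ref=float(cfg.get("eps_ref", 1e-3)),
        noise_sd=parse_quantity(cfg.get("noise_sd", 0.0)),
    )


def tracking_config_from_config(cfg: dict):
    from .tracking import TrackingConfig

    return TrackingConfig(
        px_per_mm=float(cfg["px_per_mm"]),
        threshold=cfg.get("threshold", "otsu"),
        clamp_px=int(cfg.get("clamp_px", 0)),
        fit_window=float(cfg.get("fit_window", 1.0)),
        smooth_window=int(cfg.get("smooth_window", 7)),
    )
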