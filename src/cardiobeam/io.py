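"""Serialization: deflection traces, calibration curves, ground truth,
frame stacks and analysis reports.

Traces travel as CSV with a fixed, unit-bearing header plus a JSON sidecar
holding the beam spec; frame stacks as multi-page TIFF or numbered PNG
sequences.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .beam import BeamSpec, DeflectionTrace
from .magnet import CalibrationCurve

TRACE_COLUMNS = ["t_s", "W_m", "Wdot_mps", "curvature_per_m"]
CAL_COLUMNS = ["d_m", "W_m_m", "p_m_N_per_m"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: DeflectionTrace, path) -> None:
    """Write a deflection trace as CSV + JSON sidecar (beam and provenance)."""
    path = Path(path)
    df = pd.DataFrame({
        "t_s": trace.t, "W_m": trace.W,
        "Wdot_mps": trace.Wdot, "curvature_per_m": trace.c,
    })
    df.to_csv(path, index=False)
    meta = {
        "beam": trace.beam.to_dict(),
        "provenance": trace.provenance,
        "columns": TRACE_COLUMNS,
    }
    for key in ("fps", "reference_index", "alpha_r2", "p_m0", "eps_pre",
                "stim_times", "level_id", "label", "period", "hold"):
        if key in trace.meta:
            v = trace.meta[key]
            meta[key] = v.tolist() if isinstance(v, np.ndarray) else v
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_trace(path) -> DeflectionTrace:
    """Read a trace CSV (validating the unit-bearing header) and its sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != TRACE_COLUMNS:
        raise ValueError(
            f"unexpected trace columns {list(df.columns)}; expected {TRACE_COLUMNS}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing trace sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    beam = BeamSpec.from_dict(meta["beam"])
    extra = {k: v for k, v in meta.items() if k not in ("beam", "provenance", "columns")}
    return DeflectionTrace(
        t=df["t_s"].to_numpy(), W=df["W_m"].to_numpy(),
        Wdot=df["Wdot_mps"].to_numpy(), c=df["curvature_per_m"].to_numpy(),
        beam=beam, provenance=meta.get("provenance", "tracked"), meta=extra)


def write_calibration(cal: CalibrationCurve, path) -> None:
    path = Path(path)
    pd.DataFrame({
        "d_m": cal.d, "W_m_m": cal.W_m, "p_m_N_per_m": cal.p_m,
    }).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({
        "mode": cal.mode, "beam": cal.beam.to_dict(),
    }, indent=2))


def read_calibration(path) -> CalibrationCurve:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != CAL_COLUMNS:
        raise ValueError(
            f"unexpected calibration columns {list(df.columns)}; expected {CAL_COLUMNS}")
    meta = json.loads(_sidecar(path).read_text())
    return CalibrationCurve(
        d=df["d_m"].to_numpy(), W_m=df["W_m_m"].to_numpy(),
        p_m=df["p_m_N_per_m"].to_numpy(), mode=meta["mode"],
        beam=BeamSpec.from_dict(meta["beam"]))


def write_ground_truth(truth, out_dir) -> None:
    """Write a synthetic experiment as per-level CSVs + one JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": truth.seed,
        "beam": truth.beam.to_dict(),
        "protocol": {
            "period": truth.protocol.period,
            "pulse_width": truth.protocol.pulse_width,
            "hold": truth.protocol.hold,
            "preload_levels": list(truth.protocol.preload_levels),
            "fps": truth.protocol.fps,
            "n_twitches": truth.protocol.n_twitches,
            "label": truth.protocol.label,
        },
        "twitch_model": {
            "F0": truth.model.F0, "s_FL": truth.model.s_FL,
            "t_rise": truth.model.t_rise, "t_decay": truth.model.t_decay,
            "eps_ref": truth.model.eps_ref, "noise_sd": truth.model.noise_sd,
        },
        "levels": [],
    }
    for lv in truth.levels:
        name = f"level_{lv.level_id:02d}.csv"
        pd.DataFrame({
            "t_s": lv.t, "W_m": lv.W, "W_clean_m": lv.W_clean,
            "Wdot_mps": lv.Wdot, "F_cell_N": lv.F_cell, "p_m_N_per_m": lv.p_m,
        }).to_csv(out / name, index=False)
        manifest["levels"].append({
            "level_id": lv.level_id, "file": name, "p_m0": lv.p_m0,
            "eps_pre": lv.eps_pre,
            "eps_pre_cycles": lv.eps_pre_cycles.tolist(),
            "stim_times": lv.stim_times.tolist(),
            "peaks_true": lv.peaks_true.tolist(),
        })
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))


def write_frames(frames: np.ndarray, path, fmt: str = "tiff") -> list[Path]:
    """Write a frame stack as multi-page TIFF or a numbered PNG sequence."""
    path = Path(path)
    if fmt == "tiff":
        path = path if path.suffix else path.with_suffix(".tif")
        tifffile.imwrite(path, frames, photometric="minisblack")
        return [path]
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        files = []
        for i, fr in enumerate(frames):
            f = path / f"frame_{i:06d}.png"
            iio.imwrite(f, fr)
            files.append(f)
        return files
    raise ValueError(f"unknown frame format {fmt!r}")


def read_frames(path) -> np.ndarray:
    """Read frames from a TIFF stack, a PNG-sequence directory, or a video."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png")) or sorted(path.glob("*.tif*"))
        if not files:
            raise FileNotFoundError(f"no frames found in {path}")
        return np.stack([iio.imread(f) for f in files])
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        return arr[None] if arr.ndim == 2 else arr
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 4:  # video decoded as (n, H, W, channels)
        arr = arr.mean(axis=-1).astype(np.uint8)
    return arr


def write_fl_report(fl_by_condition: dict, comparisons: list, path) -> None:
    """JSON report: per-condition FL fits plus pairwise comparisons."""
    doc = {"conditions": {}, "comparisons": []}
    for name, fl in fl_by_condition.items():
        doc["conditions"][name] = {
            "points_relative_preload": fl.points[:, 0].tolist(),
            "points_pct_increase": fl.points[:, 1].tolist(),
            "eps_pre": fl.eps_pre.tolist(),
            "slope": fl.slope, "intercept": fl.intercept,
            "slope_ci95": list(fl.slope_ci), "slope_se": fl.slope_se,
            "r2": fl.r2, "seed": fl.seed,
        }
    for rep in comparisons:
        doc["comparisons"].append({
            "a": rep.label_a, "b": rep.label_b, "dslope": rep.dslope,
            "ci95": list(rep.ci), "p_value": rep.p_value, "verdict": rep.verdict,
        })
    Path(path).write_text(json.dumps(doc, indent=2))
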