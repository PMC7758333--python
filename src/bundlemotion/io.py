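"""Reading and writing pipeline artifacts.

Image stacks travel as multi-page 16-bit TIFF with a JSON sidecar carrying
the scan configuration, stimulus, planted truth, and seed; voltage traces
as two-column CSV (time_s, value) with a JSON sidecar.  The sidecar lives
next to the TIFF/CSV with the extension replaced by ``.json``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    FrapTrace,
    FrapTruth,
    MotionTruth,
    Recording,
    ScanConfig,
    StimulusSpec,
    TimedStack,
)
from .phase_recon import PhaseStack

__all__ = [
    "write_timed_stack", "read_timed_stack",
    "write_phase_stack", "read_phase_stack",
    "write_recording", "read_recording",
    "write_frap_trace", "read_frap_trace",
]

_SCALE = "intensity_scale"  # sidecar key: float counts per 16-bit unit


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def _asdict(obj) -> Optional[dict]:
    return None if obj is None else dataclasses.asdict(obj)


def _to_uint16(frames: np.ndarray) -> tuple[np.ndarray, float]:
    peak = float(frames.max())
    scale = peak / 65535.0 if peak > 0 else 1.0
    return np.round(frames / scale).astype(np.uint16), scale


def write_timed_stack(path, stack: TimedStack) -> None:
    data, scale = _to_uint16(stack.frames)
    tifffile.imwrite(path, data)
    meta = {
        "scan": _asdict(stack.scan),
        "stimulus": _asdict(stack.stimulus),
        "truth": _asdict(stack.truth),
        "noise_sd": stack.noise_sd,
        "seed": stack.seed,
        _SCALE: scale,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_timed_stack(path) -> TimedStack:
    frames = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    frames *= meta.get(_SCALE, 1.0)
    truth = meta.get("truth")
    return TimedStack(
        frames=frames,
        scan=ScanConfig(**meta["scan"]),
        stimulus=StimulusSpec(**meta["stimulus"]),
        truth=None if truth is None else MotionTruth(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in truth.items()
        }),
        noise_sd=meta.get("noise_sd", 0.0),
        seed=meta.get("seed"),
    )


def write_phase_stack(path, stack: PhaseStack) -> None:
    data, scale = _to_uint16(np.clip(stack.frames, 0.0, None))
    tifffile.imwrite(path, data)
    meta = {
        "phases": stack.phases.tolist(),
        "nm_per_pixel": stack.nm_per_pixel,
        "provenance": stack.provenance,
        _SCALE: scale,
    }
    if stack.valid is not None:
        meta["invalid_pixels"] = int((~stack.valid).sum())
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_phase_stack(path) -> PhaseStack:
    frames = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    frames *= meta.get(_SCALE, 1.0)
    return PhaseStack(frames=frames, phases=np.asarray(meta["phases"]),
                      nm_per_pixel=meta.get("nm_per_pixel", 1.0),
                      provenance=meta.get("provenance", {}))


def write_recording(path, rec: Recording) -> None:
    pd.DataFrame({"time_s": rec.time_s, "value": rec.samples}).to_csv(
        path, index=False)
    meta = {
        "sample_rate": rec.sample_rate,
        "stimulus": _asdict(rec.stimulus),
        "epoch_markers": None if rec.epoch_markers is None
        else rec.epoch_markers.tolist(),
        "meta": rec.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_recording(path) -> Recording:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    markers = meta.get("epoch_markers")
    return Recording(
        samples=df["value"].to_numpy(),
        sample_rate=meta["sample_rate"],
        stimulus=StimulusSpec(**meta["stimulus"]),
        epoch_markers=None if markers is None else np.asarray(markers),
        meta=meta.get("meta", {}),
    )


def write_frap_trace(path, trace: FrapTrace) -> None:
    pd.DataFrame({"time_s": trace.time_s, "value": trace.intensity}).to_csv(
        path, index=False)
    meta = {"bleach_index": trace.bleach_index, "truth": _asdict(trace.truth)}
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_frap_trace(path) -> FrapTrace:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    truth = meta.get("truth")
    return FrapTrace(time_s=df["time_s"].to_numpy(),
                     intensity=df["value"].to_numpy(),
                     bleach_index=meta["bleach_index"],
                     truth=None if truth is None else FrapTruth(**truth))
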