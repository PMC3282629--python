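"""Disk formats: curve CSV dialect, JSON sidecars, frame stacks, provenance.

Curve sets are delimited text: a mandatory header row ``time_s`` followed by
one column per ROI; rates in counts/s at frame midpoints.  ROI pixel areas
and the frame duration travel in a ``<name>.meta.json`` sidecar; synthetic
ground truth in ``<name>.truth.json``.  Frame stacks are multi-frame TIFF
with a JSON sidecar holding frame timing and run-length-encoded ROI masks.
Results serialise to a versioned JSON schema.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .furcore import DRFEstimate, FURResult, LUSegment
from .simdata import FrameStack, SimulationTruth, SyntheticStudy
from .tac import TimeActivityCurve

__all__ = [
    "RESULT_SCHEMA_VERSION",
    "write_curves",
    "read_curves",
    "write_truth",
    "read_truth",
    "result_to_dict",
    "result_from_dict",
    "write_result",
    "read_result",
    "encode_mask",
    "decode_mask",
    "write_frames",
    "read_frames",
    "provenance_record",
]

RESULT_SCHEMA_VERSION = 1

_CURVE_ORDER = [
    "kidney_L",
    "kidney_R",
    "bkg_L",
    "bkg_R",
    "heart",
    "whole_body",
    "injection_site",
    "bladder",
]


def _ordered(names) -> list[str]:
    names = list(names)
    return [n for n in _CURVE_ORDER if n in names] + sorted(
        n for n in names if n not in _CURVE_ORDER
    )


def write_curves(curves, path) -> Path:
    """Write a named curve set (or a SyntheticStudy) as CSV + meta sidecar."""
    if isinstance(curves, SyntheticStudy):
        curves = curves.curves
    path = Path(path)
    names = _ordered(curves)
    first = curves[names[0]]
    frame = pd.DataFrame({"time_s": first.times})
    for name in names:
        tac = curves[name]
        if not tac.same_grid(first):
            raise ValueError("all curves must share one time grid")
        frame[name] = tac.values
    frame.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "frame_duration": first.frame_duration,
        "n_pixels": {n: curves[n].n_pixels for n in names},
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_curves(path) -> dict[str, TimeActivityCurve]:
    """Read the curve CSV dialect back into named TimeActivityCurves."""
    path = Path(path)
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns:
        raise ValueError("curve CSV must have a 'time_s' column")
    times = frame["time_s"].to_numpy(dtype=float)
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        frame_duration = float(meta["frame_duration"])
        n_pixels = meta.get("n_pixels", {})
    else:
        if times.size < 2:
            raise ValueError("cannot infer frame duration from a single frame")
        frame_duration = float(times[1] - times[0])
        n_pixels = {}
    out = {}
    for name in frame.columns:
        if name == "time_s":
            continue
        out[name] = TimeActivityCurve(
            times=times,
            values=frame[name].to_numpy(dtype=float),
            frame_duration=frame_duration,
            roi_name=name,
            n_pixels=n_pixels.get(name),
        )
    return out


def write_truth(truth: SimulationTruth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(truth), indent=1))
    return path


def read_truth(path) -> SimulationTruth:
    d = json.loads(Path(path).read_text())
    return SimulationTruth(
        fur_total_true=d["fur_total_true"],
        fur_per_kidney_true=tuple(d["fur_per_kidney_true"]),
        drf_true=tuple(d["drf_true"]),
        plasma_p0_true=d["plasma_p0_true"],
        t_min_per_kidney=tuple(d["t_min_per_kidney"]),
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _segment_to_dict(seg: LUSegment, frame_duration: float) -> dict:
    i0, i1 = seg.interval
    return {
        "interval_frames": [int(i0), int(i1)],
        "interval_seconds": [i0 * frame_duration, i1 * frame_duration],
        "slope_per_s": seg.slope,
        "intercept": seg.intercept,
        "intercept_prior": seg.intercept_prior,
        "source": seg.source,
    }


def result_to_dict(result: FURResult, frame_duration: float = 5.0) -> dict:
    return {
        "schema_version": RESULT_SCHEMA_VERSION,
        "fur_total": result.fur_total,
        "fur_left": result.fur_left,
        "fur_right": result.fur_right,
        "k_l": result.k_l,
        "k_r": result.k_r,
        "p0": result.p0,
        "id_rate": result.id_rate,
        "drf": {k: list(v) for k, v in result.drf.as_dict().items()},
        "drf_consensus": list(result.drf_consensus),
        "lu_segments": {
            s: _segment_to_dict(seg, frame_duration)
            for s, seg in result.lu_segments.items()
        },
        "plateau_intervals": {
            s: list(map(int, v)) for s, v in result.plateau_intervals.items()
        },
        "fit_window_s": list(result.fit_window),
        "renogram_descriptors": result.renogram_descriptors,
        "qc_flags": list(result.qc_flags),
    }


def result_from_dict(d: dict) -> FURResult:
    drf_pairs = {k: tuple(v) for k, v in d["drf"].items()}
    consensus = tuple(d["drf_consensus"])
    drf = DRFEstimate(
        renogram_integral=drf_pairs["renogram_integral"],
        pr_slope=drf_pairs["pr_slope"],
        irf_plateau=drf_pairs["irf_plateau"],
        consensus=consensus,
    )
    segments = {
        s: LUSegment(
            interval=tuple(sd["interval_frames"]),
            slope=sd["slope_per_s"],
            intercept=sd["intercept"],
            intercept_prior=sd["intercept_prior"],
            source=sd["source"],
        )
        for s, sd in d.get("lu_segments", {}).items()
    }
    return FURResult(
        fur_total=d["fur_total"],
        fur_left=d["fur_left"],
        fur_right=d["fur_right"],
        k_l=d["k_l"],
        k_r=d["k_r"],
        p0=d["p0"],
        id_rate=d["id_rate"],
        drf=drf,
        drf_consensus=consensus,
        lu_segments=segments,
        plateau_intervals={
            s: tuple(v) for s, v in d.get("plateau_intervals", {}).items()
        },
        fit_window=tuple(d.get("fit_window_s", (0.0, 0.0))),
        renogram_descriptors=d.get("renogram_descriptors", {}),
        qc_flags=tuple(d.get("qc_flags", ())),
    )


def write_result(result: FURResult, path, frame_duration: float = 5.0) -> Path:
    path = Path(path)
    path.write_text(json.dumps(result_to_dict(result, frame_duration), indent=1))
    return path


def read_result(path) -> FURResult:
    return result_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# frame stacks and masks
# ---------------------------------------------------------------------------

def encode_mask(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (runs of True over the flat array)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    runs = []
    for s, e in zip(starts, stops):
        runs.extend([int(s), int(e - s)])
    return {"shape": list(mask.shape), "runs": runs}


def decode_mask(d: dict) -> np.ndarray:
    shape = tuple(d["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    runs = d["runs"]
    for s, length in zip(runs[::2], runs[1::2]):
        flat[s : s + length] = True
    return flat.reshape(shape)


def write_frames(stack: FrameStack, path, sidecar=None) -> Path:
    """Write a frame stack as multi-frame TIFF plus a timing/mask sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
    payload = {
        "frame_duration": stack.frame_duration,
        "times_s": list(map(float, stack.times)),
        "masks": {name: encode_mask(m) for name, m in stack.masks.items()},
    }
    sidecar.write_text(json.dumps(payload))
    return path


def read_frames(path, sidecar=None) -> FrameStack:
    import tifffile

    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
    payload = json.loads(sidecar.read_text())
    return FrameStack(
        frames=frames,
        times=np.asarray(payload["times_s"], dtype=float),
        frame_duration=float(payload["frame_duration"]),
        masks={name: decode_mask(d) for name, d in payload["masks"].items()},
    )


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def provenance_record(config_obj, seed: int | None = None, command: str = "") -> dict:
    """Machine-readable record sufficient to reproduce a run exactly."""
    from . import __version__

    if dataclasses.is_dataclass(config_obj) and not isinstance(config_obj, type):
        config = dataclasses.asdict(config_obj)
    else:
        config = dict(config_obj)
    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "package": "renofur",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
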