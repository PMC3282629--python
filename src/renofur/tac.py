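"""Time-activity curves and ROI-level corrections for dynamic renography.

A dynamic renography study is reduced to a set of region-of-interest (ROI)
time-activity curves (TACs): count rates sampled at the midpoints of uniform
acquisition frames.  This module holds the TAC container and the standard
ROI-level operations: extraction from a frame stack, background subtraction
scaled by ROI area, estimation of the injected dose from the early whole-body
count rate, conversion of a kidney curve to percent of injected dose (%ID),
and simple renogram shape descriptors (time to peak, peak height, uptake
slope).

Conventions
-----------
* All curves are count *rates* (counts/s); raw frame counts are
  ``rate * frame_duration``.
* Frame indices are 0-based; intervals are half-open ``[start, end)``.
* Correction order is fixed: background-correct first, then convert to %ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TimeActivityCurve",
    "Renogram",
    "InjectedDose",
    "InvalidStudyError",
    "extract_tac",
    "background_correct",
    "estimate_injected_dose",
    "to_percent_id",
    "renogram_descriptors",
]


class InvalidStudyError(ValueError):
    """Raised when a study violates a precondition (e.g. non-positive ID)."""


@dataclass(frozen=True)
class TimeActivityCurve:
    """Count-rate samples of one ROI at uniform frame midpoints.

    Parameters
    ----------
    times
        Frame midpoint times in seconds, strictly increasing, uniformly
        spaced.
    values
        Count rate in counts/s per frame.
    frame_duration
        Frame length in seconds.
    roi_name
        Label of the ROI the curve was extracted from.
    n_pixels
        ROI area in pixels, used for area scaling in background correction.
        Optional for curves that never enter an area-scaled operation.
    """

    times: np.ndarray
    values: np.ndarray
    frame_duration: float
    roi_name: str = ""
    n_pixels: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9 * max(1.0, abs(dt[0])):
                raise ValueError("times must be uniformly spaced")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")

    def __len__(self) -> int:
        return self.times.size

    @property
    def counts(self) -> np.ndarray:
        """Raw counts per frame (rate times frame duration)."""
        return self.values * self.frame_duration

    def with_values(self, values: np.ndarray, roi_name: str | None = None) -> "TimeActivityCurve":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            roi_name=self.roi_name if roi_name is None else roi_name,
        )

    def same_grid(self, other: "TimeActivityCurve", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.times, other.times, rtol=0, atol=tol)
            and abs(self.frame_duration - other.frame_duration) <= tol
        )


@dataclass(frozen=True)
class Renogram:
    """A kidney curve in %ID units plus shape descriptors."""

    curve: TimeActivityCurve
    kidney_side: str
    descriptors: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class InjectedDose:
    """Injected dose expressed as a whole-body count rate.

    ``id_rate`` is the whole-body count rate averaged over the first minute,
    corrected for residual activity at the injection site (``residual_rate``).
    """

    id_rate: float
    window: tuple[float, float] = (0.0, 60.0)
    residual_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.id_rate > 0:
            raise InvalidStudyError("injected-dose rate must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_tac(
    frames, mask, frame_duration: float | None = None, roi_name: str = ""
) -> TimeActivityCurve:
    """Sum a frame stack over an ROI mask and convert to a count rate.

    ``frames`` may be a ``simdata.FrameStack`` or a raw ``(n, H, W)`` array
    (in which case ``frame_duration`` is required).
    """
    arr = getattr(frames, "frames", frames)
    if hasattr(frames, "frame_duration"):
        frame_duration = frames.frame_duration
    if frame_duration is None or frame_duration <= 0:
        raise ValueError("frame_duration required when frames carry no timing")
    arr = np.asarray(arr, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if arr.ndim != 3:
        raise ValueError("frames must be a (n_frames, H, W) stack")
    if mask.shape != arr.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {arr.shape[1:]}"
        )
    n_pix = int(mask.sum())
    if n_pix == 0:
        raise ValueError("empty ROI mask")
    sums = arr[:, mask].sum(axis=1)
    n = arr.shape[0]
    times = getattr(frames, "times", None)
    if times is None:
        times = (np.arange(n) + 0.5) * frame_duration
    return TimeActivityCurve(
        times=np.asarray(times, dtype=float),
        values=sums / frame_duration,
        frame_duration=frame_duration,
        roi_name=roi_name,
        n_pixels=n_pix,
    )


def background_correct(
    kidney: TimeActivityCurve, background: TimeActivityCurve
) -> tuple[TimeActivityCurve, int]:
    """Subtract area-scaled background from a kidney curve.

    The background rate is scaled by the pixel-area ratio of the two ROIs
    before subtraction.  Negative corrected rates are clipped to zero; the
    number of clipped frames is returned as a QC count.

    Returns
    -------
    corrected, n_clipped
    """
    if not kidney.same_grid(background):
        raise ValueError("kidney and background curves must share the time grid")
    if kidney.n_pixels is not None and background.n_pixels is not None:
        scale = kidney.n_pixels / background.n_pixels
    else:
        if kidney.n_pixels != background.n_pixels:
            raise ValueError(
                "n_pixels required on both curves to scale background by ROI area"
            )
        scale = 1.0  # both None: assume equal-area ROIs
    corrected = kidney.values - scale * background.values
    n_clipped = int(np.count_nonzero(corrected < 0))
    corrected = np.clip(corrected, 0.0, None)
    out = replace(
        kidney,
        values=corrected,
        roi_name=(kidney.roi_name + "_corr") if kidney.roi_name else "corrected",
    )
    return out, n_clipped


def estimate_injected_dose(
    whole_body: TimeActivityCurve,
    injection_site: TimeActivityCurve | None = None,
    window: tuple[float, float] = (0.0, 60.0),
) -> InjectedDose:
    """Estimate the injected dose from the early whole-body count rate.

    The ID rate is the whole-body count rate minus the injection-site
    residual, averaged over frames whose midpoints fall in ``window``
    (midpoint strictly below the upper edge).
    """
    sel = (whole_body.times >= window[0]) & (whole_body.times < window[1])
    if not np.any(sel):
        raise InvalidStudyError("whole-body curve does not cover the ID window")
    wb = whole_body.values[sel]
    if injection_site is not None:
        if not whole_body.same_grid(injection_site):
            raise ValueError("whole-body and injection-site curves must share the grid")
        res = injection_site.values[sel]
    else:
        res = np.zeros_like(wb)
    id_rate = float(np.mean(wb - res))
    if id_rate <= 0:
        raise InvalidStudyError(
            "non-positive injected-dose rate: whole-body does not exceed the "
            "injection-site residual over the first minute"
        )
    return InjectedDose(id_rate=id_rate, window=window, residual_rate=float(np.mean(res)))


def to_percent_id(
    corrected_kidney: TimeActivityCurve,
    injected_dose: InjectedDose,
    kidney_side: str = "",
    whole_body: TimeActivityCurve | None = None,
    per_frame: bool = False,
) -> Renogram:
    """Convert a background-corrected kidney curve to %ID.

    By default divides by the scalar first-minute ID rate.  With
    ``per_frame=True`` the kidney curve is instead divided frame-by-frame by
    the residual-corrected whole-body curve (an alternative reading of the
    normalisation; requires ``whole_body``).
    """
    if per_frame:
        if whole_body is None:
            raise ValueError("per-frame normalisation requires the whole-body curve")
        denom = whole_body.values - injected_dose.residual_rate
        if np.any(denom <= 0):
            raise InvalidStudyError("whole-body curve non-positive after residual correction")
        values = 100.0 * corrected_kidney.values / denom
    else:
        values = 100.0 * corrected_kidney.values / injected_dose.id_rate
    curve = replace(corrected_kidney, values=values)
    reno = Renogram(curve=curve, kidney_side=kidney_side)
    if len(curve) >= 10:
        desc, flags = renogram_descriptors(reno)
        reno = replace(reno, descriptors=desc, flags=tuple(flags))
    return reno


def renogram_descriptors(renogram: Renogram) -> tuple[dict, list[str]]:
    """Time to peak, peak height and uptake slope of a renogram.

    * ``time_to_peak`` — midpoint time of the global maximum (first
      occurrence on ties), seconds.
    * ``peak_height`` — that maximum, %ID.
    * ``uptake_slope`` — least-squares slope of the renogram between 20% and
      80% of the time to peak, %ID/min.

    A curve that never turns over (peak on the last frame) is flagged
    ``no_washout``.
    """
    curve = renogram.curve
    if len(curve) < 10:
        raise ValueError("renogram descriptors need at least 10 frames")
    flags: list[str] = []
    i_peak = int(np.argmax(curve.values))  # argmax returns the first maximum
    if i_peak == len(curve) - 1:
        flags.append("no_washout")
    t_peak = float(curve.times[i_peak])
    peak = float(curve.values[i_peak])
    lo, hi = 0.2 * t_peak, 0.8 * t_peak
    sel = (curve.times >= lo) & (curve.times <= hi)
    if np.count_nonzero(sel) >= 2:
        slope_per_s = float(np.polyfit(curve.times[sel], curve.values[sel], 1)[0])
        uptake_slope = slope_per_s * 60.0
    else:
        uptake_slope = float("nan")
        flags.append("uptake_slope_undefined")
    desc = {
        "time_to_peak": t_peak,
        "peak_height": peak,
        "uptake_slope": uptake_slope,
    }
    return desc, flags
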