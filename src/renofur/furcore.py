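"""Fractional uptake rate (FUR) and split renal function from renography.

Implements the quantitative chain of MAG3 renography:

1. **Patlak-Rutland (PR) plot** of a background-corrected kidney curve
   ``R(t)`` against the plasma (cardiac) curve ``P(t)``:
   ``y = R(t)/P(t)`` versus ``x = int_0^t P / P(t)``.  With this convention
   the abscissa has dimension time and the slope of the linear uptake (LU)
   segment is the renal uptake constant ``k`` in 1/s.
2. **Impulse retention function (IRF)** by constrained least-squares
   deconvolution of ``R = conv(P, H) dt`` — ``H`` non-negative,
   non-increasing, lightly smoothed.  The early plateau of ``H`` has height
   ``k`` and ends at the minimum transit time; the theoretical equality of
   PR slope and IRF plateau height underpins both the automatic LU-segment
   detection and a consistency QC check.
3. **LU segment detection** from the dominant IRF plateau before the
   renogram peak; the LU line is fitted with an extra pseudo data point at
   ``x = 0`` whose ordinate is an intercept estimate derived from the IRF,
   stabilising the fit.
4. **P(0)** by mono-exponential back-extrapolation of the cardiac curve over
   the combined extent of the two LU segments.
5. **FUR** = ``P(0) (k_l + k_r) / ID``, reported in %ID/min; **DRF** by
   three methods (renogram integrals, PR slopes, IRF plateau heights) over
   the common uptake interval, with their mutual agreement as a QC measure;
   split FUR = total FUR times DRF/100.
6. A standalone **attenuation sensitivity** tool: how a depth difference
   between the kidneys distorts an ideal split under a linear attenuation
   coefficient (no depth correction is applied in the main pipeline).

Frames are 0-based and intervals half-open ``[start, end)`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import toeplitz

from .tac import (
    InjectedDose,
    InvalidStudyError,
    Renogram,
    TimeActivityCurve,
    background_correct,
    estimate_injected_dose,
    to_percent_id,
)

__all__ = [
    "PlasmaModel",
    "PatlakPlot",
    "IRFEstimate",
    "LUSegment",
    "FURResult",
    "AnalysisOptions",
    "PlasmaFitError",
    "LUSegmentError",
    "plasma_integral",
    "build_patlak",
    "fit_plasma_monoexp",
    "deconvolve_irf",
    "detect_lu_segment",
    "fit_lu_slope",
    "compute_fur",
    "compute_drf",
    "DRFEstimate",
    "split_fur",
    "attenuation_drf",
    "depth_for_split",
    "analyze_study",
    "qc_report",
]

PCT_PER_MIN = 100.0 * 60.0  # 1/s -> %/min conversion applied once, at FUR reporting


class PlasmaFitError(RuntimeError):
    """Mono-exponential plasma fit failed; carries the log-linear fallback."""

    def __init__(self, message: str, loglinear: tuple[float, float] | None = None):
        super().__init__(message)
        self.loglinear = loglinear  # (p0, decay_rate) from the log-linear fit


class LUSegmentError(ValueError):
    """No acceptable linear-uptake segment; a manual interval is required."""


@dataclass(frozen=True)
class PlasmaModel:
    """Mono-exponential description of the cardiac curve near injection."""

    p0: float                       # back-extrapolated P(0), counts/s
    decay_rate: float               # 1/s
    fit_window: tuple[float, float]  # seconds
    rss: float = 0.0

    def __post_init__(self) -> None:
        if not self.p0 > 0:
            raise ValueError("plasma P(0) must be positive")


@dataclass(frozen=True)
class PatlakPlot:
    """PR-plot coordinates on the frame grid.

    ``x`` in seconds (``int P / P``), ``y`` dimensionless (``R/P``); frames
    where the plasma falls below 1% of its maximum are masked invalid.
    """

    x: np.ndarray
    y: np.ndarray
    valid_mask: np.ndarray
    times: np.ndarray
    frame_duration: float
    plasma_values: np.ndarray


@dataclass(frozen=True)
class IRFEstimate:
    """Deconvolved impulse retention function (units 1/s per frame)."""

    irf: np.ndarray
    plateau_height: float
    plateau_interval: tuple[int, int]   # half-open frames
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class LUSegment:
    """Linear uptake segment of a PR plot."""

    interval: tuple[int, int]   # half-open frames
    slope: float = float("nan")       # 1/s
    intercept: float = float("nan")   # dimensionless
    intercept_prior: float = 0.0
    source: str = "auto"        # auto | manual


@dataclass(frozen=True)
class DRFEstimate:
    """Differential renal function by three methods, (L, R) percent pairs."""

    renogram_integral: tuple[float, float]
    pr_slope: tuple[float, float]
    irf_plateau: tuple[float, float]
    consensus: tuple[float, float]
    qc_flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "renogram_integral": self.renogram_integral,
            "pr_slope": self.pr_slope,
            "irf_plateau": self.irf_plateau,
        }


@dataclass(frozen=True)
class FURResult:
    """Complete per-study result of the FUR/DRF pipeline."""

    fur_total: float                 # %ID/min
    fur_left: float
    fur_right: float
    k_l: float                       # 1/s
    k_r: float
    p0: float                        # counts/s
    id_rate: float                   # counts/s
    drf: DRFEstimate
    drf_consensus: tuple[float, float]
    lu_segments: dict = field(default_factory=dict)       # side -> LUSegment
    plateau_intervals: dict = field(default_factory=dict)  # side -> (start, end)
    fit_window: tuple[float, float] = (0.0, 0.0)
    renogram_descriptors: dict = field(default_factory=dict)
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        scale = max(abs(self.fur_total), 1.0)
        if abs(self.fur_left + self.fur_right - self.fur_total) > 1e-9 * scale:
            raise ValueError("split FUR must sum to the total")
        if abs(sum(self.drf_consensus) - 100.0) > 1e-6:
            raise ValueError("DRF consensus pair must sum to 100")


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable switches of the analysis pipeline (defaults documented)."""

    plateau_band: float = 0.10          # relative IRF plateau band
    smoothing: float = 1e-3             # second-difference penalty weight
    pseudo_point_weight: float = 1.0    # LU intercept pseudo-point weight
    min_lu_length: int = 4              # frames
    id_window: tuple[float, float] = (0.0, 60.0)
    percent_id_per_frame: bool = False
    manual_lu: dict | None = None       # side -> (start, end) frames


# ---------------------------------------------------------------------------
# Patlak-Rutland plot
# ---------------------------------------------------------------------------

def plasma_integral(plasma: TimeActivityCurve) -> np.ndarray:
    """Cumulative ``int_0^{t_i} P`` on the midpoint grid.

    Trapezoid between midpoints plus a leading rectangle ``t_0 * P_0`` for
    the unobserved ``[0, t_0)`` interval.
    """
    return (
        cumulative_trapezoid(plasma.values, plasma.times, initial=0.0)
        + plasma.times[0] * plasma.values[0]
    )


def build_patlak(
    renogram_counts: TimeActivityCurve, plasma: TimeActivityCurve
) -> PatlakPlot:
    """PR transform of a corrected kidney curve against the plasma curve."""
    if not renogram_counts.same_grid(plasma):
        raise ValueError("kidney and plasma curves must share the time grid")
    p = plasma.values
    pmax = float(np.max(p))
    if pmax <= 0:
        raise InvalidStudyError("plasma curve has no positive values")
    valid = p >= 0.01 * pmax
    if int(valid.sum()) < 5:
        raise InvalidStudyError("fewer than 5 frames with usable plasma signal")
    integral = plasma_integral(plasma)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(valid, integral / p, np.nan)
        y = np.where(valid, renogram_counts.values / p, np.nan)
    return PatlakPlot(
        x=x,
        y=y,
        valid_mask=valid,
        times=plasma.times,
        frame_duration=plasma.frame_duration,
        plasma_values=p,
    )


# ---------------------------------------------------------------------------
# plasma back-extrapolation
# ---------------------------------------------------------------------------

def fit_plasma_monoexp(
    cardiac: TimeActivityCurve, window: tuple[float, float]
) -> PlasmaModel:
    """Fit ``A exp(-lambda t)`` to the cardiac curve over ``window``.

    Nonlinear least squares initialised from a log-linear fit; ``p0`` is the
    fitted value at ``t = 0`` (back-extrapolation).
    """
    sel = (cardiac.times >= window[0]) & (cardiac.times <= window[1])
    sel &= cardiac.values > 0
    if int(sel.sum()) < 4:
        raise InvalidStudyError("plasma fit window must contain >= 4 positive frames")
    t, v = cardiac.times[sel], cardiac.values[sel]
    slope, logint = np.polyfit(t, np.log(v), 1)
    p0_ll, lam_ll = float(np.exp(logint)), float(-slope)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, lam: a * np.exp(-lam * tt),
            t,
            v,
            p0=[p0_ll, lam_ll],
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise PlasmaFitError(
            f"mono-exponential plasma fit did not converge: {exc}",
            loglinear=(p0_ll, lam_ll),
        ) from exc
    a, lam = float(popt[0]), float(popt[1])
    rss = float(np.sum((v - a * np.exp(-lam * t)) ** 2))
    if a <= 0:
        raise PlasmaFitError(
            "mono-exponential plasma fit returned non-positive P(0)",
            loglinear=(p0_ll, lam_ll),
        )
    return PlasmaModel(p0=a, decay_rate=lam, fit_window=tuple(window), rss=rss)


# ---------------------------------------------------------------------------
# constrained deconvolution
# ---------------------------------------------------------------------------

def deconvolve_irf(
    renogram_counts: TimeActivityCurve,
    plasma: TimeActivityCurve,
    smoothing: float = 1e-3,
    plateau_band: float = 0.10,
) -> IRFEstimate:
    """Estimate the impulse retention function by constrained least squares.

    Solves ``R_i = dt * sum_j P_{i-j} H_j`` for ``H >= 0`` non-increasing,
    with a light second-difference smoothing penalty.  ``H_k`` estimates the
    retention at lag ``k * dt`` (midpoint quadrature over the plasma
    samples; the lag-zero column carries half weight because only half of
    the first frame's input can contribute by its own midpoint).
    Monotonicity is enforced exactly by parameterising ``H`` as a reversed
    cumulative sum of non-negative increments and solving the resulting
    NNLS problem.

    The plateau is the longest run of frames before the renogram peak where
    ``H`` stays within ``plateau_band`` (relative) of its running maximum;
    ties go to the earliest run.  ``plateau_height`` is the median of ``H``
    over that run.
    """
    if not renogram_counts.same_grid(plasma):
        raise ValueError("kidney and plasma curves must share the time grid")
    n = len(plasma)
    if n < 20:
        raise InvalidStudyError("deconvolution requires at least 20 frames")
    dt = plasma.frame_duration
    r = renogram_counts.values
    if np.max(r) <= 0:
        return IRFEstimate(
            irf=np.zeros(n),
            plateau_height=0.0,
            plateau_interval=(0, 0),
            flags=("zero_renogram",),
        )
    a = dt * toeplitz(plasma.values, np.zeros(n))
    a[:, 0] *= 0.5  # half-frame overlap of the lag-zero cell
    u = np.triu(np.ones((n, n)))          # H = U g, g >= 0  =>  H >= 0, non-increasing
    au = a @ u
    d2 = np.diff(np.eye(n), n=2, axis=0)  # second-difference operator on H
    d2u = d2 @ u
    lam = smoothing * np.linalg.norm(au) / max(np.linalg.norm(d2u), 1e-30)
    design = np.vstack([au, lam * d2u])
    rhs = np.concatenate([r, np.zeros(n - 2)])
    g, _ = optimize.nnls(design, rhs, maxiter=10 * n)
    h = u @ g

    flags: list[str] = []
    i_peak = int(np.argmax(r))
    start, end = _dominant_plateau(h, i_peak, plateau_band)
    if end <= start:
        flags.append("no_plateau")
        height = float(h[0]) if n else 0.0
    else:
        height = float(np.median(h[start:end]))
    return IRFEstimate(
        irf=h, plateau_height=height, plateau_interval=(start, end), flags=tuple(flags)
    )


def _dominant_plateau(h: np.ndarray, i_peak: int, band: float) -> tuple[int, int]:
    """Longest near-flat stretch of ``h`` within frames ``[0, i_peak]``.

    ``h`` is non-increasing by construction, so a plateau is a stretch
    ``[i, j)`` over which ``h`` falls by less than ``band`` relative to its
    value at ``i``.  The longest such stretch wins; ties go to the earliest
    (an isolated lag-zero spike therefore cannot mask the renal plateau).
    """
    stop = min(i_peak + 1, h.size)
    if stop == 0 or np.max(h[:stop]) <= 0:
        return 0, 0
    best = (0, 0)
    j = 0
    for i in range(stop):
        if h[i] <= 0:
            break
        j = max(j, i + 1)
        while j < stop and h[j] >= (1.0 - band) * h[i]:
            j += 1
        if j - i > best[1] - best[0]:  # strict: earliest stretch wins ties
            best = (i, j)
    return best


# ---------------------------------------------------------------------------
# LU segment detection and fitting
# ---------------------------------------------------------------------------

def detect_lu_segment(
    patlak: PatlakPlot,
    irf: IRFEstimate,
    min_length: int = 4,
) -> LUSegment:
    """LU segment = PR frames of the IRF plateau, trimmed for bolus arrival.

    The first two frames after the plasma curve exceeds 10% of its maximum
    are discarded (bolus mixing); the remaining plateau frames form the
    segment.  The intercept prior is the excess of the IRF over its plateau
    at lag zero, converted to PR-ordinate units (``(H[0] - plateau) * dt``) —
    an estimate of the vascular component of the kidney ROI.
    """
    p_start, p_end = irf.plateau_interval
    if p_end <= p_start:
        raise LUSegmentError("empty IRF plateau; supply a manual LU interval")
    arrival = int(np.argmax(patlak.plasma_values > 0.1 * np.max(patlak.plasma_values)))
    start = max(p_start, arrival + 2)
    valid_idx = np.flatnonzero(patlak.valid_mask)
    end = min(p_end, int(valid_idx[-1]) + 1)
    if end - start < min_length:
        raise LUSegmentError(
            f"LU segment [{start}, {end}) shorter than {min_length} frames; "
            "supply a manual interval"
        )
    prior = max(float(irf.irf[0]) - irf.plateau_height, 0.0) * patlak.frame_duration
    return LUSegment(interval=(start, end), intercept_prior=prior, source="auto")


def fit_lu_slope(
    patlak: PatlakPlot, segment: LUSegment, pseudo_point_weight: float = 1.0
) -> LUSegment:
    """Weighted least-squares line over the LU segment plus a pseudo-point.

    The pseudo-point ``(0, intercept_prior)`` enters with the weight of
    ``pseudo_point_weight`` ordinary observations, shrinking the fitted
    intercept toward the IRF-derived estimate.
    """
    i0, i1 = segment.interval
    sel = np.zeros_like(patlak.valid_mask)
    sel[i0:i1] = True
    sel &= patlak.valid_mask
    xs, ys = patlak.x[sel], patlak.y[sel]
    if xs.size < 2:
        raise LUSegmentError("LU segment has fewer than 2 usable frames")
    w = np.ones(xs.size + 1)
    w[-1] = pseudo_point_weight
    xs = np.append(xs, 0.0)
    ys = np.append(ys, segment.intercept_prior)
    if np.ptp(xs) <= 0:
        raise ValueError("singular design: constant abscissa over the LU segment")
    sw = np.sqrt(w)
    design = np.column_stack([xs, np.ones_like(xs)]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(design, ys * sw, rcond=None)
    return replace(segment, slope=float(coef[0]), intercept=float(coef[1]))


# ---------------------------------------------------------------------------
# FUR / DRF
# ---------------------------------------------------------------------------

def compute_fur(
    k_l: float, k_r: float, plasma: PlasmaModel, injected: InjectedDose
) -> tuple[float, tuple[str, ...]]:
    """Total FUR = ``P(0) (k_l + k_r) / ID`` in %ID/min.

    Negative slopes are permitted but flagged.
    """
    flags = tuple(
        f"negative_slope_{side}" for side, k in (("L", k_l), ("R", k_r)) if k < 0
    )
    fur_total = plasma.p0 * (k_l + k_r) / injected.id_rate * PCT_PER_MIN
    return float(fur_total), flags


def _normalize_pair(left: float, right: float) -> tuple[float, float]:
    total = left + right
    if total <= 0:
        raise InvalidStudyError("zero total uptake: DRF undefined")
    return 100.0 * left / total, 100.0 * right / total


def compute_drf(
    corrected_l: TimeActivityCurve,
    corrected_r: TimeActivityCurve,
    patlak_l: PatlakPlot,
    patlak_r: PatlakPlot,
    irf_l: IRFEstimate,
    irf_r: IRFEstimate,
    uptake_interval: tuple[int, int],
    pseudo_point_weight: float = 1.0,
    agreement_tol: float = 5.0,
) -> DRFEstimate:
    """DRF over the common uptake interval by three methods.

    (a) integrals of the background-corrected renograms, (b) PR-plot slopes,
    (c) IRF plateau heights — each normalised to an (L, R) pair summing to
    100.  The consensus is the PR-slope pair; any method deviating from it
    by more than ``agreement_tol`` percentage points raises a QC flag.
    """
    i0, i1 = uptake_interval
    if i1 - i0 < 2:
        raise InvalidStudyError("uptake interval too short for DRF")
    t = corrected_l.times[i0:i1]
    integ = _normalize_pair(
        float(np.trapezoid(corrected_l.values[i0:i1], t)),
        float(np.trapezoid(corrected_r.values[i0:i1], t)),
    )
    slopes = []
    for patlak, irf in ((patlak_l, irf_l), (patlak_r, irf_r)):
        seg = LUSegment(
            interval=uptake_interval,
            intercept_prior=max(float(irf.irf[0]) - irf.plateau_height, 0.0)
            * patlak.frame_duration,
        )
        slopes.append(max(fit_lu_slope(patlak, seg, pseudo_point_weight).slope, 0.0))
    pr = _normalize_pair(*slopes)
    plateau = _normalize_pair(
        float(np.median(irf_l.irf[i0:i1])), float(np.median(irf_r.irf[i0:i1]))
    )
    flags = tuple(
        f"drf_method_disagreement_{name}"
        for name, pair in (("renogram_integral", integ), ("irf_plateau", plateau))
        if abs(pair[0] - pr[0]) > agreement_tol
    )
    return DRFEstimate(
        renogram_integral=integ,
        pr_slope=pr,
        irf_plateau=plateau,
        consensus=pr,
        qc_flags=flags,
    )


def split_fur(fur_total: float, drf_consensus: tuple[float, float]) -> tuple[float, float]:
    """Split the total FUR by the consensus DRF (exact multiplication)."""
    if abs(sum(drf_consensus) - 100.0) > 1e-6:
        raise ValueError("DRF pair must sum to 100")
    return fur_total * drf_consensus[0] / 100.0, fur_total * drf_consensus[1] / 100.0


# ---------------------------------------------------------------------------
# attenuation sensitivity (standalone tool; the pipeline applies no
# depth correction)
# ---------------------------------------------------------------------------

def attenuation_drf(
    true_split: tuple[float, float],
    depth_diff: float,
    mu: float = 0.12,
    deeper: str = "R",
) -> tuple[float, float]:
    """Observed DRF when one kidney lies ``depth_diff`` cm deeper.

    The deeper kidney's counts are attenuated by ``exp(-mu * depth_diff)``
    and the pair renormalised to 100.  ``mu`` is the linear attenuation
    coefficient in 1/cm (0.12 for 99mTc in soft tissue).
    """
    if mu <= 0:
        raise ValueError("attenuation coefficient must be positive")
    if min(true_split) <= 0:
        raise ValueError("both DRF shares must be positive")
    factor = float(np.exp(-mu * depth_diff))
    left, right = true_split
    if deeper == "R":
        right *= factor
    elif deeper == "L":
        left *= factor
    else:
        raise ValueError("deeper must be 'L' or 'R'")
    return _normalize_pair(left, right)


def depth_for_split(
    observed_split: tuple[float, float],
    mu: float = 0.12,
    true_split: tuple[float, float] = (50.0, 50.0),
) -> float:
    """Depth difference (cm) needed to turn ``true_split`` into the observed one.

    Closed form: ``d = ln(ratio_observed / ratio_true) / mu`` with each ratio
    taken as larger share over smaller share.
    """
    if mu <= 0:
        raise ValueError("attenuation coefficient must be positive")
    if min(observed_split) <= 0 or min(true_split) <= 0:
        raise ValueError("DRF shares must be positive")
    ratio_obs = max(observed_split) / min(observed_split)
    ratio_true = max(true_split) / min(true_split)
    return float(np.log(ratio_obs / ratio_true) / mu)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def analyze_study(
    curves: Mapping[str, TimeActivityCurve],
    options: AnalysisOptions | None = None,
    return_intermediates: bool = False,
):
    """Run the complete FUR/DRF pipeline on a named ROI curve set.

    Requires curves ``heart``, ``kidney_L``, ``kidney_R``, ``whole_body``;
    uses ``bkg_L``/``bkg_R`` and ``injection_site`` when present.
    """
    opts = options or AnalysisOptions()
    if "heart" not in curves:
        raise InvalidStudyError("cardiac curve required: missing 'heart' ROI")
    for name in ("kidney_L", "kidney_R", "whole_body"):
        if name not in curves:
            raise InvalidStudyError(f"missing required ROI curve '{name}'")
    plasma = curves["heart"]
    qc: list[str] = []

    injected = estimate_injected_dose(
        curves["whole_body"], curves.get("injection_site"), window=opts.id_window
    )

    corrected: dict[str, TimeActivityCurve] = {}
    for side in ("L", "R"):
        kidney = curves[f"kidney_{side}"]
        bkg = curves.get(f"bkg_{side}")
        if bkg is None:
            qc.append(f"no_background_roi_{side}")
            corrected[side] = kidney
        else:
            corrected[side], n_clip = background_correct(kidney, bkg)
            if n_clip:
                qc.append(f"clipped_{n_clip}_frames_{side}")

    patlak, irf, segments = {}, {}, {}
    for side in ("L", "R"):
        patlak[side] = build_patlak(corrected[side], plasma)
        irf[side] = deconvolve_irf(
            corrected[side], plasma, smoothing=opts.smoothing, plateau_band=opts.plateau_band
        )
        qc.extend(f"irf_{side}:{f}" for f in irf[side].flags)
        manual = (opts.manual_lu or {}).get(side)
        if manual is not None:
            prior = max(float(irf[side].irf[0]) - irf[side].plateau_height, 0.0)
            seg = LUSegment(
                interval=(int(manual[0]), int(manual[1])),
                intercept_prior=prior * plasma.frame_duration,
                source="manual",
            )
            qc.append(f"manual_lu_{side}")
        else:
            seg = detect_lu_segment(patlak[side], irf[side], min_length=opts.min_lu_length)
        segments[side] = fit_lu_slope(patlak[side], seg, opts.pseudo_point_weight)

    # mono-exponential fit window: convex hull of the two LU segments, seconds
    i_lo = min(segments[s].interval[0] for s in ("L", "R"))
    i_hi = max(segments[s].interval[1] for s in ("L", "R"))
    window = (float(plasma.times[i_lo]), float(plasma.times[i_hi - 1]))
    plasma_model = fit_plasma_monoexp(plasma, window)

    k_l, k_r = segments["L"].slope, segments["R"].slope
    fur_total, fur_flags = compute_fur(k_l, k_r, plasma_model, injected)
    qc.extend(fur_flags)

    drf = compute_drf(
        corrected["L"],
        corrected["R"],
        patlak["L"],
        patlak["R"],
        irf["L"],
        irf["R"],
        uptake_interval=(i_lo, i_hi),
        pseudo_point_weight=opts.pseudo_point_weight,
    )
    qc.extend(drf.qc_flags)
    fur_left, fur_right = split_fur(fur_total, drf.consensus)

    renograms: dict[str, Renogram] = {}
    descriptors: dict[str, dict] = {}
    for side in ("L", "R"):
        reno = to_percent_id(
            corrected[side],
            injected,
            kidney_side=side,
            whole_body=curves["whole_body"],
            per_frame=opts.percent_id_per_frame,
        )
        renograms[side] = reno
        descriptors[side] = dict(reno.descriptors)
        qc.extend(f"renogram_{side}:{f}" for f in reno.flags)

    result = FURResult(
        fur_total=fur_total,
        fur_left=fur_left,
        fur_right=fur_right,
        k_l=k_l,
        k_r=k_r,
        p0=plasma_model.p0,
        id_rate=injected.id_rate,
        drf=drf,
        drf_consensus=drf.consensus,
        lu_segments=dict(segments),
        plateau_intervals={s: irf[s].plateau_interval for s in ("L", "R")},
        fit_window=window,
        renogram_descriptors=descriptors,
        qc_flags=tuple(qc),
    )
    if return_intermediates:
        intermediates = {
            "corrected": corrected,
            "patlak": patlak,
            "irf": irf,
            "plasma_model": plasma_model,
            "injected": injected,
            "renograms": renograms,
        }
        return result, intermediates
    return result


def qc_report(
    curves: Mapping[str, TimeActivityCurve],
    path,
    options: AnalysisOptions | None = None,
    side: str = "L",
) -> FURResult:
    """Write the three-panel QC figure for one kidney and return the result.

    Panels: PR plot with the LU segment and fitted line; IRF with the
    detected plateau; %ID renogram with the fitted plasma-integral input
    (``k int P / ID``) over the uptake interval.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    result, inter = analyze_study(curves, options, return_intermediates=True)
    seg: LUSegment = result.lu_segments[side]
    patlak: PatlakPlot = inter["patlak"][side]
    irf: IRFEstimate = inter["irf"][side]
    reno: Renogram = inter["renograms"][side]
    injected: InjectedDose = inter["injected"]
    t = patlak.times

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    ax = axes[0]
    ax.plot(patlak.x, patlak.y, "k.", ms=3)
    i0, i1 = seg.interval
    xs = patlak.x[i0:i1]
    ax.plot(xs, seg.intercept + seg.slope * xs, "r-", lw=1.5)
    for xedge in (np.nanmin(xs), np.nanmax(xs)):
        ax.axvline(xedge, color="k", lw=0.8)
    ax.set_xlabel("int P / P  (s)")
    ax.set_ylabel("R / P")
    ax.set_title(f"PR plot, kidney {side} (k = {seg.slope:.4g} /s)")

    ax = axes[1]
    ax.step(t, irf.irf, where="mid", color="k")
    p0_, p1_ = irf.plateau_interval
    ax.axvspan(t[p0_], t[min(p1_, len(t)) - 1], color="orange", alpha=0.3)
    ax.axhline(irf.plateau_height, color="r", lw=0.8, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("IRF (1/s)")
    ax.set_title(f"IRF plateau = {irf.plateau_height:.4g} /s")

    ax = axes[2]
    ax.plot(t, reno.curve.values, "k-", lw=1)
    fitted = 100.0 * seg.slope * plasma_integral(curves["heart"]) / injected.id_rate
    ax.plot(t[i0:i1], fitted[i0:i1], "r--", lw=1.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("%ID")
    ax.set_title(f"renogram, FUR total = {result.fur_total:.1f} %ID/min")

    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return result
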