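"""Synthetic dynamic renography with closed-form ground truth.

Generates two-kidney MAG3-like studies — ROI time-activity curves and,
optionally, rendered 2-D frame stacks — from a compartmental forward model
whose fractional uptake rate (FUR) and differential renal function (DRF) are
known in closed form, so every downstream analysis stage can be validated
without animal data.

Forward model
-------------
* Plasma (cardiac ROI) input: bi-exponential bolus clearance
  ``P(t) = A1 exp(-alpha t) + A2 exp(-beta t)`` sampled at frame midpoints.
* Kidney parenchyma: linear time-invariant uptake
  ``R_k(t) = F_k * int_0^t P(tau) h_k(t - tau) dtau`` with a
  plateau-then-exponential retention function: ``h_k(u) = 1`` for
  ``u < T_min_k`` (minimum transit time) and ``exp(-w_k (u - T_min_k))``
  afterwards.  During uptake (``t < T_min_k``) the kidney is a pure
  integrator of plasma, which is exactly the regime in which the FUR
  definition ``FUR = P(0) (k_l + k_r) / ID`` holds.
* Kidney ROIs see parenchyma plus tissue background
  (``background_fraction * P``); paired background ROIs of equal pixel area
  see the background alone.
* Whole body is a conserved plateau at ``injected_dose``; an injection-site
  residual (a fraction of the dose) is released into circulation with rate
  ``residual_release_rate``; excreted activity accumulates in the bladder.
* Optional Poisson counting noise is applied to per-frame counts and
  converted back to rates.

Default parameter values are the study conditions emulated throughout the
package; see ``docs/methods.md`` for their rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import fftconvolve

from .tac import TimeActivityCurve

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SyntheticStudy",
    "FrameStack",
    "EllipseROI",
    "DEFAULT_GEOMETRY",
    "simulate_plasma",
    "simulate_kidney",
    "ground_truth_fur",
    "simulate_study",
    "render_frames",
]

_SIDES = {"L": 0, "R": 1}

#: Decay constant of 99mTc (half-life 6.01 h), for the optional decay switch.
TC99M_DECAY_RATE = np.log(2.0) / (6.01 * 3600.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic renography study.

    Two-element tuples are ordered (left, right).  Rates are per second,
    times in seconds, activities in counts/s at the detector.
    """

    frame_duration: float = 5.0
    n_frames: int = 120
    plasma_amplitudes: tuple[float, float] = (280.0, 70.0)   # A1, A2 counts/s
    plasma_rates: tuple[float, float] = (0.012, 0.005)       # alpha, beta 1/s
    uptake_constants: tuple[float, float] = (0.0140, 0.0176)  # F_k 1/s
    min_transit_times: tuple[float, float] = (140.0, 160.0)  # T_min,k s
    washout_rates: tuple[float, float] = (0.012, 0.012)      # 1/s
    background_fraction: float = 0.1
    injection_residual_fraction: float = 0.05
    residual_release_rate: float = 0.05                      # 1/s
    injected_dose: float = 2000.0                            # counts/s plateau
    physical_decay_rate: float = 0.0                         # 0 = no decay
    noise: str = "none"                                      # none | poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if sum(self.plasma_amplitudes) <= 0:
            raise ValueError("plasma amplitudes must sum to a positive value")
        for name in ("plasma_rates", "uptake_constants", "washout_rates"):
            if any(r < 0 for r in getattr(self, name)):
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.injection_residual_fraction < 1:
            raise ValueError("injection_residual_fraction must lie in [0, 1)")
        if self.background_fraction < 0 or self.residual_release_rate < 0:
            raise ValueError("fractions and rates must be non-negative")
        if self.physical_decay_rate < 0:
            raise ValueError("physical_decay_rate must be non-negative")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")

    @property
    def times(self) -> np.ndarray:
        """Frame midpoint times, seconds."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration

    def plasma_at(self, t: np.ndarray) -> np.ndarray:
        a1, a2 = self.plasma_amplitudes
        al, be = self.plasma_rates
        return a1 * np.exp(-al * np.asarray(t, float)) + a2 * np.exp(-be * np.asarray(t, float))


@dataclass(frozen=True)
class SimulationTruth:
    """Closed-form labels of a synthetic study."""

    fur_total_true: float                     # %ID/min
    fur_per_kidney_true: tuple[float, float]  # %ID/min, (L, R)
    drf_true: tuple[float, float]             # percent, sums to 100
    plasma_p0_true: float                     # counts/s
    t_min_per_kidney: tuple[float, float]     # s


@dataclass(frozen=True)
class EllipseROI:
    """Axis-aligned elliptical ROI on the image grid (row, col in pixels)."""

    center: tuple[float, float]
    axes: tuple[float, float]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        (r0, c0), (ar, ac) = self.center, self.axes
        return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


#: Default organ layout on a 128x128 grid.  Kidney and background ellipses
#: are congruent so their pixel areas match (equal-area background ROIs).
DEFAULT_GEOMETRY: dict[str, EllipseROI] = {
    "heart": EllipseROI((28.0, 64.0), (9.0, 9.0)),
    "kidney_L": EllipseROI((60.0, 42.0), (12.0, 9.0)),
    "kidney_R": EllipseROI((60.0, 86.0), (12.0, 9.0)),
    "bkg_L": EllipseROI((88.0, 42.0), (12.0, 9.0)),
    "bkg_R": EllipseROI((88.0, 86.0), (12.0, 9.0)),
    "bladder": EllipseROI((110.0, 64.0), (8.0, 8.0)),
    "injection_site": EllipseROI((12.0, 12.0), (5.0, 5.0)),
    "body": EllipseROI((66.0, 64.0), (58.0, 44.0)),
}

_IMAGE_SHAPE = (128, 128)


@dataclass(frozen=True)
class FrameStack:
    """Multi-frame 2-D image stack with frame timing and named ROI masks."""

    frames: np.ndarray                 # (n_frames, H, W)
    times: np.ndarray                  # frame midpoints, s
    frame_duration: float
    masks: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticStudy:
    """One simulated study: ROI curves, ground truth and optional frames.

    ``curves`` carry the configured noise; ``clean_curves`` are the
    noise-free counterparts kept for rendering and for oracle tests.
    """

    config: SimulationConfig
    curves: dict[str, TimeActivityCurve]
    truth: SimulationTruth
    clean_curves: dict[str, TimeActivityCurve] = field(default_factory=dict)
    frames: FrameStack | None = None


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

def _decay_factor(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    if config.physical_decay_rate > 0:
        return np.exp(-config.physical_decay_rate * np.asarray(t, float))
    return np.ones_like(np.asarray(t, float))


def _apply_noise(values: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    """Poisson-sample per-frame counts and convert back to a rate."""
    if config.noise != "poisson":
        return values
    counts = rng.poisson(np.clip(values, 0, None) * config.frame_duration)
    return counts.astype(float) / config.frame_duration


def _kidney_clean(config: SimulationConfig, side: str) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free parenchymal retention R_k and cumulative uptake U_k.

    Evaluated by trapezoid convolution on an internal grid refined 10x
    relative to the frame grid, then sampled at frame midpoints.
    """
    idx = _SIDES[side]
    f_k = config.uptake_constants[idx]
    if f_k < 0:
        raise ValueError("uptake constant must be non-negative")
    t_min = config.min_transit_times[idx]
    w = config.washout_rates[idx]
    refine = 10
    dtf = config.frame_duration / refine
    n_fine = config.n_frames * refine
    tf = np.arange(n_fine + 1) * dtf
    pf = config.plasma_at(tf)
    hf = np.where(tf < t_min, 1.0, np.exp(-w * np.clip(tf - t_min, 0, None)))
    conv = fftconvolve(pf, hf)[: n_fine + 1] * dtf
    conv -= 0.5 * dtf * (pf[0] * hf + pf * hf[0])  # trapezoid end-weights
    conv = np.clip(conv, 0.0, None)
    mid = np.arange(config.n_frames) * refine + refine // 2
    r_k = f_k * conv[mid]
    u_k = f_k * cumulative_trapezoid(pf, dx=dtf, initial=0.0)[mid]
    return r_k, u_k


def _clean_curve_set(config: SimulationConfig) -> dict[str, np.ndarray]:
    t = config.times
    plasma = config.plasma_at(t)
    bkg = config.background_fraction * plasma
    r_l, u_l = _kidney_clean(config, "L")
    r_r, u_r = _kidney_clean(config, "R")
    residual = (
        config.injection_residual_fraction
        * config.injected_dose
        * np.exp(-config.residual_release_rate * t)
    )
    bladder = np.clip((u_l - r_l) + (u_r - r_r), 0.0, None)
    curves = {
        "kidney_L": r_l + bkg,
        "kidney_R": r_r + bkg,
        "bkg_L": bkg.copy(),
        "bkg_R": bkg.copy(),
        "heart": plasma,
        "whole_body": np.full_like(t, float(config.injected_dose)),
        "injection_site": residual,
        "bladder": bladder,
    }
    decay = _decay_factor(config, t)
    return {name: v * decay for name, v in curves.items()}


def _roi_pixel_counts() -> dict[str, int]:
    return {
        name: int(roi.mask(_IMAGE_SHAPE).sum())
        for name, roi in DEFAULT_GEOMETRY.items()
        if name != "body"
    }


_N_PIXELS = None


def _n_pixels(name: str) -> int | None:
    global _N_PIXELS
    if _N_PIXELS is None:
        _N_PIXELS = _roi_pixel_counts()
    return _N_PIXELS.get(name)


def _as_tac(config: SimulationConfig, values: np.ndarray, name: str) -> TimeActivityCurve:
    return TimeActivityCurve(
        times=config.times,
        values=values,
        frame_duration=config.frame_duration,
        roi_name=name,
        n_pixels=_n_pixels(name),
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_plasma(config: SimulationConfig, rng=None) -> TimeActivityCurve:
    """Plasma clearance curve ``P(t)`` at frame midpoints (cardiac ROI).

    Poisson noise is applied only when ``config.noise == 'poisson'``.
    """
    values = config.plasma_at(config.times) * _decay_factor(config, config.times)
    if config.noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        values = _apply_noise(values, config, rng)
    return _as_tac(config, values, "heart")


def simulate_kidney(config: SimulationConfig, side: str, rng=None) -> TimeActivityCurve:
    """Parenchymal kidney retention curve ``R_k(t)`` (background-free).

    For ``t < T_min_k`` the kidney is a pure integrator of plasma:
    ``R_k(t) = F_k int_0^t P``.
    """
    if side not in _SIDES:
        raise ValueError("side must be 'L' or 'R'")
    values, _ = _kidney_clean(config, side)
    values = values * _decay_factor(config, config.times)
    if config.noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        values = _apply_noise(values, config, rng)
    return _as_tac(config, values, f"kidney_{side}")


def ground_truth_fur(config: SimulationConfig) -> SimulationTruth:
    """Closed-form FUR/DRF labels: ``FUR_k = P(0) F_k / ID`` in %ID/min."""
    if config.injected_dose <= 0:
        raise ValueError("ground truth undefined for non-positive injected dose")
    p0 = float(sum(config.plasma_amplitudes))
    f_l, f_r = config.uptake_constants
    f_tot = f_l + f_r
    if f_tot <= 0:
        raise ValueError("ground truth DRF undefined when both uptake constants are zero")
    to_pct_per_min = 100.0 * 60.0
    fur = tuple(p0 * f / config.injected_dose * to_pct_per_min for f in (f_l, f_r))
    drf = (100.0 * f_l / f_tot, 100.0 * f_r / f_tot)
    return SimulationTruth(
        fur_total_true=fur[0] + fur[1],
        fur_per_kidney_true=fur,
        drf_true=drf,
        plasma_p0_true=p0,
        t_min_per_kidney=tuple(config.min_transit_times),
    )


def simulate_study(config: SimulationConfig, render: bool = False) -> SyntheticStudy:
    """Assemble the full named ROI curve set (plus frames if ``render``).

    With ``noise='none'`` and no physical decay the whole-body curve is a
    constant plateau (activity is conserved in the field of view).  Under a
    fixed seed the output is reproducible bit for bit; truth labels never
    depend on the noise setting.
    """
    clean_values = _clean_curve_set(config)
    rng = np.random.default_rng(config.seed)
    curves: dict[str, TimeActivityCurve] = {}
    clean: dict[str, TimeActivityCurve] = {}
    for name in sorted(clean_values):  # fixed order for reproducible noise
        clean[name] = _as_tac(config, clean_values[name], name)
        curves[name] = _as_tac(config, _apply_noise(clean_values[name], config, rng), name)
    study = SyntheticStudy(
        config=config, curves=curves, truth=ground_truth_fur(config), clean_curves=clean
    )
    if render:
        study = replace(study, frames=render_frames(study))
    return study


def render_frames(
    study: SyntheticStudy, geometry: dict[str, EllipseROI] | None = None
) -> FrameStack:
    """Distribute organ activity over elliptical masks on a 128x128 grid.

    Each organ's per-frame counts are spread uniformly over its mask; the
    residual whole-body activity (blood and soft tissue) fills the body
    ellipse outside the organ masks.  In Poisson mode each pixel is sampled
    independently, so mask sums retain Poisson counting statistics; with
    ``noise='none'`` mask sums reproduce the organ curves exactly.
    """
    geometry = dict(DEFAULT_GEOMETRY if geometry is None else geometry)
    body = geometry.pop("body", None)
    config = study.config
    masks = {name: roi.mask(_IMAGE_SHAPE) for name, roi in geometry.items()}
    stacked = np.zeros(_IMAGE_SHAPE, dtype=int)
    for m in masks.values():
        stacked += m.astype(int)
    if np.any(stacked > 1):
        raise ValueError("organ masks must not overlap")

    organ_names = [n for n in masks if n in study.clean_curves and n != "whole_body"]
    clean = {n: study.clean_curves[n].values for n in organ_names}
    total = study.clean_curves["whole_body"].values
    remainder = total - sum(clean.values())
    if np.min(remainder) < -1e-6 * config.injected_dose:
        raise ValueError("organ curves exceed the whole-body activity")
    remainder = np.clip(remainder, 0.0, None)
    if body is not None:
        rem_mask = body.mask(_IMAGE_SHAPE)
        for m in masks.values():
            rem_mask &= ~m
    else:
        rem_mask = ~(stacked > 0)

    n_frames, fd = config.n_frames, config.frame_duration
    frames = np.zeros((n_frames,) + _IMAGE_SHAPE, dtype=float)
    for name in organ_names:
        m = masks[name]
        frames[:, m] += (clean[name] * fd / m.sum())[:, None]
    frames[:, rem_mask] += (remainder * fd / max(rem_mask.sum(), 1))[:, None]
    if config.noise == "poisson":
        rng = np.random.default_rng((config.seed, 17))
        frames = rng.poisson(frames).astype(float)
    masks["whole_body"] = np.ones(_IMAGE_SHAPE, dtype=bool)
    return FrameStack(frames=frames, times=config.times, frame_duration=fd, masks=masks)
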