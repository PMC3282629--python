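"""Longitudinal cohort statistics for FUR/DRF follow-up studies.

Assembles per-animal results across timepoints (baseline, day 8, day 14
after unilateral ischemia), normalises follow-up values to percent of
baseline, and produces mean +/- SEM summary tables with two-sided paired
t-tests — the layout of a longitudinal renography study with the left
kidney as the non-ischemic control and the right as the injured side.
Also includes the repeat-analysis agreement report (Pearson r, mean and SD
of differences, paired t) used as a reproducibility QC, and a planted-effect
cohort simulator driving the full pipeline.

Percent-of-baseline has two inequivalent definitions, both computed:

* ``ratio_of_means`` (table default): 100 * mean(follow-up) / mean(baseline);
* ``mean_of_ratios``: mean over animals of 100 * follow-up / baseline.

No multiple-testing correction is applied; this is recorded in the table
metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import simdata
from .furcore import FURResult, analyze_study

__all__ = [
    "TIMEPOINTS",
    "StudySeries",
    "SummaryTable",
    "AgreementReport",
    "TTest",
    "percent_of_baseline",
    "paired_t",
    "summarize_study",
    "repeat_agreement",
    "simulate_cohort",
]

TIMEPOINTS = ("baseline", "day8", "day14")

#: Planted follow-up effects as (left, right) multiplicative factors on the
#: uptake constants: the non-ischemic left kidney retains most function, the
#: ischemic right kidney drops to 56% of baseline by day 8 and partially
#: recovers by day 14.
DEFAULT_EFFECTS: dict[str, tuple[float, float]] = {
    "day8": (0.79, 0.56),
    "day14": (0.86, 0.69),
}


@dataclass(frozen=True)
class StudySeries:
    """All timepoints of one animal."""

    animal_id: str
    timepoints: dict[str, FURResult]
    group: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.timepoints) - set(TIMEPOINTS)
        if unknown:
            raise ValueError(f"unknown timepoint labels: {sorted(unknown)}")


@dataclass(frozen=True)
class TTest:
    t: float
    df: int
    p: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SummaryTable:
    """Mean +/- SEM table across timepoints with p-value columns."""

    frame: pd.DataFrame
    alpha: float = 0.05
    percent_definition: str = "ratio_of_means"
    meta: dict = field(default_factory=lambda: {"multiple_testing": "none"})

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=True)

    def to_text(self) -> str:
        """Aligned text mirroring the FUR/DRF table layout."""
        lines = [
            f"{'':12s}{'Total':>8s}{'FUR_L':>14s}{'%base':>7s}"
            f"{'FUR_R':>14s}{'%base':>7s}{'P(L vs R)':>11s}",
        ]
        for tp, row in self.frame.iterrows():
            lines.append(
                f"{tp:12s}{row['fur_total_mean']:8.1f}"
                f"{row['fur_L_mean']:8.1f} ± {row['fur_L_sem']:3.1f}"
                f"{row['fur_L_pct_baseline']:7.0f}"
                f"{row['fur_R_mean']:8.1f} ± {row['fur_R_sem']:3.1f}"
                f"{row['fur_R_pct_baseline']:7.0f}"
                f"{_fmt_p(row['p_L_vs_R'], self.alpha):>11s}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between two analyses of the same kidneys."""

    r: float
    mean_diff: float
    sd_diff: float
    p_paired: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError("correlation out of range")


def _fmt_p(p: float, alpha: float) -> str:
    if not np.isfinite(p):
        return "n/a"
    if p < 0.01:
        return f"{p:.3g} **"
    if p < alpha:
        return f"{p:.3g} *"
    return "n.s."


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _fur_of(result: FURResult, kidney: str) -> float:
    return result.fur_left if kidney == "L" else result.fur_right


def percent_of_baseline(series: StudySeries, kidney: str) -> dict[str, float]:
    """Per-animal percent of baseline: ``100 * value(t) / value(baseline)``."""
    if "baseline" not in series.timepoints:
        raise ValueError(f"animal {series.animal_id}: baseline timepoint missing")
    base = _fur_of(series.timepoints["baseline"], kidney)
    if base <= 0:
        raise ValueError(f"animal {series.animal_id}: non-positive baseline FUR")
    return {
        tp: 100.0 * _fur_of(res, kidney) / base for tp, res in series.timepoints.items()
    }


def paired_t(sample_a, sample_b) -> TTest:
    """Classical two-sided paired t-test (df = n - 1).

    Differences with zero variance make the statistic undefined; the result
    is flagged rather than raising.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return TTest(t=0.0, df=a.size - 1, p=1.0)
        return TTest(
            t=float("nan"), df=a.size - 1, p=float("nan"), flags=("zero_variance",)
        )
    res = stats.ttest_rel(a, b)
    return TTest(t=float(res.statistic), df=a.size - 1, p=float(res.pvalue))


def summarize_study(
    cohort: list[StudySeries],
    alpha: float = 0.05,
    percent_definition: str = "ratio_of_means",
) -> SummaryTable:
    """Mean +/- SEM per timepoint with percent-of-baseline and t-tests.

    Columns include, per kidney: mean, SEM, percent-of-baseline under both
    definitions; ``p_L_vs_R`` (paired t between left and right FUR at the
    timepoint) and ``p_vs_baseline_{L,R}`` (paired t against baseline within
    kidney).  Missing timepoints yield blank (NaN) cells.
    """
    if len(cohort) < 2:
        raise ValueError("cohort summary needs at least 2 animals")
    if percent_definition not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError("unknown percent-of-baseline definition")
    rows = {}
    base_mean = {}
    for tp in TIMEPOINTS:
        have = [s for s in cohort if tp in s.timepoints]
        if not have:
            continue
        row: dict[str, float] = {"n": len(have)}
        for kidney in ("L", "R"):
            vals = np.array([_fur_of(s.timepoints[tp], kidney) for s in have])
            drfs = np.array(
                [s.timepoints[tp].drf_consensus[0 if kidney == "L" else 1] for s in have]
            )
            row[f"fur_{kidney}_mean"] = vals.mean()
            row[f"fur_{kidney}_sem"] = (
                vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
            )
            row[f"drf_{kidney}_mean"] = drfs.mean()
            row[f"drf_{kidney}_sem"] = (
                drfs.std(ddof=1) / math.sqrt(len(drfs)) if len(drfs) > 1 else 0.0
            )
            if tp == "baseline":
                base_mean[kidney] = vals.mean()
        row["fur_total_mean"] = row["fur_L_mean"] + row["fur_R_mean"]
        # percent of baseline, both definitions
        for kidney in ("L", "R"):
            paired = [
                s for s in have if "baseline" in s.timepoints
            ]
            if tp == "baseline":
                rom = mor = 100.0
            elif paired and base_mean.get(kidney):
                follow = np.array([_fur_of(s.timepoints[tp], kidney) for s in paired])
                base = np.array(
                    [_fur_of(s.timepoints["baseline"], kidney) for s in paired]
                )
                rom = 100.0 * follow.mean() / base.mean()
                mor = float(np.mean(100.0 * follow / base))
            else:
                rom = mor = float("nan")
            row[f"fur_{kidney}_pct_baseline_ratio_of_means"] = rom
            row[f"fur_{kidney}_pct_baseline_mean_of_ratios"] = mor
            row[f"fur_{kidney}_pct_baseline"] = (
                rom if percent_definition == "ratio_of_means" else mor
            )
        # paired t: L vs R at this timepoint
        l_vals = np.array([_fur_of(s.timepoints[tp], "L") for s in have])
        r_vals = np.array([_fur_of(s.timepoints[tp], "R") for s in have])
        row["p_L_vs_R"] = paired_t(l_vals, r_vals).p if len(have) >= 2 else float("nan")
        # paired t vs baseline within kidney
        for kidney in ("L", "R"):
            both = [s for s in have if "baseline" in s.timepoints]
            if tp != "baseline" and len(both) >= 2:
                fa = np.array([_fur_of(s.timepoints[tp], kidney) for s in both])
                fb = np.array([_fur_of(s.timepoints["baseline"], kidney) for s in both])
                row[f"p_vs_baseline_{kidney}"] = paired_t(fa, fb).p
            else:
                row[f"p_vs_baseline_{kidney}"] = float("nan")
        rows[tp] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "timepoint"
    return SummaryTable(frame=frame, alpha=alpha, percent_definition=percent_definition)


def repeat_agreement(values_a, values_b) -> AgreementReport:
    """Agreement of repeated FUR analyses: Pearson r, difference stats, paired t."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("repeat agreement needs two equal 1-D samples of length >= 3")
    flags: list[str] = []
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
        flags.append("constant_input")
    else:
        r = float(stats.pearsonr(a, b).statistic)
    d = a - b
    sd = float(np.std(d, ddof=1))
    tt = paired_t(a, b)
    flags.extend(tt.flags)
    return AgreementReport(
        r=r, mean_diff=float(d.mean()), sd_diff=sd, p_paired=tt.p, flags=tuple(flags)
    )


# ---------------------------------------------------------------------------
# planted-effect cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_animals: int = 8,
    seed: int = 0,
    base_config: simdata.SimulationConfig | None = None,
    effects: dict[str, tuple[float, float]] | None = None,
    animal_cv: float = 0.10,
    noise: str = "poisson",
) -> list[StudySeries]:
    """Simulate and analyse a longitudinal cohort with planted effects.

    Each animal draws per-kidney baseline uptake constants as the base
    config's values jittered by a lognormal factor of coefficient of
    variation ``animal_cv``; follow-up timepoints scale them by the planted
    (left, right) ``effects`` factors.  Every study is run through the full
    analysis pipeline, so recovered effects include all estimation error.
    """
    if n_animals < 2:
        raise ValueError("cohort needs at least 2 animals")
    base = base_config or simdata.SimulationConfig()
    effects = DEFAULT_EFFECTS if effects is None else effects
    master = np.random.default_rng(seed)
    cohort: list[StudySeries] = []
    for a in range(n_animals):
        jitter = np.exp(master.normal(0.0, animal_cv, size=2))
        f_base = tuple(f * j for f, j in zip(base.uptake_constants, jitter))
        timepoints: dict[str, FURResult] = {}
        for tp in TIMEPOINTS:
            if tp == "baseline":
                factors = (1.0, 1.0)
            elif tp in effects:
                factors = effects[tp]
            else:
                continue
            cfg = replace(
                base,
                uptake_constants=tuple(f * c for f, c in zip(f_base, factors)),
                noise=noise,
                seed=int(master.integers(2**31)),
            )
            study = simdata.simulate_study(cfg)
            timepoints[tp] = analyze_study(study.curves)
        cohort.append(StudySeries(animal_id=f"m{a:02d}", timepoints=timepoints))
    return cohort
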