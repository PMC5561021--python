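"""PCR amplification-efficiency estimation.

Two conventions coexist and are both exposed:

* per-well efficiency from a raw fluorescence curve: a constant baseline is
  removed, a window-of-linearity is located in the exponential phase, and
  ``E = 10**slope`` of the regression of log10(fluorescence) on cycle — the
  approach popularised by curve-fitting tools that work on non-baseline-
  corrected data;
* dilution-series efficiency from a standard curve: ``E = 10**(-1/slope)``
  of the regression of Cq on log10(template dilution).

A perfect reaction doubles product every cycle (E = 2); published quality
conventions treat 1.8 <= mean E <= 2.0 and a regression correlation
r >= 0.995 as ideal, and estimates outside those bands are flagged, not
discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    InsufficientDataError,
    InvalidDilutionSeriesError,
    NoAmplificationError,
    RejectedWellError,
    ValidationError,
)

logger = logging.getLogger(__name__)

IDEAL_E_RANGE = (1.8, 2.0)
IDEAL_MIN_R = 0.995


@dataclass
class AmplificationCurve:
    """A single well's fluorescence-vs-cycle trace (non-baseline-corrected).

    ``baseline`` records how much constant background has already been
    subtracted (0 for raw instrument data).
    """

    well_id: str
    gene_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.shape != self.fluorescence.shape:
            raise ValidationError("cycles and fluorescence differ in length")
        if len(self.cycles) < 10:
            raise ValidationError("curve needs at least 10 cycles")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValidationError("cycles must be strictly increasing")


@dataclass
class WellEfficiency:
    well_id: str
    gene_id: str
    efficiency: float
    slope: float          # log10 fluorescence per cycle
    r: float              # regression correlation coefficient
    window: tuple[int, int]


@dataclass
class EfficiencyEstimate:
    """Per-amplicon efficiency: mean and SD over accepted wells."""

    gene_id: str
    per_well: list[WellEfficiency]
    mean_e: float
    sd_e: float
    r: float                       # mean per-well regression r
    slope: float                   # mean per-well slope
    window: tuple[int, int]        # envelope of per-well windows
    outlier_wells: list[str] = field(default_factory=list)
    quality_flag: bool = False
    quality_reasons: list[str] = field(default_factory=list)

    @property
    def per_well_e(self) -> list[float]:
        return [w.efficiency for w in self.per_well]


def _window_r2(log_f: np.ndarray, cyc: np.ndarray) -> tuple[float, float, float]:
    """Slope, r and R^2 of log10(F) on cycle; assumes >=2 points.

    Closed-form least squares: this runs inside the baseline optimiser's
    inner loop, where scipy.stats.linregress overhead dominates.
    """
    x = cyc - cyc.mean()
    y = log_f - log_f.mean()
    sxx = float(x @ x)
    syy = float(y @ y)
    sxy = float(x @ y)
    slope = sxy / sxx
    if syy <= 0.0:
        return slope, 0.0, 0.0  # flat window: not an exponential phase
    r = sxy / math.sqrt(sxx * syy)
    return slope, r, r * r


def _candidate_windows(
    curve: AmplificationCurve,
    min_len: int,
    max_len: int,
    plateau_fraction: float,
) -> list[tuple[float, int, int, float, float]]:
    """All eligible windows as (r2, start_idx, length, slope, r)."""
    f = curve.fluorescence
    eligible = (f > 0) & (f < plateau_fraction * np.nanmax(f))
    n = len(f)
    out = []
    for start in range(n):
        for length in range(max_len, min_len - 1, -1):
            stop = start + length
            if stop > n or not eligible[start:stop].all():
                continue
            cyc = curve.cycles[start:stop]
            logf = np.log10(f[start:stop])
            slope, r, r2 = _window_r2(logf, cyc)
            out.append((r2, start, length, slope, r))
    return out


def window_of_linearity(
    curve: AmplificationCurve,
    min_len: int = 4,
    max_len: int = 6,
    plateau_fraction: float = 0.8,
) -> tuple[int, int]:
    """Locate the most log-linear exponential-phase window.

    Scans every contiguous run of ``min_len``..``max_len`` cycles whose
    fluorescence is strictly positive and below ``plateau_fraction`` of the
    curve maximum, and returns the (first cycle, last cycle) pair maximising
    the R^2 of log10(F) vs cycle.  Ties go to the earlier window, then to
    the longer one.
    """
    cands = _candidate_windows(curve, min_len, max_len, plateau_fraction)
    if not cands:
        raise NoAmplificationError(
            f"well {curve.well_id}: fewer than {min_len} eligible exponential-"
            "phase points"
        )
    best = None
    for r2, start, length, slope, r in cands:
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, start, length)
        # candidates arrive ordered by (start asc, length desc): within a
        # tie the earliest/longest already holds, so ties never replace.
    _, start, length = best
    return int(curve.cycles[start]), int(curve.cycles[start + length - 1])


def baseline_correct(
    curve: AmplificationCurve,
    max_iterations: int = 60,
    min_fold: float = 5.0,
    min_len: int = 4,
    max_len: int = 6,
    plateau_fraction: float = 0.8,
) -> AmplificationCurve:
    """Remove a constant background fluorescence from a raw curve.

    The baseline is the constant ``b`` in ``[0, min early-cycle F]`` that
    maximises the best window R^2 of log10(F - b) vs cycle — i.e. the
    subtraction that makes the exponential phase maximally log-linear.  The
    search is a coarse grid of ``max_iterations`` points refined by bounded
    Brent minimisation.

    Raises
    ------
    NoAmplificationError
        if the curve never rises ``min_fold``-fold above its early-cycle
        median (flat / failed reaction).
    """
    f = curve.fluorescence
    early = float(np.median(f[:5]))
    rise = np.nanmax(f) / max(early, np.finfo(float).tiny)
    if rise < min_fold:
        raise NoAmplificationError(
            f"well {curve.well_id}: max/early-median fluorescence ratio "
            f"{rise:.2f} < {min_fold} (no amplification)"
        )

    ub = float(np.min(f[:10]))
    if ub <= 0:
        return replace(curve, baseline=curve.baseline)

    # The search evaluates log-linearity over windows *longer* than the
    # final window-of-linearity: a residual baseline can cancel plateau
    # curvature over 4-6 points and look spuriously linear, but not over a
    # span of several extra cycles.
    search_len = max_len + 4

    def objective(b: float) -> float:
        cands = _candidate_windows(
            replace(curve, fluorescence=f - b),
            min_len, search_len, plateau_fraction,
        )
        if not cands:
            return 1.0
        longest = max(c[2] for c in cands)
        return 1.0 - max(c[0] for c in cands if c[2] == longest)

    grid = np.linspace(0.0, ub * (1 - 1e-9), max(max_iterations, 8))
    scores = [objective(b) for b in grid]
    i = int(np.argmin(scores))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    b = float(res.x) if res.fun <= min(scores) + 1e-15 else float(grid[i])

    # Polish: the max-over-windows objective goes flat once 1 - R^2 of the
    # best window reaches machine precision.  Re-optimising the baseline on
    # the *selected* window alone (fixed, so the objective stays sharp)
    # recovers several more digits; iterate because the selected window can
    # move after the baseline improves.
    h = max(float(grid[1] - grid[0]), 1e-12) if len(grid) > 1 else 1e-12
    prev_window = None
    for _ in range(5):
        cands = _candidate_windows(
            replace(curve, fluorescence=f - b), min_len, max_len, plateau_fraction,
        )
        if not cands:
            break
        best = None
        for r2, start, length, slope, r in cands:
            if best is None or r2 > best[0] + 1e-12:
                best = (r2, start, length)
        _, start, length = best
        if (start, length) == prev_window:
            break
        prev_window = (start, length)
        cyc = curve.cycles[start:start + length]
        fwin = f[start:start + length]

        def fixed_window_objective(bb: float) -> float:
            fv = fwin - bb
            if np.any(fv <= 0):
                return 1.0
            _, _, r2 = _window_r2(np.log10(fv), cyc)
            return 1.0 - r2

        # xatol must resolve baseline shifts small relative to the window's
        # faintest point, else wells with very low early fluorescence keep a
        # visible slope bias.
        xatol = max(float(np.min(fwin)) * 1e-9, 1e-18)
        res2 = optimize.minimize_scalar(
            fixed_window_objective,
            bounds=(max(0.0, b - h), min(ub, b + h)),
            method="bounded", options={"xatol": xatol, "maxiter": 1000},
        )
        if res2.fun <= fixed_window_objective(b):
            b = float(res2.x)

    corrected = f - b
    return replace(curve, fluorescence=corrected, baseline=curve.baseline + b)


def well_efficiency(
    curve: AmplificationCurve,
    window: tuple[int, int],
) -> WellEfficiency:
    """Efficiency of one reaction: ``E = 10**slope`` over the given window."""
    lo, hi = window
    mask = (curve.cycles >= lo) & (curve.cycles <= hi)
    f = curve.fluorescence[mask]
    if len(f) < 2 or np.any(f <= 0):
        raise ValidationError(f"window {window} invalid for well {curve.well_id}")
    slope, r, _ = _window_r2(np.log10(f), curve.cycles[mask])
    if slope <= 0:
        raise RejectedWellError(
            f"well {curve.well_id}: non-positive log-slope {slope:.4f}"
        )
    return WellEfficiency(curve.well_id, curve.gene_id,
                          10.0 ** slope, slope, r, (lo, hi))


def amplicon_efficiency(
    wells: Iterable[AmplificationCurve],
    gene_id: str | None = None,
    e_range: tuple[float, float] = (1.5, 2.3),
    exclude_outliers: bool = False,
    min_len: int = 4,
    max_len: int = 6,
    plateau_fraction: float = 0.8,
) -> EfficiencyEstimate:
    """Per-amplicon efficiency: baseline-correct, window and regress each well.

    Wells with no amplification or a rejected regression are skipped with a
    log message.  Wells whose E falls outside ``e_range`` are flagged as
    outliers and, unless ``exclude_outliers``, still contribute to the mean.
    The quality flag is raised when the mean E leaves the ideal [1.8, 2.0]
    band or the mean regression r drops below 0.995.
    """
    wells = list(wells)
    if gene_id is None:
        if not wells:
            raise InsufficientDataError("no wells supplied")
        gene_id = wells[0].gene_id
    per_well: list[WellEfficiency] = []
    for curve in wells:
        try:
            corrected = baseline_correct(
                curve, min_len=min_len, max_len=max_len,
                plateau_fraction=plateau_fraction,
            )
            win = window_of_linearity(corrected, min_len, max_len, plateau_fraction)
            per_well.append(well_efficiency(corrected, win))
        except (NoAmplificationError, RejectedWellError) as exc:
            logger.warning("excluding well %s: %s", curve.well_id, exc)
    outliers = [
        w.well_id for w in per_well
        if not (e_range[0] <= w.efficiency <= e_range[1])
    ]
    used = per_well
    if exclude_outliers:
        used = [w for w in per_well if w.well_id not in outliers]
    if len(used) < 2:
        raise InsufficientDataError(
            f"amplicon {gene_id}: {len(used)} accepted wells (need >= 2)"
        )
    e = np.array([w.efficiency for w in used])
    mean_e = float(e.mean())
    sd_e = float(e.std(ddof=1))
    mean_r = float(np.mean([w.r for w in used]))
    reasons = []
    if not (IDEAL_E_RANGE[0] <= mean_e <= IDEAL_E_RANGE[1]):
        reasons.append(f"mean E {mean_e:.3f} outside ideal {IDEAL_E_RANGE}")
    if mean_r < IDEAL_MIN_R:
        reasons.append(f"mean r {mean_r:.4f} < {IDEAL_MIN_R}")
    window = (min(w.window[0] for w in used), max(w.window[1] for w in used))
    return EfficiencyEstimate(
        gene_id=gene_id,
        per_well=per_well,
        mean_e=mean_e,
        sd_e=sd_e,
        r=mean_r,
        slope=float(np.mean([w.slope for w in used])),
        window=window,
        outlier_wells=outliers,
        quality_flag=bool(reasons),
        quality_reasons=reasons,
    )


@dataclass(frozen=True)
class StandardCurveResult:
    efficiency: float
    slope: float        # Cq per log10(dilution)
    r_squared: float


def standard_curve_efficiency(
    cq: Sequence[float],
    log10_dilution: Sequence[float],
) -> StandardCurveResult:
    """Dilution-series efficiency ``E = 10**(-1/slope)``.

    ``slope`` is the least-squares slope of Cq on log10(relative template
    amount); a perfect doubling reaction gives slope -3.3219 and E = 2.
    """
    cq = np.asarray(cq, dtype=float)
    x = np.asarray(log10_dilution, dtype=float)
    if len(cq) < 3:
        raise InsufficientDataError("standard curve needs >= 3 dilution points")
    res = stats.linregress(x, cq)
    if res.slope >= 0:
        raise InvalidDilutionSeriesError(
            f"Cq does not decrease with template amount (slope {res.slope:.3f})"
        )
    return StandardCurveResult(10.0 ** (-1.0 / res.slope),
                               float(res.slope), float(res.rvalue ** 2))
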