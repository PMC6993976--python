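"""Patlak multiple-time regression kinetics for blood-brain barrier tracers.

The quantitative core: log10-linear serum clearance, the exposure-time
transform that corrects brain uptake for clearance of tracer from blood,
brain/serum ratios with vascular-space correction by a co-injected albumin
marker, and the Patlak regression yielding the unidirectional influx
constant Ki (slope) and reversible vascular binding Vi (intercept).

Model
-----
With serum tracer concentration Cp(t) and brain radioactivity Am (cpm/g),
irreversible uptake linearises as::

    Am(t)/Cp(t) = Ki * Expt(t) + Vi,   Expt(t) = int_0^t Cp dtau / Cp(t)

For mono-exponential serum decay Cp = C0 exp(-k t) the exposure time has
the closed form (exp(k t) - 1)/k, which reduces to t as k -> 0 (constant
serum).  The brain/serum ratio of a non-penetrating vascular marker
estimates vascular space Vv and is subtracted from the tracer ratio before
regression ("delta B/S").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import AnimalRecord, RegionMeasurement, StudyDataset
from .regions import DEFAULT_WHOLE_BRAIN_EXCLUDE, WHOLE_BRAIN

logger = logging.getLogger(__name__)

#: Rounded log10(2) used to convert a log10-slope into a half-life.  Kept at
#: the printed three-digit value on the default (compatibility) path; pass
#: ``half_life_constant=math.log10(2)`` for the high-precision path.
LOG10_2_ROUNDED = 0.301

LN10 = math.log(10.0)


class FitError(ValueError):
    """Raised when a regression cannot be performed on the given points."""


# ---------------------------------------------------------------------------
# serum clearance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SerumDecayFit:
    """Log10-linear fit of serum tracer concentration over time.

    ``half_life = half_life_constant / |slope_log10|`` and
    ``k = -ln(10) * slope_log10``; with the rounded constant the product
    ``half_life * k`` equals ln 2 only to ~1e-3 relative.
    """

    slope_log10: float          # /min, expected < 0 for a cleared tracer
    intercept_log10: float      # log10(cpm/uL) at t = 0
    r_squared: float
    window: tuple[float, float]
    k: float                    # elimination rate, /min
    half_life: float            # min
    n_points: int
    half_life_constant: float = LOG10_2_ROUNDED

    def concentration(self, t: np.ndarray | float) -> np.ndarray | float:
        """Fitted Cp(t), cpm/uL (t=0 value is the back-extrapolated C0)."""
        return 10.0 ** (self.intercept_log10 + self.slope_log10 * np.asarray(t, float))


def _auto_trim_early(x: np.ndarray, y: np.ndarray, min_points: int = 4) -> int:
    """Drop earliest points while r-squared improves by > 0.01.

    Returns the start index into the time-sorted arrays.  This is the
    optional automatic "linear portion" rule; it is never applied silently.
    """
    start = 0
    res = sps.linregress(x, y)
    r2 = res.rvalue ** 2
    while len(x) - (start + 1) >= min_points:
        cand = sps.linregress(x[start + 1:], y[start + 1:])
        if cand.rvalue ** 2 > r2 + 0.01:
            start += 1
            r2 = cand.rvalue ** 2
        else:
            break
    return start


def fit_serum_decay(
    observations: Sequence[tuple[float, float]],
    window: tuple[float, float] | None = None,
    *,
    half_life_constant: float = LOG10_2_ROUNDED,
    auto_window: bool = False,
) -> SerumDecayFit:
    """Fit log10 serum concentration against time by ordinary least squares.

    Parameters
    ----------
    observations:
        (time min, concentration cpm/uL) pairs, one per animal.
    window:
        Optional (t_min, t_max) restricting the fit to the linear portion;
        default is the full observed range.
    half_life_constant:
        Constant converting 1/|slope| to a half-life (rounded log10(2) by
        default).
    auto_window:
        If True, drop earliest points while r-squared improves by more than
        0.01 (minimum 4 points kept); every drop is logged.

    Raises
    ------
    FitError
        Fewer than 3 usable points in the window.
    """
    arr = np.asarray(sorted(observations), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FitError("observations must be (time, concentration) pairs")
    if window is None:
        window = (float(arr[:, 0].min()), float(arr[:, 0].max()))
    in_win = (arr[:, 0] >= window[0]) & (arr[:, 0] <= window[1])
    arr = arr[in_win]
    positive = arr[:, 1] > 0
    if not positive.all():
        n_bad = int((~positive).sum())
        logger.warning(
            "fit_serum_decay: excluding %d non-positive concentration(s) "
            "at t=%s", n_bad, arr[~positive, 0].tolist(),
        )
        arr = arr[positive]
    if len(arr) < 3:
        raise FitError(
            f"need >= 3 usable observations for a serum decay fit, got {len(arr)}"
        )
    t, logc = arr[:, 0], np.log10(arr[:, 1])
    if np.ptp(t) == 0:
        raise FitError("all observation times identical; slope undefined")
    if auto_window:
        start = _auto_trim_early(t, logc)
        if start:
            logger.info(
                "fit_serum_decay: auto window dropped %d earliest point(s) "
                "(t < %.3g min)", start, t[start],
            )
            t, logc = t[start:], logc[start:]
            window = (float(t.min()), window[1])
    res = sps.linregress(t, logc)
    slope = float(res.slope)
    half_life = half_life_constant / abs(slope) if slope != 0 else math.inf
    return SerumDecayFit(
        slope_log10=slope,
        intercept_log10=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        window=window,
        k=-LN10 * slope,
        half_life=half_life,
        n_points=len(t),
        half_life_constant=half_life_constant,
    )


def half_life_from_log10_slope(
    slope_log10: float, half_life_constant: float = LOG10_2_ROUNDED
) -> float:
    """Half-life (min) from the slope of log10 concentration vs time."""
    if slope_log10 == 0:
        return math.inf
    return half_life_constant / abs(slope_log10)


# ---------------------------------------------------------------------------
# exposure time
# ---------------------------------------------------------------------------

def exposure_time(
    decay: SerumDecayFit | float,
    t: float,
    *,
    method: str = "analytic",
    n_grid: int = 4097,
) -> float:
    """Clearance-corrected exposure time int_0^t Cp dtau / Cp(t), in min.

    Parameters
    ----------
    decay:
        A ``SerumDecayFit`` or a bare elimination rate k (/min).  k may be
        zero (constant serum, Expt = t) or negative (rising curve).
    t:
        Terminal time, min; must be > 0.
    method:
        ``"analytic"`` uses the closed form (exp(k t) - 1)/k of the fitted
        mono-exponential.  ``"empirical"`` integrates the fitted curve by
        trapezoidal quadrature on an ``n_grid``-point grid with Cp(0)
        back-extrapolated from the fit.
    """
    if t <= 0:
        raise ValueError(f"terminal time must be > 0, got {t}")
    k = decay.k if isinstance(decay, SerumDecayFit) else float(decay)
    if method == "analytic":
        if k == 0.0:
            return float(t)
        return float(np.expm1(k * t) / k)
    if method == "empirical":
        if isinstance(decay, SerumDecayFit):
            grid = np.linspace(0.0, t, n_grid)
            conc = np.asarray(decay.concentration(grid), dtype=float)
        else:
            grid = np.linspace(0.0, t, n_grid)
            conc = np.exp(-k * grid)
        cp_t = conc[-1]
        if cp_t <= 0 or not np.all(conc > 0):
            raise ValueError("serum curve must be positive on (0, t]")
        return float(np.trapezoid(conc, grid) / cp_t)
    raise ValueError(f"unknown exposure-time method {method!r}")


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def brain_serum_ratio(
    tissue_cpm: float, tissue_weight_g: float, serum_cpm: float, aliquot_ul: float
) -> float:
    """Brain/serum ratio, uL/g: (cpm per g tissue) / (cpm per uL serum)."""
    if tissue_weight_g <= 0:
        raise ValueError("tissue weight must be > 0")
    if serum_cpm <= 0:
        raise ValueError("serum counts must be > 0 for a B/S ratio")
    if aliquot_ul <= 0:
        raise ValueError("aliquot volume must be > 0")
    if tissue_cpm < 0:
        raise ValueError("tissue counts must be >= 0")
    return (tissue_cpm / tissue_weight_g) / (serum_cpm / aliquot_ul)


def delta_bs(tracer_bs: float, marker_bs: float) -> float:
    """Vascular-space-corrected ratio: tracer B/S minus marker B/S, uL/g.

    Negative values are legitimate (early times, low-uptake regions) and are
    preserved.
    """
    if not (math.isfinite(tracer_bs) and math.isfinite(marker_bs)):
        raise ValueError("B/S ratios must be finite")
    return tracer_bs - marker_bs


# ---------------------------------------------------------------------------
# Patlak regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatlakPoint:
    """One animal's coordinate on the Patlak plot."""

    expt: float      # exposure time, min
    delta_bs: float  # vascular-corrected B/S, uL/g
    animal_id: str = ""


@dataclass(frozen=True)
class PatlakFit:
    """OLS fit of delta B/S against exposure time for one group x region.

    ``transport_significant`` requires a two-sided slope p-value below alpha
    *and* a positive slope; a significantly negative slope is an anomaly,
    not transport.  Where transport is non-significant ("ns") the intercept
    is non-measurable ("nm"): ``vi_measurable == transport_significant``.
    """

    ki: float
    ki_se: float
    vi: float
    vi_se: float
    r: float
    n: int
    p_slope: float
    transport_significant: bool
    alpha: float = 0.05
    window: tuple[float, float] | None = None

    @property
    def vi_measurable(self) -> bool:
        return self.transport_significant


def patlak_fit(
    points: Sequence[PatlakPoint],
    alpha: float = 0.05,
    window: tuple[float, float] | None = None,
    *,
    auto_window: bool = False,
) -> PatlakFit:
    """Fit the Patlak line: slope = Ki (uL/g-min), intercept = Vi (uL/g).

    Parameters
    ----------
    points:
        (Expt, delta B/S) coordinates, one per animal.
    alpha:
        Two-sided significance level for the slope test.
    window:
        Optional (min, max) exposure-time interval restricting the fit to
        the linear portion.
    auto_window:
        Optional early-point trimming rule (logged, off by default), as for
        :func:`fit_serum_decay`.

    Raises
    ------
    FitError
        Fewer than 3 points in the window, or all exposure times identical.
    """
    pts = sorted(points, key=lambda p: p.expt)
    if window is not None:
        pts = [p for p in pts if window[0] <= p.expt <= window[1]]
    if len(pts) < 3:
        raise FitError(f"need >= 3 Patlak points, got {len(pts)}")
    x = np.array([p.expt for p in pts], dtype=float)
    y = np.array([p.delta_bs for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise FitError("all exposure times identical; Patlak slope undefined")
    if auto_window:
        start = _auto_trim_early(x, y)
        if start:
            logger.info("patlak_fit: auto window dropped %d earliest point(s)", start)
            x, y = x[start:], y[start:]
    res = sps.linregress(x, y)
    significant = bool(res.pvalue < alpha and res.slope > 0)
    return PatlakFit(
        ki=float(res.slope),
        ki_se=float(res.stderr),
        vi=float(res.intercept),
        vi_se=float(res.intercept_stderr),
        r=float(res.rvalue),
        n=len(x),
        p_slope=float(res.pvalue),
        transport_significant=significant,
        alpha=alpha,
        window=window,
    )


# ---------------------------------------------------------------------------
# whole-brain aggregation
# ---------------------------------------------------------------------------

def aggregate_whole_brain(
    animal: AnimalRecord,
    exclude: Sequence[str] = DEFAULT_WHOLE_BRAIN_EXCLUDE,
) -> RegionMeasurement:
    """Sum weights and counts over non-excluded regions into "whole brain".

    The resulting B/S ratio equals the region-weight-weighted mean of the
    included regional B/S ratios.  By default the olfactory bulb is excluded.
    """
    excluded = set(exclude)
    kept = [m for m in animal.regions if m.region not in excluded]
    if not kept:
        raise ValueError(
            f"animal {animal.id}: no regions left after excluding {sorted(excluded)}"
        )
    return RegionMeasurement(
        region=WHOLE_BRAIN,
        weight_g=sum(m.weight_g for m in kept),
        tracer_cpm=sum(m.tracer_cpm for m in kept),
        marker_cpm=sum(m.marker_cpm for m in kept),
    )


# ---------------------------------------------------------------------------
# vascular space
# ---------------------------------------------------------------------------

@dataclass
class VascularSpaceSummary:
    """Marker (albumin) B/S collapsed across time, per group x region.

    Collapsing across time is only valid where the marker B/S shows no time
    trend (``time_trend_p >= 0.05``); each row carries that check.
    """

    table: pd.DataFrame
    alpha: float = 0.05


def vascular_space_summary(
    dataset: StudyDataset,
    group_by: Sequence[str] = ("genotype", "sex"),
    *,
    include_whole_brain: bool = True,
    alpha: float = 0.05,
) -> VascularSpaceSummary:
    """Summarise marker B/S (vascular space, uL/g) per group x region.

    Per cell: mean, standard error, n, and the p-value of an OLS regression
    of marker B/S on terminal time (the justification for collapsing across
    time).  Cells with fewer than 2 animals get an undefined SE and are
    flagged.
    """
    rows = []
    for a in dataset:
        regions = list(a.regions)
        if include_whole_brain:
            regions.append(aggregate_whole_brain(a))
        for m in regions:
            rows.append(
                {
                    "genotype": a.genotype,
                    "sex": a.sex,
                    "region": m.region,
                    "time_min": a.terminal_time_min,
                    "marker_bs": brain_serum_ratio(
                        m.marker_cpm, m.weight_g, a.serum_marker_cpm, a.aliquot_ul
                    ),
                }
            )
    df = pd.DataFrame(rows)
    out = []
    for keys, sub in df.groupby([*group_by, "region"], sort=False):
        vals = sub["marker_bs"].to_numpy()
        n = len(vals)
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
        if n >= 3 and np.ptp(sub["time_min"].to_numpy()) > 0:
            if np.ptp(vals) == 0:
                trend_p = 1.0  # exactly time-flat marker
            else:
                trend_p = float(sps.linregress(sub["time_min"], sub["marker_bs"]).pvalue)
        else:
            trend_p = math.nan
        out.append(
            {
                **dict(zip([*group_by, "region"], keys)),
                "mean": mean,
                "se": se,
                "n": n,
                "time_trend_p": trend_p,
                "collapse_valid": bool(trend_p >= alpha) if math.isfinite(trend_p) else False,
                "flagged": n < 2,
            }
        )
    return VascularSpaceSummary(table=pd.DataFrame(out), alpha=alpha)
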