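"""End-to-end analysis: study dataset -> kinetic results bundle.

Orchestrates the full terminal-sample Patlak workflow: eligibility
screening, per-group serum decay fits (clearance / half-life), exposure
times, brain/serum ratios with albumin vascular correction, whole-brain
aggregation, Patlak regressions per group x region, and the
collapsed-across-time vascular-space summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .datatypes import AnimalRecord, StudyDataset
from .kinetics import (
    FitError,
    PatlakFit,
    PatlakPoint,
    SerumDecayFit,
    VascularSpaceSummary,
    aggregate_whole_brain,
    brain_serum_ratio,
    delta_bs,
    exposure_time,
    fit_serum_decay,
    patlak_fit,
    vascular_space_summary,
    LOG10_2_ROUNDED,
)
from .regions import DEFAULT_WHOLE_BRAIN_EXCLUDE, WHOLE_BRAIN

logger = logging.getLogger(__name__)

SERUM_SCOPES = ("group", "sex", "pooled")
DOSE_CORRECTIONS = ("none", "marker")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable choices of the analysis pipeline.

    ``serum_fit_scope`` selects which animals share a serum decay curve for
    exposure-time computation: per genotype x sex group (default), per sex
    (genotypes collapsed), or one pooled curve.  ``dose_correction="marker"``
    divides each animal's tracer serum level by its albumin-marker serum
    level (both isotopes share the injected syringe, so per-animal dose
    variation cancels exactly); the fitted elimination rate is then shifted
    by the marker's own (near-zero) clearance.
    """

    alpha: float = 0.05
    serum_fit_scope: str = "group"
    serum_window: tuple[float, float] | None = None
    serum_auto_window: bool = False
    patlak_window: tuple[float, float] | None = None
    patlak_auto_window: bool = False
    expt_method: str = "analytic"
    dose_correction: str = "none"
    half_life_constant: float = LOG10_2_ROUNDED
    whole_brain_exclude: tuple[str, ...] = DEFAULT_WHOLE_BRAIN_EXCLUDE
    patlak_group_by: tuple[str, ...] = ("genotype", "sex")

    def validate(self) -> None:
        if self.serum_fit_scope not in SERUM_SCOPES:
            raise ValueError(f"serum_fit_scope must be one of {SERUM_SCOPES}")
        if self.dose_correction not in DOSE_CORRECTIONS:
            raise ValueError(f"dose_correction must be one of {DOSE_CORRECTIONS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.expt_method not in ("analytic", "empirical"):
            raise ValueError("expt_method must be 'analytic' or 'empirical'")


def _scope_key(animal: AnimalRecord, scope: str) -> tuple:
    if scope == "group":
        return (animal.genotype, animal.sex)
    if scope == "sex":
        return (animal.sex,)
    return ("all",)


def _patlak_key(animal: AnimalRecord, by: Sequence[str]) -> tuple:
    return tuple(getattr(animal, {"genotype": "genotype", "sex": "sex"}[b]) for b in by)


@dataclass
class ResultsBundle:
    """Everything the pipeline computes, in analysis-ready form."""

    analysis: AnalysisConfig
    serum_fits: dict[tuple, SerumDecayFit]
    patlak_points: pd.DataFrame
    patlak_fits: dict[tuple, PatlakFit | None]
    vascular: VascularSpaceSummary
    exclusions: list[dict]
    provenance: dict

    # -- tidy output tables ------------------------------------------------

    def clearance_table(self) -> pd.DataFrame:
        rows = []
        for key, f in self.serum_fits.items():
            rows.append(
                {
                    "serum_group": " ".join(key),
                    "slope_log10": f.slope_log10,
                    "intercept_log10": f.intercept_log10,
                    "r_squared": f.r_squared,
                    "k_per_min": f.k,
                    "half_life_min": f.half_life,
                    "n": f.n_points,
                }
            )
        return pd.DataFrame(rows)

    def _fit_rows(self) -> pd.DataFrame:
        by = self.analysis.patlak_group_by
        rows = []
        for key, f in self.patlak_fits.items():
            *grp, region = key
            row = dict(zip(by, grp))
            row["region"] = region
            if f is None:
                row.update(
                    ki=math.nan, ki_se=math.nan, vi=math.nan, vi_se=math.nan,
                    r=math.nan, n=0, p_slope=math.nan,
                    transport_significant=False, vi_measurable=False,
                )
            else:
                row.update(
                    ki=f.ki, ki_se=f.ki_se, vi=f.vi, vi_se=f.vi_se, r=f.r,
                    n=f.n, p_slope=f.p_slope,
                    transport_significant=f.transport_significant,
                    vi_measurable=f.vi_measurable,
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def whole_brain_pk_table(self) -> pd.DataFrame:
        df = self._fit_rows()
        return df[df["region"] == WHOLE_BRAIN].drop(columns="region").reset_index(drop=True)

    def regional_ki_table(self) -> pd.DataFrame:
        """Per-region influx table; non-significant transport displays "ns"."""
        df = self._fit_rows()
        df = df[df["region"] != WHOLE_BRAIN].copy()
        df["ki_display"] = [
            f"{ki:.3f}" if sig else "ns"
            for ki, sig in zip(df["ki"], df["transport_significant"])
        ]
        return df.reset_index(drop=True)

    def regional_vi_table(self) -> pd.DataFrame:
        """Per-region intercept table; non-measurable binding displays "nm"."""
        df = self._fit_rows()
        df = df[df["region"] != WHOLE_BRAIN].copy()
        df["vi_display"] = [
            f"{vi:.2f}" if ok else "nm"
            for vi, ok in zip(df["vi"], df["vi_measurable"])
        ]
        return df.reset_index(drop=True)

    def vascular_space_table(self) -> pd.DataFrame:
        return self.vascular.table.copy()

    def to_tables(self) -> dict[str, pd.DataFrame]:
        """All output tables keyed by their file stem."""
        return {
            "clearance": self.clearance_table(),
            "whole_brain_pk": self.whole_brain_pk_table(),
            "regional_ki": self.regional_ki_table(),
            "regional_vi": self.regional_vi_table(),
            "vascular_space": self.vascular_space_table(),
            "patlak_points": self.patlak_points.copy(),
        }


def run_pipeline(
    dataset: StudyDataset, analysis: AnalysisConfig | None = None
) -> ResultsBundle:
    """Run the complete kinetic analysis on a validated study dataset.

    Animals with a non-positive serum count for either isotope are excluded
    (and logged) before any fit.  Patlak fits that cannot be performed
    (fewer than 3 eligible animals in a cell) are recorded as ``None`` with
    a logged reason rather than aborting the whole run.  The bundle is a
    deterministic function of (dataset, analysis).
    """
    analysis = analysis or AnalysisConfig()
    analysis.validate()
    dataset.validate()

    exclusions: list[dict] = []
    eligible: list[AnimalRecord] = []
    for a in dataset:
        if a.serum_tracer_cpm <= 0 or a.serum_marker_cpm <= 0:
            reason = "non-positive serum count"
            exclusions.append({"animal_id": a.id, "reason": reason})
            logger.warning("excluding animal %s: %s", a.id, reason)
        else:
            eligible.append(a)
    if not eligible:
        raise FitError("no eligible animals after serum screening")
    screened = StudyDataset(animals=eligible, provenance=dataset.provenance)

    # serum decay fits per scope cell
    scope_obs: dict[tuple, list[tuple[float, float]]] = {}
    for a in eligible:
        conc = a.serum_tracer_conc
        if analysis.dose_correction == "marker":
            conc = conc / a.serum_marker_conc
        scope_obs.setdefault(_scope_key(a, analysis.serum_fit_scope), []).append(
            (a.terminal_time_min, conc)
        )
    # under marker correction the fitted quantity is the (dose-free)
    # tracer/marker serum ratio; only the slope feeds the exposure time,
    # so the absolute concentration scale is irrelevant
    serum_fits: dict[tuple, SerumDecayFit] = {}
    for key, obs in scope_obs.items():
        serum_fits[key] = fit_serum_decay(
            obs,
            analysis.serum_window,
            half_life_constant=analysis.half_life_constant,
            auto_window=analysis.serum_auto_window,
        )

    # per-animal exposure times and Patlak coordinates
    point_rows = []
    for a in eligible:
        fit = serum_fits[_scope_key(a, analysis.serum_fit_scope)]
        expt = exposure_time(fit, a.terminal_time_min, method=analysis.expt_method)
        regions = list(a.regions) + [
            aggregate_whole_brain(a, analysis.whole_brain_exclude)
        ]
        for m in regions:
            tracer_bs = brain_serum_ratio(
                m.tracer_cpm, m.weight_g, a.serum_tracer_cpm, a.aliquot_ul
            )
            marker_bs = brain_serum_ratio(
                m.marker_cpm, m.weight_g, a.serum_marker_cpm, a.aliquot_ul
            )
            point_rows.append(
                {
                    "animal_id": a.id,
                    "genotype": a.genotype,
                    "sex": a.sex,
                    "region": m.region,
                    "time_min": a.terminal_time_min,
                    "expt": expt,
                    "tracer_bs": tracer_bs,
                    "marker_bs": marker_bs,
                    "delta_bs": delta_bs(tracer_bs, marker_bs),
                }
            )
    points = pd.DataFrame(point_rows)

    # Patlak fits per group x region (dissected + whole brain)
    patlak_fits: dict[tuple, PatlakFit | None] = {}
    region_order = [m.region for m in eligible[0].regions] + [WHOLE_BRAIN]
    group_keys: list[tuple] = []
    for a in eligible:
        gk = _patlak_key(a, analysis.patlak_group_by)
        if gk not in group_keys:
            group_keys.append(gk)
    for gk in group_keys:
        mask = np.ones(len(points), dtype=bool)
        for col, val in zip(analysis.patlak_group_by, gk):
            mask &= (points[col] == val).to_numpy()
        for region in region_order:
            sub = points[mask & (points["region"] == region).to_numpy()]
            pts = [
                PatlakPoint(expt=r.expt, delta_bs=r.delta_bs, animal_id=r.animal_id)
                for r in sub.itertuples()
            ]
            key = (*gk, region)
            try:
                patlak_fits[key] = patlak_fit(
                    pts,
                    alpha=analysis.alpha,
                    window=analysis.patlak_window,
                    auto_window=analysis.patlak_auto_window,
                )
            except FitError as e:
                logger.warning("patlak fit skipped for %s: %s", key, e)
                patlak_fits[key] = None

    vascular = vascular_space_summary(screened, alpha=analysis.alpha)

    return ResultsBundle(
        analysis=analysis,
        serum_fits=serum_fits,
        patlak_points=points,
        patlak_fits=patlak_fits,
        vascular=vascular,
        exclusions=exclusions,
        provenance={
            **dataset.provenance,
            "bbbpk_version": _version,
            "n_animals": len(dataset),
            "n_eligible": len(eligible),
        },
    )
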