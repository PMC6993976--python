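"""Optional figures: Patlak regressions and serum clearance curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def patlak_figure(points: pd.DataFrame, region: str, group_by=("genotype", "sex")):
    """Delta B/S vs exposure time with per-group OLS lines for one region."""
    sub = points[points["region"] == region]
    fig, ax = plt.subplots(figsize=(5, 4))
    for key, grp in sub.groupby(list(group_by), sort=False):
        label = " ".join(map(str, key if isinstance(key, tuple) else (key,)))
        x, y = grp["expt"].to_numpy(), grp["delta_bs"].to_numpy()
        (line,) = ax.plot(x, y, "o", label=label, ms=4)
        if len(x) >= 3 and np.ptp(x) > 0:
            coef = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, np.polyval(coef, xs), "-", color=line.get_color(), lw=1)
    ax.set_xlabel("exposure time (min)")
    ax.set_ylabel("delta B/S (uL/g)")
    ax.set_title(region)
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def serum_figure(serum_points: pd.DataFrame):
    """log10 serum tracer concentration against time, per sex."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for sex, grp in serum_points.groupby("sex", sort=False):
        ax.plot(grp["time_min"], grp["log10_conc"], "o", label=f"sex {sex}", ms=4)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("log10 serum tracer (cpm/uL)")
    ax.legend()
    fig.tight_layout()
    return fig


def save_figures(points: pd.DataFrame, outdir: str | Path,
                 serum_points: pd.DataFrame | None = None) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for region in points["region"].unique():
        fig = patlak_figure(points, region)
        p = outdir / f"patlak_{region.replace('/', '-').replace(' ', '_')}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    if serum_points is not None:
        fig = serum_figure(serum_points)
        p = outdir / "serum_clearance.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
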