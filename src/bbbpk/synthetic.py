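"""Synthetic dual-tracer terminal-sample study generator.

Emulates the study design the analysis assumes: a 2x2 genotype x sex layout
(apoE3/apoE4 targeted-replacement mice, both sexes), n mice per group, a
single terminal blood + brain sample per animal at 0.5-10 min after
intravenous co-injection of an iodinated test tracer (~1e6 cpm) and a
technetium-albumin vascular marker (~5e5 cpm), 50 uL serum aliquots, and
eleven dissected brain regions.

The forward model is the one the Patlak analysis inverts: mono-exponential
serum decay Cp(t) = C0 exp(-k t) per compartment, brain tracer per gram
Am(t) = Ki * int_0^t Cp dtau + (Vi + Vv) * Cp(t), and brain marker per gram
Vv * Cp_marker(t).  With the noise model off the generated dataset inverts
exactly; with Poisson counting noise it reproduces gamma-counter statistics.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import AnimalRecord, RegionMeasurement, StudyDataset
from .regions import CANONICAL_REGIONS, GROUPS, WHOLE_BRAIN

NOISE_MODELS = ("none", "poisson_counts", "lognormal_cv")

#: Assumed circulating blood volume of a 25-30 g mouse, uL.  The absolute
#: serum cpm scale is not observable from the analysis (it cancels in B/S
#: ratios); this declared assumption only sets realistic count magnitudes.
DEFAULT_BLOOD_VOLUME_UL = 1500.0

DEFAULT_INJECTED_TRACER_CPM = 1.0e6
DEFAULT_INJECTED_MARKER_CPM = 5.0e5

#: (mean g, sd g) per dissected region; sums to ~0.45 g, a typical adult
#: mouse brain.  SDs are ~10% of the mean.
DEFAULT_REGION_WEIGHTS: dict[str, tuple[float, float]] = {
    "olfactory bulb": (0.025, 0.0025),
    "striatum": (0.025, 0.0025),
    "frontal cortex": (0.050, 0.0050),
    "hypothalamus": (0.014, 0.0015),
    "hippocampus": (0.032, 0.0030),
    "thalamus": (0.025, 0.0025),
    "parietal cortex": (0.050, 0.0050),
    "occipital cortex": (0.030, 0.0030),
    "cerebellum": (0.058, 0.0055),
    "midbrain": (0.042, 0.0040),
    "pons/medulla": (0.070, 0.0065),
}

#: Serum elimination rates (/min).  Females clear iodinated insulin over
#: twice as fast as males; genotypes do not differ.
DEFAULT_K_CLEAR: dict[tuple[str, str], float] = {
    ("E3", "F"): 0.23,
    ("E3", "M"): 0.10,
    ("E4", "F"): 0.23,
    ("E4", "M"): 0.10,
}

Group = tuple[str, str]
TruthKey = tuple[str, str, str]  # (genotype, sex, region)

# Reference group-level estimates used to seed the default ground truth,
# in table column order (E3 F, E3 M, E4 F, E4 M).  Zeros mark cells where
# transport was non-significant (Ki) / the intercept non-measurable (Vi).
_VV_TABLE: dict[str, tuple[float, float, float, float]] = {
    WHOLE_BRAIN: (6.75, 6.87, 6.67, 6.95),
    "olfactory bulb": (10.63, 11.37, 10.71, 12.23),
    "striatum": (4.49, 4.42, 4.10, 5.40),
    "frontal cortex": (5.41, 5.62, 5.21, 5.48),
    "hypothalamus": (5.79, 6.18, 6.48, 5.05),
    "hippocampus": (6.72, 6.10, 6.14, 6.22),
    "thalamus": (4.46, 5.19, 5.67, 5.55),
    "parietal cortex": (6.22, 5.78, 6.31, 6.68),
    "occipital cortex": (7.51, 7.16, 6.74, 6.51),
    "cerebellum": (8.66, 9.36, 8.49, 9.64),
    "midbrain": (7.09, 6.30, 6.75, 6.81),
    "pons/medulla": (10.99, 10.67, 10.20, 10.92),
}

_KI_TABLE: dict[str, tuple[float, float, float, float]] = {
    WHOLE_BRAIN: (1.128, 0.820, 1.033, 0.781),
    "olfactory bulb": (2.178, 1.607, 1.530, 1.712),
    "striatum": (0.0, 0.0, 0.0, 0.0),
    "frontal cortex": (0.796, 0.895, 0.720, 1.023),
    "hypothalamus": (1.541, 1.425, 1.116, 2.272),
    "hippocampus": (0.0, 1.813, 1.171, 0.0),
    "thalamus": (0.752, 0.0, 0.634, 1.203),
    "parietal cortex": (0.550, 0.961, 0.859, 0.920),
    "occipital cortex": (0.742, 0.826, 0.811, 0.793),
    "cerebellum": (1.189, 1.159, 2.110, 0.0),
    "midbrain": (0.689, 1.244, 0.699, 0.887),
    "pons/medulla": (1.462, 0.739, 1.111, 0.0),
}

_VI_TABLE: dict[str, tuple[float, float, float, float]] = {
    WHOLE_BRAIN: (4.41, 7.17, 7.17, 8.23),
    "olfactory bulb": (6.67, 11.89, 11.71, 13.31),
    "striatum": (0.0, 0.0, 0.0, 0.0),
    "frontal cortex": (4.65, 5.61, 7.79, 5.90),
    "hypothalamus": (-2.91, 8.45, 4.88, 5.63),
    "hippocampus": (0.0, 11.37, 10.01, 0.0),
    "thalamus": (4.04, 0.0, 7.60, 4.56),
    "parietal cortex": (4.50, 4.17, 3.31, 4.74),
    "occipital cortex": (6.73, 5.50, 6.53, 6.71),
    "cerebellum": (8.36, 8.90, 8.91, 0.0),
    "midbrain": (4.41, 4.81, 5.93, 6.38),
    "pons/medulla": (3.90, 7.70, 8.76, 0.0),
}

_TABLE_GROUP_ORDER: tuple[Group, ...] = (("E3", "F"), ("E3", "M"), ("E4", "F"), ("E4", "M"))


@dataclass
class SimulationConfig:
    """Ground truth and design schedule for a simulated study.

    Truth maps are keyed ``(genotype, sex, region)``.  Entries for the
    ``"whole brain"`` pseudo-region are reference values only: the simulator
    generates dissected regions and whole brain is derived downstream, so
    the recoverable whole-brain truth is :meth:`whole_brain_truth`.
    """

    groups: tuple[Group, ...] = GROUPS
    n_per_group: int = 10
    time_schedule: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.linspace(0.5, 10.0, 10))
    )
    c0_tracer: float = DEFAULT_INJECTED_TRACER_CPM / DEFAULT_BLOOD_VOLUME_UL
    c0_marker: float = DEFAULT_INJECTED_MARKER_CPM / DEFAULT_BLOOD_VOLUME_UL
    k_clear_tracer: dict[Group, float] = field(
        default_factory=lambda: dict(DEFAULT_K_CLEAR)
    )
    k_clear_marker: float = 0.005
    ki_true: dict[TruthKey, float] = field(default_factory=dict)
    vi_true: dict[TruthKey, float] = field(default_factory=dict)
    vv_true: dict[TruthKey, float] = field(default_factory=dict)
    region_weights: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    aliquot_volume: float = 50.0
    noise_model: str = "none"
    noise_cv: float = 0.1
    #: Per-animal injected-dose variability (lognormal sigma); multiplies
    #: serum and brain signals of both isotopes alike, so it cancels in
    #: every B/S ratio.
    dose_cv: float = 0.0
    #: Optional fast early distribution phase (fraction, rate /min) giving a
    #: bi-exponential tracer serum curve; off (None) by default.
    tracer_fast_phase: tuple[float, float] | None = None
    seed: int = 0

    # -- accessors ---------------------------------------------------------

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.region_weights)

    def truth(self, group: Group, region: str) -> tuple[float, float, float]:
        """(ki, vi, vv) ground truth for one group x dissected region."""
        key = (*group, region)
        return (
            self.ki_true.get(key, 0.0),
            self.vi_true.get(key, 0.0),
            self.vv_true.get(key, 0.0),
        )

    def whole_brain_truth(
        self, group: Group, exclude: tuple[str, ...] = ("olfactory bulb",)
    ) -> tuple[float, float, float]:
        """Derived whole-brain (ki, vi, vv): weight-weighted regional means.

        Uses mean region weights; because whole brain is the count-weighted
        sum of dissected regions, this is the truth the pipeline can recover
        (exactly so in a noiseless simulation).
        """
        kept = [r for r in self.regions if r not in exclude]
        w = np.array([self.region_weights[r][0] for r in kept])
        tri = np.array([self.truth(group, r) for r in kept])
        ki, vi, vv = (w @ tri) / w.sum()
        return float(ki), float(vi), float(vv)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        problems: list[str] = []
        if self.noise_model not in NOISE_MODELS:
            problems.append(f"noise_model must be one of {NOISE_MODELS}")
        if not self.groups:
            problems.append("at least one group required")
        if self.n_per_group < 1:
            problems.append("n_per_group must be >= 1")
        if not self.time_schedule or any(t <= 0 for t in self.time_schedule):
            problems.append("time_schedule values must be strictly positive")
        if self.c0_tracer <= 0 or self.c0_marker <= 0:
            problems.append("initial serum concentrations must be > 0")
        if self.aliquot_volume <= 0:
            problems.append("aliquot_volume must be > 0")
        if self.k_clear_marker < 0:
            problems.append("k_clear_marker must be >= 0")
        if self.dose_cv < 0 or self.noise_cv < 0:
            problems.append("noise/dose dispersions must be >= 0")
        for g in self.groups:
            if g not in self.k_clear_tracer:
                problems.append(f"missing k_clear_tracer for group {g}")
            elif self.k_clear_tracer[g] < 0:
                problems.append(f"k_clear_tracer for group {g} must be >= 0")
        for region, (mean, sd) in self.region_weights.items():
            if region not in CANONICAL_REGIONS:
                problems.append(f"region_weights: unknown region {region!r}")
            if mean <= 0 or sd < 0:
                problems.append(f"region_weights[{region!r}] must have mean > 0, sd >= 0")
        for name, m in (("ki_true", self.ki_true), ("vv_true", self.vv_true)):
            for key, v in m.items():
                if v < 0:
                    problems.append(f"{name}[{key}] must be >= 0")
        for g in self.groups:
            for region in self.region_weights:
                ki, vi, vv = self.truth(g, region)
                if vi + vv < 0:
                    problems.append(
                        f"group {g}, region {region!r}: vi + vv = {vi + vv:g} < 0 "
                        "would give negative expected brain signal"
                    )
        if self.tracer_fast_phase is not None:
            f, kf = self.tracer_fast_phase
            if not (0 <= f < 1) or kf < 0:
                problems.append("tracer_fast_phase must be (fraction in [0,1), rate >= 0)")
        if problems:
            raise ValueError(
                "invalid simulation config:\n  - " + "\n  - ".join(problems)
            )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def truth_map(m: Mapping[TruthKey, float]) -> dict:
            out: dict[str, dict[str, float]] = {}
            for (gt, sex, region), v in m.items():
                out.setdefault(f"{gt} {sex}", {})[region] = v
            return out

        return {
            "schema": "bbbpk-sim-config/1",
            "groups": [list(g) for g in self.groups],
            "n_per_group": self.n_per_group,
            "time_schedule": list(map(float, self.time_schedule)),
            "c0_tracer": self.c0_tracer,
            "c0_marker": self.c0_marker,
            "k_clear_tracer": {f"{g} {s}": v for (g, s), v in self.k_clear_tracer.items()},
            "k_clear_marker": self.k_clear_marker,
            "ki_true": truth_map(self.ki_true),
            "vi_true": truth_map(self.vi_true),
            "vv_true": truth_map(self.vv_true),
            "region_weights": {r: list(ws) for r, ws in self.region_weights.items()},
            "aliquot_volume": self.aliquot_volume,
            "noise_model": self.noise_model,
            "noise_cv": self.noise_cv,
            "dose_cv": self.dose_cv,
            "tracer_fast_phase": (
                list(self.tracer_fast_phase) if self.tracer_fast_phase else None
            ),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        schema = d.pop("schema", "bbbpk-sim-config/1")
        if schema != "bbbpk-sim-config/1":
            raise ValueError(f"unrecognised config schema {schema!r}")

        def parse_truth(m: Mapping) -> dict[TruthKey, float]:
            out: dict[TruthKey, float] = {}
            for glabel, regions in m.items():
                gt, sex = glabel.split()
                for region, v in regions.items():
                    out[(gt, sex, region)] = float(v)
            return out

        known = {
            "groups", "n_per_group", "time_schedule", "c0_tracer", "c0_marker",
            "k_clear_tracer", "k_clear_marker", "ki_true", "vi_true", "vv_true",
            "region_weights", "aliquot_volume", "noise_model", "noise_cv",
            "dose_cv", "tracer_fast_phase", "seed",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs: dict = {}
        if "groups" in d:
            kwargs["groups"] = tuple(tuple(g) for g in d["groups"])
        for key in ("n_per_group", "c0_tracer", "c0_marker", "k_clear_marker",
                    "aliquot_volume", "noise_model", "noise_cv", "dose_cv", "seed"):
            if key in d:
                kwargs[key] = d[key]
        if "time_schedule" in d:
            kwargs["time_schedule"] = tuple(float(t) for t in d["time_schedule"])
        if "k_clear_tracer" in d:
            kwargs["k_clear_tracer"] = {
                tuple(k.split()): float(v) for k, v in d["k_clear_tracer"].items()
            }
        for key in ("ki_true", "vi_true", "vv_true"):
            if key in d:
                kwargs[key] = parse_truth(d[key])
        if "region_weights" in d:
            kwargs["region_weights"] = {
                r: (float(ws[0]), float(ws[1])) for r, ws in d["region_weights"].items()
            }
        if d.get("tracer_fast_phase") is not None:
            kwargs["tracer_fast_phase"] = tuple(d["tracer_fast_phase"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Stable hash of the full configuration (for provenance logging)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_config(*, noise: bool = True, seed: int = 0) -> SimulationConfig:
    """The reference study configuration.

    Ground truth Ki/Vi/Vv per group x region is seeded from the reported
    group-level estimates of the reference insulin BBB study (regions with
    non-significant transport get ki_true = 0 and vi_true = 0); the design
    is 4 groups x 10 mice, terminal times evenly spread over 0.5-10 min.

    With ``noise=True``: Poisson counting noise, sampled region weights and
    5% lognormal per-animal dose variability.  With ``noise=False`` the
    dataset is a deterministic evaluation of the forward model.
    """
    ki, vi, vv = {}, {}, {}
    for region in _VV_TABLE:
        for group, kv, iv, vvv in zip(
            _TABLE_GROUP_ORDER, _KI_TABLE[region], _VI_TABLE[region], _VV_TABLE[region]
        ):
            key = (*group, region)
            ki[key] = kv
            vi[key] = iv
            vv[key] = vvv
    return SimulationConfig(
        ki_true=ki,
        vi_true=vi,
        vv_true=vv,
        noise_model="poisson_counts" if noise else "none",
        dose_cv=0.05 if noise else 0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _serum_conc(c0: float, k: float, t: float,
                fast: tuple[float, float] | None = None) -> float:
    """Cp(t) for mono- (default) or bi-exponential decay."""
    if fast is None:
        return c0 * math.exp(-k * t)
    f, kf = fast
    return c0 * ((1 - f) * math.exp(-k * t) + f * math.exp(-kf * t))


def _serum_integral(c0: float, k: float, t: float,
                    fast: tuple[float, float] | None = None) -> float:
    """int_0^t Cp dtau, closed form."""
    def mono(c: float, rate: float) -> float:
        return c * t if rate == 0 else c * (1 - math.exp(-rate * t)) / rate

    if fast is None:
        return mono(c0, k)
    f, kf = fast
    return mono(c0 * (1 - f), k) + mono(c0 * f, kf)


def simulate_study(config: SimulationConfig, seed: int | None = None) -> StudyDataset:
    """Generate one study dataset from the forward model.

    Identical (config, seed) yields an identical dataset.  With
    ``noise_model="poisson_counts"`` configurations whose expected serum
    counts are low enough that a zero serum draw has > 1% probability for
    any animal are rejected (an unusable design).

    Parameters
    ----------
    config:
        Validated simulation configuration.
    seed:
        Overrides ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    poisson = config.noise_model == "poisson_counts"
    lognorm = config.noise_model == "lognormal_cv"
    noisy = config.noise_model != "none"
    # mean-one multiplicative lognormal with CV = noise_cv
    s_ln = math.sqrt(math.log1p(config.noise_cv ** 2)) if lognorm else 0.0

    # min expected serum counts so that P(Poisson draw == 0) <= 1%
    min_serum_mu = math.log(100.0)

    def measure(expected: float) -> float:
        if poisson:
            return float(rng.poisson(expected))
        if lognorm:
            return expected * float(rng.lognormal(-s_ln ** 2 / 2.0, s_ln))
        return expected

    animals: list[AnimalRecord] = []
    for group in config.groups:
        gt, sex = group
        k = config.k_clear_tracer[group]
        for i in range(config.n_per_group):
            t = config.time_schedule[i % len(config.time_schedule)]
            dose = (
                float(rng.lognormal(0.0, config.dose_cv)) if config.dose_cv > 0 else 1.0
            )
            cp_tracer = dose * _serum_conc(config.c0_tracer, k, t, config.tracer_fast_phase)
            cp_marker = dose * _serum_conc(config.c0_marker, config.k_clear_marker, t)
            integral = dose * _serum_integral(config.c0_tracer, k, t, config.tracer_fast_phase)
            mu_serum_tracer = cp_tracer * config.aliquot_volume
            mu_serum_marker = cp_marker * config.aliquot_volume
            if poisson and min(mu_serum_tracer, mu_serum_marker) < min_serum_mu:
                raise ValueError(
                    f"unusable design: expected serum counts "
                    f"{min(mu_serum_tracer, mu_serum_marker):.2f} cpm at t={t:g} min "
                    "give > 1% probability of a zero serum draw"
                )
            regions = []
            for region in config.regions:
                w_mean, w_sd = config.region_weights[region]
                if noisy and w_sd > 0:
                    weight = max(float(rng.normal(w_mean, w_sd)), w_mean * 0.1)
                else:
                    weight = w_mean
                ki, vi, vv = config.truth(group, region)
                am_tracer = ki * integral + (vi + vv) * cp_tracer   # cpm/g
                am_marker = vv * cp_marker
                regions.append(
                    RegionMeasurement(
                        region=region,
                        weight_g=weight,
                        tracer_cpm=measure(am_tracer * weight),
                        marker_cpm=measure(am_marker * weight),
                    )
                )
            animals.append(
                AnimalRecord(
                    id=f"{gt}{sex}-{i + 1:02d}",
                    genotype=gt,
                    sex=sex,
                    terminal_time_min=float(t),
                    serum_tracer_cpm=measure(mu_serum_tracer),
                    serum_marker_cpm=measure(mu_serum_marker),
                    aliquot_ul=config.aliquot_volume,
                    regions=regions,
                )
            )
    return StudyDataset(
        animals=animals,
        provenance={
            "generator": "bbbpk.synthetic.simulate_study",
            "config_digest": config.digest(),
            "seed": int(config.seed if seed is None else seed),
            "noise_model": config.noise_model,
        },
    )


def ground_truth_frame(config: SimulationConfig) -> pd.DataFrame:
    """Tidy sidecar of recoverable ground truth per group x region.

    Whole-brain rows carry the derived (weight-aggregated) truth, which is
    what the analysis pipeline estimates.
    """
    rows = []
    for group in config.groups:
        for region in config.regions:
            ki, vi, vv = config.truth(group, region)
            rows.append(
                {
                    "genotype": group[0], "sex": group[1], "region": region,
                    "ki_true": ki, "vi_true": vi, "vv_true": vv,
                }
            )
        ki, vi, vv = config.whole_brain_truth(group)
        rows.append(
            {
                "genotype": group[0], "sex": group[1], "region": WHOLE_BRAIN,
                "ki_true": ki, "vi_true": vi, "vv_true": vv,
            }
        )
    return pd.DataFrame(rows)
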