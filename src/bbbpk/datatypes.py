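"""In-memory containers for dual-tracer terminal-sample study data.

Units are fixed package-wide: time min, weight g, volume uL, counts cpm,
influx Ki uL/g-min, B/S ratios and Vi uL/g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import pandas as pd

from .regions import CANONICAL_REGIONS, GENOTYPES, SEXES


class StudyValidationError(ValueError):
    """Raised when a dataset violates the study schema.

    Carries every violation found, not just the first.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "study validation failed:\n  - " + "\n  - ".join(self.problems)
        )


@dataclass(frozen=True)
class RegionMeasurement:
    """Gamma counts for one dissected region of one animal."""

    region: str
    weight_g: float
    tracer_cpm: float
    marker_cpm: float

    def check(self) -> list[str]:
        problems = []
        if self.weight_g <= 0:
            problems.append(f"region {self.region!r}: weight_g must be > 0")
        if self.tracer_cpm < 0 or self.marker_cpm < 0:
            problems.append(f"region {self.region!r}: counts must be >= 0")
        return problems


@dataclass
class AnimalRecord:
    """One mouse's terminal observation.

    A single arterial blood sample and the dissected brain are collected at
    ``terminal_time_min`` after intravenous co-injection of the test tracer
    and the vascular (albumin) marker.
    """

    id: str
    genotype: str
    sex: str
    terminal_time_min: float
    serum_tracer_cpm: float
    serum_marker_cpm: float
    aliquot_ul: float = 50.0
    regions: list[RegionMeasurement] = field(default_factory=list)

    @property
    def group(self) -> tuple[str, str]:
        return (self.genotype, self.sex)

    @property
    def serum_tracer_conc(self) -> float:
        """Tracer serum concentration, cpm/uL."""
        return self.serum_tracer_cpm / self.aliquot_ul

    @property
    def serum_marker_conc(self) -> float:
        """Marker serum concentration, cpm/uL."""
        return self.serum_marker_cpm / self.aliquot_ul

    def region_map(self) -> dict[str, RegionMeasurement]:
        return {m.region: m for m in self.regions}

    def check(self) -> list[str]:
        problems = []
        if self.genotype not in GENOTYPES:
            problems.append(f"animal {self.id}: genotype must be one of {GENOTYPES}")
        if self.sex not in SEXES:
            problems.append(f"animal {self.id}: sex must be one of {SEXES}")
        if not self.terminal_time_min > 0:
            problems.append(f"animal {self.id}: terminal_time_min must be > 0")
        if self.aliquot_ul <= 0:
            problems.append(f"animal {self.id}: aliquot_ul must be > 0")
        seen: set[str] = set()
        for m in self.regions:
            if m.region in seen:
                problems.append(f"animal {self.id}: duplicate region {m.region!r}")
            seen.add(m.region)
            if m.region not in CANONICAL_REGIONS:
                problems.append(
                    f"animal {self.id}: region {m.region!r} not in canonical list"
                )
            problems.extend(f"animal {self.id}: {p}" for p in m.check())
        return problems


@dataclass
class StudyDataset:
    """A complete study: one ``AnimalRecord`` per mouse, plus provenance."""

    animals: list[AnimalRecord]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __iter__(self) -> Iterator[AnimalRecord]:
        return iter(self.animals)

    def __len__(self) -> int:
        return len(self.animals)

    def validate(self) -> None:
        """Check all dataset invariants; report every violation together."""
        problems: list[str] = []
        if not self.animals:
            problems.append("no animals in dataset")
        ids = [a.id for a in self.animals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            problems.append(f"duplicate animal ids: {dupes}")
        for a in self.animals:
            problems.extend(a.check())
        region_sets = {frozenset(m.region for m in a.regions) for a in self.animals}
        if len(region_sets) > 1:
            problems.append("animals do not all carry the same region set")
        if problems:
            raise StudyValidationError(problems)

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (genotype, sex) groups, in first-appearance order."""
        out: list[tuple[str, str]] = []
        for a in self.animals:
            if a.group not in out:
                out.append(a.group)
        return out

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Tidy (animal-level, region-level) DataFrames."""
        animal_rows = [
            {
                "id": a.id,
                "genotype": a.genotype,
                "sex": a.sex,
                "time_min": a.terminal_time_min,
                "serum_tracer_cpm": a.serum_tracer_cpm,
                "serum_marker_cpm": a.serum_marker_cpm,
                "aliquot_ul": a.aliquot_ul,
            }
            for a in self.animals
        ]
        region_rows = [
            {
                "id": a.id,
                "region": m.region,
                "weight_g": m.weight_g,
                "tracer_cpm": m.tracer_cpm,
                "marker_cpm": m.marker_cpm,
            }
            for a in self.animals
            for m in a.regions
        ]
        return pd.DataFrame(animal_rows), pd.DataFrame(region_rows)
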