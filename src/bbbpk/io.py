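"""Study CSV schema, readers/writers, and results serialisation.

The interchange format is a single CSV with a versioned header comment
(``# bbbpk-study/1``) holding two row types linked by animal id:

* ``animal`` rows: id, genotype, sex, time_min, serum_tracer_cpm,
  serum_marker_cpm, aliquot_ul;
* ``region`` rows: id, region, weight_g, tracer_cpm, marker_cpm.

Floats in study files are written at full precision so that
write -> read round-trips bit-identically.  Results tables are written at
6 significant digits with a full-precision JSON sidecar.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .datatypes import AnimalRecord, RegionMeasurement, StudyDataset, StudyValidationError
from .pipeline import ResultsBundle
from .regions import normalize_region
from .synthetic import SimulationConfig

STUDY_SCHEMA = "bbbpk-study/1"

_ANIMAL_COLS = (
    "id", "genotype", "sex", "time_min",
    "serum_tracer_cpm", "serum_marker_cpm", "aliquot_ul",
)
_REGION_COLS = ("id", "region", "weight_g", "tracer_cpm", "marker_cpm")
_ALL_COLS = ("row_type",) + _ANIMAL_COLS[:1] + (
    "genotype", "sex", "time_min", "serum_tracer_cpm", "serum_marker_cpm",
    "aliquot_ul", "region", "weight_g", "tracer_cpm", "marker_cpm",
)


def write_study(dataset: StudyDataset, path: str | Path) -> None:
    """Write a study dataset to the versioned CSV schema."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# {STUDY_SCHEMA}\n")
        writer = csv.writer(fh)
        writer.writerow(_ALL_COLS)
        for a in dataset:
            writer.writerow(
                ["animal", a.id, a.genotype, a.sex, repr(a.terminal_time_min),
                 repr(a.serum_tracer_cpm), repr(a.serum_marker_cpm),
                 repr(a.aliquot_ul), "", "", "", ""]
            )
            for m in a.regions:
                writer.writerow(
                    ["region", a.id, "", "", "", "", "", "", m.region,
                     repr(m.weight_g), repr(m.tracer_cpm), repr(m.marker_cpm)]
                )


def _parse_float(value: str, what: str, line: int, problems: list[str],
                 nonneg: bool = False, positive: bool = False) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        problems.append(f"line {line}: {what} is not a number: {value!r}")
        return math.nan
    if positive and not v > 0:
        problems.append(f"line {line}: {what} must be > 0, got {v!r}")
    elif nonneg and v < 0:
        problems.append(f"line {line}: {what} must be >= 0, got {v!r}")
    return v


def read_study(
    path: str | Path, aliases: dict[str, str] | None = None
) -> StudyDataset:
    """Read and validate a study CSV.

    All schema violations are collected and reported together in a single
    :class:`StudyValidationError`, each with its line number.

    Parameters
    ----------
    path:
        Study CSV path.
    aliases:
        Optional explicit region-alias mapping (alias -> canonical name).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    problems: list[str] = []
    with path.open(newline="") as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or STUDY_SCHEMA not in first:
            raise StudyValidationError(
                [f"line 1: missing or unrecognised schema header "
                 f"(expected '# {STUDY_SCHEMA}', got {first!r})"]
            )
        reader = csv.DictReader(fh)
        animals: dict[str, AnimalRecord] = {}
        region_rows: list[tuple[int, str, RegionMeasurement]] = []
        seen_regions: set[tuple[str, str]] = set()
        for line_no, row in enumerate(reader, start=3):
            row_type = (row.get("row_type") or "").strip()
            aid = (row.get("id") or "").strip()
            if not aid:
                problems.append(f"line {line_no}: missing animal id")
                continue
            if row_type == "animal":
                if aid in animals:
                    problems.append(f"line {line_no}: duplicate animal id {aid!r}")
                    continue
                animals[aid] = AnimalRecord(
                    id=aid,
                    genotype=(row.get("genotype") or "").strip(),
                    sex=(row.get("sex") or "").strip(),
                    terminal_time_min=_parse_float(
                        row.get("time_min"), "time_min", line_no, problems, positive=True
                    ),
                    serum_tracer_cpm=_parse_float(
                        row.get("serum_tracer_cpm"), "serum_tracer_cpm", line_no,
                        problems, nonneg=True,
                    ),
                    serum_marker_cpm=_parse_float(
                        row.get("serum_marker_cpm"), "serum_marker_cpm", line_no,
                        problems, nonneg=True,
                    ),
                    aliquot_ul=_parse_float(
                        row.get("aliquot_ul"), "aliquot_ul", line_no, problems,
                        positive=True,
                    ),
                    regions=[],
                )
            elif row_type == "region":
                raw_region = (row.get("region") or "").strip()
                try:
                    region = normalize_region(raw_region, aliases)
                except ValueError as e:
                    problems.append(f"line {line_no}: {e}")
                    continue
                if (aid, region) in seen_regions:
                    problems.append(
                        f"line {line_no}: duplicate region {region!r} for animal {aid!r}"
                    )
                    continue
                seen_regions.add((aid, region))
                measurement = RegionMeasurement(
                    region=region,
                    weight_g=_parse_float(
                        row.get("weight_g"), "weight_g", line_no, problems, positive=True
                    ),
                    tracer_cpm=_parse_float(
                        row.get("tracer_cpm"), "tracer_cpm", line_no, problems, nonneg=True
                    ),
                    marker_cpm=_parse_float(
                        row.get("marker_cpm"), "marker_cpm", line_no, problems, nonneg=True
                    ),
                )
                region_rows.append((line_no, aid, measurement))
            else:
                problems.append(
                    f"line {line_no}: unknown row_type {row_type!r} "
                    "(expected 'animal' or 'region')"
                )
    for line_no, aid, m in region_rows:
        if aid not in animals:
            problems.append(
                f"line {line_no}: region row references unknown animal id {aid!r}"
            )
        else:
            animals[aid].regions.append(m)
    if not animals and not problems:
        problems.append("no animals found in study file")
    if problems:
        raise StudyValidationError(problems)
    # only the file name, not the absolute path: results must be
    # byte-identical across working directories for the same inputs
    dataset = StudyDataset(
        animals=list(animals.values()), provenance={"source": path.name}
    )
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# simulation config files
# ---------------------------------------------------------------------------

def load_sim_config(path: str | Path) -> SimulationConfig:
    """Load a simulation config from YAML or JSON (validated)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return SimulationConfig.from_dict(data)


def save_sim_config(config: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# results output
# ---------------------------------------------------------------------------

def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_results(bundle: ResultsBundle, outdir: str | Path) -> list[Path]:
    """Write all results tables (6 significant digits) plus a
    full-precision machine-readable sidecar (``results.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = bundle.to_tables()
    for stem, df in tables.items():
        p = outdir / f"{stem}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    sidecar = {
        "schema": "bbbpk-results/1",
        "provenance": _jsonify(bundle.provenance),
        "analysis": _jsonify(bundle.analysis),
        "exclusions": _jsonify(bundle.exclusions),
        "serum_fits": {
            " ".join(k): _jsonify(f) for k, f in bundle.serum_fits.items()
        },
        "patlak_fits": {
            " | ".join(k): _jsonify(f) for k, f in bundle.patlak_fits.items()
        },
        "tables": {
            stem: _jsonify(df.to_dict(orient="records"))
            for stem, df in tables.items()
        },
    }
    p = outdir / "results.json"
    p.write_text(json.dumps(sidecar, indent=2))
    written.append(p)
    return written
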