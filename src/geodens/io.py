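"""Readers and writers for the pipeline's on-disk formats.

Geometry travels as GeoJSON FeatureCollections, tables as CSV with fixed
headers, configuration as YAML. All writers are deterministic (no
timestamps, stable key order) so identical seeds give byte-identical runs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .covariates import COVARIATE_NAMES
from .types import (
    BufferObservation,
    DisseminationArea,
    SamplingPoint,
    SimulationConfig,
    StudyRegion,
    UserPoint,
)

USERS_CSV_COLUMNS = ("id", "x", "y", "shows_location")
BUFFERS_CSV_COLUMNS = (
    "point_id",
    "x",
    "y",
    "slot",
    "sample_order",
    "radius",
    "user_count",
    "ambiguous_count",
    "land_area",
    "density",
)


def write_das_geojson(das: Sequence[DisseminationArea], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(da.polygon),
            "properties": {
                "id": da.id,
                "population": da.population,
                **{k: da.covariates.get(k) for k in COVARIATE_NAMES},
            },
        }
        for da in das
    ]
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc))


def read_das_geojson(path: str | Path) -> list[DisseminationArea]:
    fc = json.loads(Path(path).read_text())
    das = []
    for feat in fc["features"]:
        props = feat["properties"]
        das.append(
            DisseminationArea(
                id=str(props["id"]),
                polygon=shape(feat["geometry"]),
                population=float(props.get("population", 0.0)),
                covariates={
                    k: float(props[k]) for k in COVARIATE_NAMES if props.get(k) is not None
                },
            )
        )
    return das


def write_users_csv(users: Sequence[UserPoint], path: str | Path) -> None:
    df = pd.DataFrame(
        [(u.id, u.x, u.y, u.shows_location) for u in users],
        columns=list(USERS_CSV_COLUMNS),
    )
    # %.17g guarantees float64 round-trips exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_users_csv(path: str | Path) -> list[UserPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        UserPoint(id=str(r.id), x=float(r.x), y=float(r.y),
                  shows_location=bool(r.shows_location))
        for r in df.itertuples()
    ]


def write_buffers_csv(buffers: Sequence[BufferObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                b.point.id, b.point.x, b.point.y, b.point.slot, b.point.sample_order,
                b.radius, b.user_count, b.ambiguous_count, b.land_area, b.density,
            )
            for b in buffers
        ],
        columns=list(BUFFERS_CSV_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_buffers_csv(path: str | Path) -> list[BufferObservation]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        BufferObservation(
            point=SamplingPoint(
                id=int(r.point_id), x=float(r.x), y=float(r.y),
                slot=str(r.slot), sample_order=int(r.sample_order),
            ),
            radius=float(r.radius),
            user_count=int(r.user_count),
            ambiguous_count=int(r.ambiguous_count),
            land_area=float(r.land_area),
            density=int(r.density),
        )
        for r in df.itertuples()
    ]


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["region"] = dataclasses.asdict(config.region)
    d["slot_effects"] = list(config.slot_effects)
    d.pop("p_hidden_field", None)  # callables are not serializable
    return d


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    region = d.pop("region", None)
    kwargs = {}
    if region is not None:
        kwargs["region"] = StudyRegion(**region)
    if "slot_effects" in d:
        d["slot_effects"] = tuple(d["slot_effects"])
    kwargs.update(d)
    return SimulationConfig(**kwargs)


def write_yaml(data: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
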