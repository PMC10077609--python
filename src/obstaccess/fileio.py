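"""File formats: registry/area/cohort CSV, network CSV + GeoJSON, YAML config.

CSV dialect: UTF-8, comma-separated, "." decimal mark. GeoJSON follows
RFC 7946 structurally; synthetic regions use planar km coordinates, declared
in the FeatureCollection's ``properties.crs_note``. Write-then-read of every
emitted format is lossless for all mandatory fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .network import TIME_ATTR, RoadNetwork
from .operationalize import CohortRow, HospitalRecord

REGISTRY_MANDATORY_COLUMNS = (
    "site_id",
    "year",
    "node_id",
    "postal_area",
    "departments",
    "procedures",
    "ownership",
    "teaching",
    "whole_hospital_closed",
)


def _encode_departments(departments: frozenset[str]) -> str:
    return ";".join(sorted(departments))


def _encode_procedures(procedures: Mapping[str, int]) -> str:
    return ";".join(f"{code}:{count}" for code, count in sorted(procedures.items()))


def write_registry(records: Sequence[HospitalRecord], path: str | Path) -> None:
    rows = [
        {
            "site_id": r.site_id,
            "year": r.year,
            "node_id": r.location,
            "postal_area": r.postal_area,
            "departments": _encode_departments(r.departments),
            "procedures": _encode_procedures(r.procedures),
            "ownership": r.ownership,
            "teaching": r.teaching,
            "whole_hospital_closed": r.whole_hospital_closed,
            "facility_type": r.facility_type,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REGISTRY_MANDATORY_COLUMNS) + ["facility_type"]).to_csv(
        path, index=False
    )


def read_registry(path: str | Path) -> list[HospitalRecord]:
    """Validated registry records; unknown columns are preserved as extras.

    A missing mandatory column fails naming the column; an unparseable row
    fails naming its line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REGISTRY_MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"registry {path}: missing mandatory column {col!r}")
    extra_cols = [
        c for c in df.columns if c not in REGISTRY_MANDATORY_COLUMNS and c != "facility_type"
    ]
    records: list[HospitalRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        key = (row["site_id"], row["year"])
        if key in seen:
            raise ValueError(
                f"registry {path}: duplicate (site_id, year) {key} at line {line}"
            )
        seen.add(key)
        try:
            procedures: dict[str, int] = {}
            if row["procedures"]:
                for item in row["procedures"].split(";"):
                    code, count = item.rsplit(":", 1)
                    procedures[code] = int(count)
            departments = frozenset(d for d in row["departments"].split(";") if d)
            node_id: object = row["node_id"]
            try:
                node_id = int(node_id)
            except (TypeError, ValueError):
                pass
            records.append(
                HospitalRecord(
                    site_id=row["site_id"],
                    year=int(row["year"]),
                    location=node_id,
                    postal_area=row["postal_area"],
                    departments=departments,
                    procedures=procedures,
                    ownership=row["ownership"],
                    teaching=row["teaching"],
                    whole_hospital_closed=str(row["whole_hospital_closed"]).lower()
                    in ("true", "1", "yes"),
                    facility_type=row.get("facility_type", "acute") or "acute",
                    extras={c: row[c] for c in extra_cols},
                )
            )
        except (ValueError, KeyError) as exc:
            if "duplicate" in str(exc):
                raise
            raise ValueError(f"registry {path}: unparseable row at line {line}: {exc}") from exc
    return records


def write_areas(area_attributes: Mapping[str, tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"postal_area": k, "density_raw": v[0], "fertility_rate": v[1]}
            for k, v in area_attributes.items()
        ]
    ).to_csv(path, index=False)


def read_areas(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path)
    for col in ("postal_area", "density_raw", "fertility_rate"):
        if col not in df.columns:
            raise ValueError(f"area table {path}: missing mandatory column {col!r}")
    return {
        str(r["postal_area"]): (float(r["density_raw"]), float(r["fertility_rate"]))
        for _, r in df.iterrows()
    }


def write_network_csv(network: RoadNetwork, nodes_path: str | Path, edges_path: str | Path) -> None:
    g = network.graph
    pd.DataFrame(
        [{"node_id": n, "x": d["x"], "y": d["y"]} for n, d in g.nodes(data=True)]
    ).to_csv(nodes_path, index=False)
    pd.DataFrame(
        [{"u": u, "v": v, "time_min": t} for u, v, t in g.edges(data=TIME_ATTR)]
    ).to_csv(edges_path, index=False)


def read_network_csv(nodes_path: str | Path, edges_path: str | Path) -> RoadNetwork:
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    g = nx.Graph()
    for _, r in nodes.iterrows():
        g.add_node(int(r["node_id"]), x=float(r["x"]), y=float(r["y"]))
    for _, r in edges.iterrows():
        g.add_edge(int(r["u"]), int(r["v"]), **{TIME_ATTR: float(r["time_min"])})
    return RoadNetwork(g)


def write_network_geojson(network: RoadNetwork, path: str | Path) -> None:
    """Edges as LineString features (planar km coordinates, declared as such)."""
    g = network.graph
    features = []
    for u, v, t in g.edges(data=TIME_ATTR):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [g.nodes[u]["x"], g.nodes[u]["y"]],
                        [g.nodes[v]["x"], g.nodes[v]["y"]],
                    ],
                },
                "properties": {"u": u, "v": v, "time_min": t},
            }
        )
    collection = {
        "type": "FeatureCollection",
        "properties": {"crs_note": "planar km coordinates (synthetic region)"},
        "features": features,
    }
    Path(path).write_text(json.dumps(collection, sort_keys=True))


def write_surface_geojson(surface, path: str | Path) -> None:
    features = []
    for _, r in surface.points.iterrows():
        t = r["min_time"]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r["x"], r["y"]]},
                "properties": {
                    "min_time": None if math.isinf(t) else t,
                    "band": r["band"],
                },
            }
        )
    collection = {
        "type": "FeatureCollection",
        "properties": {
            "crs_note": "planar km coordinates (synthetic region)",
            "scenario": surface.scenario,
            "seed": surface.seed,
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(collection, sort_keys=True))


def write_cohort(cohort: Sequence[CohortRow], path: str | Path) -> None:
    from .operationalize import cohort_frame

    cohort_frame(list(cohort)).to_csv(path, index=False)


def write_regression_table(result, path: str | Path) -> None:
    """Coefficient table CSV mirroring the published layout, plus fit stats."""
    tab = result.table.copy()
    tab["gvif"] = tab["term"].map(result.gvif).where(tab["term"] != "(Intercept)")
    tab.to_csv(path, index=False)
    stats = {
        "log_likelihood": result.log_likelihood,
        "null_deviance": result.null_deviance,
        "deviance": result.deviance,
        "aic": result.aic,
        "bic": result.bic,
        "mcfadden_adjusted_r2": result.mcfadden_adjusted_r2,
        "n_obs": result.n_obs,
        "n_params": result.n_params,
    }
    Path(path).with_suffix(".stats.json").write_text(json.dumps(stats, sort_keys=True, indent=2))


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run configuration. ``seed`` is mandatory for every stochastic stage."""

    seed: int
    simulate: bool = True
    n_sites: int = 702
    n_nodes: int = 1500
    sampler_n: int = 10000
    thresholds: tuple[float, float] = (30.0, 40.0)
    density_cutpoints: tuple[float, float] = (100.0, 1000.0)
    fertility_cutpoints: tuple[float, float] = (1.3, 1.6)
    scenarios: tuple[dict, ...] = (
        {"name": "all", "require_pediatrics": False, "min_live_births": None},
        {"name": "pediatrics_only", "require_pediatrics": True, "min_live_births": None},
        {"name": "min600", "require_pediatrics": False, "min_live_births": 600},
    )
    registry_baseline: str | None = None
    registry_followup: str | None = None
    areas: str | None = None
    network_nodes: str | None = None
    network_edges: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        for name in ("thresholds", "density_cutpoints", "fertility_cutpoints"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be strictly increasing, got ({lo}, {hi})")
        if not self.simulate:
            for name in ("registry_baseline", "registry_followup", "areas"):
                if getattr(self, name) is None:
                    raise ValueError(f"non-simulated run needs {name!r} path")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a mapping")
    if "seed" not in raw:
        raise ValueError(f"config {path}: refusing to run without an explicit seed")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
    for tuple_key in ("thresholds", "density_cutpoints", "fertility_cutpoints"):
        if tuple_key in raw:
            raw[tuple_key] = tuple(raw[tuple_key])
    if "scenarios" in raw:
        raw["scenarios"] = tuple(raw["scenarios"])
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    data["scenarios"] = [dict(s) for s in config.scenarios]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
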