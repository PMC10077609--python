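"""Travel-time accessibility surfaces and regionalization scenarios.

Samples random points over the study region, snaps them to the road network,
computes each point's minimum car travel time to the nearest active obstetric
facility (one multi-source Dijkstra sweep seeded at all facilities), and
classifies the times against the 30/40-minute policy thresholds. Scenario
filters (pediatrics on site, minimum annual live births) shrink the facility
set; travel times can then only grow, so the over-threshold area fraction is
non-decreasing — this monotonicity is asserted on every scenario comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import TIME_ATTR, RoadNetwork

#: Policy driving-time thresholds in minutes (lower, upper band boundary).
DEFAULT_THRESHOLDS = (30.0, 40.0)

BANDS = ("under30", "band30to40", "over40")


@dataclass(frozen=True)
class Facility:
    site_id: str
    node: object
    live_births: int
    has_pediatrics: bool


@dataclass
class FacilitySet:
    """Active obstetric facilities snapped to network nodes."""

    sites: tuple[Facility, ...]

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def nodes(self) -> list[object]:
        return [f.node for f in self.sites]

    def validate_against(self, network: RoadNetwork) -> None:
        for f in self.sites:
            if f.node not in network.graph:
                raise ValueError(f"facility {f.site_id}: node {f.node!r} not in network")

    @classmethod
    def from_cohort(cls, cohort_frame: pd.DataFrame, node_col: str = "location") -> "FacilitySet":
        return cls(
            tuple(
                Facility(
                    site_id=str(r["site_id"]),
                    node=r[node_col],
                    live_births=int(r["live_births"]),
                    has_pediatrics=bool(r["has_pediatrics"]),
                )
                for _, r in cohort_frame.iterrows()
            )
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """Regionalization scenario: which facilities stay active.

    ``min_live_births`` is inclusive (≥). A spec with no active criterion is
    the identity ("all facilities") scenario.
    """

    name: str
    require_pediatrics: bool = False
    min_live_births: int | None = None


def apply_scenario(facilities: FacilitySet, spec: ScenarioSpec) -> FacilitySet:
    """Subset of facilities satisfying every active scenario criterion."""
    kept = []
    for f in facilities.sites:
        if spec.require_pediatrics and not f.has_pediatrics:
            continue
        if spec.min_live_births is not None and f.live_births < spec.min_live_births:
            continue
        kept.append(f)
    if not kept:
        warnings.warn(f"scenario {spec.name!r} leaves no active facility", stacklevel=2)
    return FacilitySet(tuple(kept))


def shortest_time_map(network: RoadNetwork, facility_nodes: Sequence[object]) -> dict[object, float]:
    """Minimum travel time (minutes) from every network node to the nearest facility.

    Single multi-source Dijkstra sweep; equals the per-facility minimum over
    independent single-source runs. Unreachable nodes get ``+inf``; an empty
    facility set yields all ``+inf`` with a warning.
    """
    nodes = list(network.graph.nodes)
    if len(facility_nodes) == 0:
        warnings.warn("empty facility set: all nodes unreachable", stacklevel=2)
        return {v: math.inf for v in nodes}
    sources = set(facility_nodes)
    missing = [s for s in sources if s not in network.graph]
    if missing:
        raise ValueError(f"facility nodes not in network: {missing}")
    dist = nx.multi_source_dijkstra_path_length(network.graph, sources, weight=TIME_ATTR)
    return {v: dist.get(v, math.inf) for v in nodes}


def classify_time(minutes: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Threshold band: t < 30 → under30; 30 ≤ t ≤ 40 → band30to40; t > 40 → over40.

    ``+inf`` (unreachable, the islands analog) classifies as over40.
    """
    lo, hi = thresholds
    if math.isnan(minutes) or minutes < 0:
        raise ValueError(f"travel time must be >= 0 or +inf, got {minutes}")
    if minutes < lo:
        return BANDS[0]
    if minutes <= hi:
        return BANDS[1]
    return BANDS[2]


def sample_points(
    bbox: tuple[float, float, float, float],
    n: int,
    seed: int,
    region_polygon=None,
) -> np.ndarray:
    """n points uniform over the bbox (or a shapely polygon inside it), seeded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    x0, y0, x1, y1 = bbox
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate region: bbox has no area")
    rng = np.random.default_rng(seed)
    if region_polygon is None:
        return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    if region_polygon.area <= 0:
        raise ValueError("degenerate region: polygon has no area")
    from shapely import points as _mk_points, contains

    out = np.empty((0, 2))
    while len(out) < n:
        batch = max(n - len(out), 1) * 2
        cand = np.column_stack([rng.uniform(x0, x1, batch), rng.uniform(y0, y1, batch)])
        keep = contains(region_polygon, _mk_points(cand))
        out = np.vstack([out, cand[keep]])
    return out[:n]


@dataclass
class AccessSurface:
    """Sampled points with minimum travel time to the nearest active facility."""

    points: pd.DataFrame  # x, y, node, snap_km, min_time, band
    n_points: int
    seed: int
    scenario: str = "all"
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS

    def band_counts(self) -> dict[str, int]:
        counts = self.points["band"].value_counts()
        return {b: int(counts.get(b, 0)) for b in BANDS}


def access_surface(
    network: RoadNetwork,
    facilities: FacilitySet,
    n_points: int,
    seed: int,
    bbox: tuple[float, float, float, float] | None = None,
    region_polygon=None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    scenario_name: str = "all",
    points: np.ndarray | None = None,
) -> AccessSurface:
    """Sample points, snap them to the network, and band their travel times.

    Pass ``points`` to reuse one sampled point set across scenarios (the
    scenario comparisons below require a common sample).
    """
    facilities.validate_against(network)
    if points is None:
        if bbox is None:
            _, xy = network.coords()
            bbox = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
        points = sample_points(bbox, n_points, seed, region_polygon=region_polygon)
    nodes, snap = network.nearest_nodes(points)
    node_time = shortest_time_map(network, facilities.nodes())
    times = np.array([node_time[v] for v in nodes])
    bands = [classify_time(t, thresholds) for t in times]
    df = pd.DataFrame(
        {
            "x": points[:, 0],
            "y": points[:, 1],
            "node": nodes,
            "snap_km": snap,
            "min_time": times,
            "band": bands,
        }
    )
    return AccessSurface(
        points=df,
        n_points=len(df),
        seed=seed,
        scenario=scenario_name,
        thresholds=thresholds,
    )


@dataclass
class CoverageReport:
    """Band fractions with Monte-Carlo standard errors, per scenario."""

    fractions: pd.DataFrame  # scenario, band, fraction, se, n_points
    deltas: pd.DataFrame | None = None  # scenario pair deltas per band


def coverage_report(
    surfaces: Mapping[str, AccessSurface] | AccessSurface,
    baseline: str | None = None,
) -> CoverageReport:
    """Band fractions (sum to 1) with binomial SEs; deltas vs a baseline scenario."""
    if isinstance(surfaces, AccessSurface):
        surfaces = {surfaces.scenario: surfaces}
    rows = []
    for name, surf in surfaces.items():
        n = surf.n_points
        if n == 0:
            raise ValueError(f"surface {name!r} has zero points")
        counts = surf.band_counts()
        for band in BANDS:
            frac = counts[band] / n
            rows.append(
                {
                    "scenario": name,
                    "band": band,
                    "fraction": frac,
                    "se": math.sqrt(frac * (1 - frac) / n),
                    "n_points": n,
                }
            )
    fractions = pd.DataFrame(rows)
    deltas = None
    if baseline is not None:
        if baseline not in surfaces:
            raise KeyError(f"baseline scenario {baseline!r} not among surfaces")
        base = fractions[fractions["scenario"] == baseline].set_index("band")["fraction"]
        drows = []
        for name in surfaces:
            if name == baseline:
                continue
            cur = fractions[fractions["scenario"] == name].set_index("band")["fraction"]
            for band in BANDS:
                drows.append(
                    {
                        "scenario": name,
                        "baseline": baseline,
                        "band": band,
                        "delta": float(cur[band] - base[band]),
                    }
                )
        deltas = pd.DataFrame(drows)
    return CoverageReport(fractions=fractions, deltas=deltas)


def run_scenarios(
    network: RoadNetwork,
    facilities: FacilitySet,
    scenarios: Sequence[ScenarioSpec],
    n_points: int,
    seed: int,
    bbox: tuple[float, float, float, float] | None = None,
    region_polygon=None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> tuple[dict[str, AccessSurface], CoverageReport]:
    """Evaluate scenario surfaces on one common point sample.

    The first scenario is the comparison baseline. For every scenario whose
    facility set is a subset of the baseline's, per-point travel-time
    monotonicity (no point gets closer when facilities are removed) is
    asserted as an internal consistency check.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    if bbox is None:
        _, xy = network.coords()
        bbox = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
    points = sample_points(bbox, n_points, seed, region_polygon=region_polygon)

    surfaces: dict[str, AccessSurface] = {}
    for spec in scenarios:
        active = apply_scenario(facilities, spec)
        surfaces[spec.name] = access_surface(
            network,
            active,
            n_points=n_points,
            seed=seed,
            thresholds=thresholds,
            scenario_name=spec.name,
            points=points,
        )

    base_name = scenarios[0].name
    base = surfaces[base_name]
    base_ids = {f.site_id for f in apply_scenario(facilities, scenarios[0]).sites}
    for spec in scenarios[1:]:
        ids = {f.site_id for f in apply_scenario(facilities, spec).sites}
        if ids <= base_ids:
            worse = surfaces[spec.name].points["min_time"].to_numpy()
            better = base.points["min_time"].to_numpy()
            if np.any(worse < better - 1e-9):
                raise AssertionError(
                    f"monotonicity violated: scenario {spec.name!r} shortened a travel time"
                )
    report = coverage_report(surfaces, baseline=base_name)
    return surfaces, report
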