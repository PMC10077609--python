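"""Synthetic study region: road network, area attributes, hospital registries.

Generates a self-contained planar region whose hospital cohort matches the
statistical structure of the German obstetric-hospital study population:
~700 sites with ownership shares near 39.9/43.2/16.9% (nonprofit/public/
private), ~39.5% pediatrics availability, density strata near 5/42/53%
(low/medium/high), right-skewed annual live births (median ≈683, IQR
≈450–1126), and nearest-competitor travel times with a median near 18 min.
Closures are then simulated from a logistic true model whose default odds
ratios follow the published final closure model; its intercept is calibrated
so the expected closure rate matches the published 10.26% event share.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.special import expit

from .network import TIME_ATTR, RoadNetwork
from .operationalize import (
    BASELINE_YEAR,
    FOLLOWUP_YEAR,
    HospitalRecord,
    LIVE_BIRTH_CODES,
    OBSTETRICS_DEPT_CODES,
    PEDIATRICS_DEPT_CODES,
    categorize_density,
    min_interfacility_time,
)

_Z75 = 0.6744897501960817  # standard-normal 75% quantile


def lognormal_from_median_iqr(median: float, q25: float, q75: float) -> tuple[float, float]:
    """Solve (mu, sigma) of a log-normal from its median and quartiles."""
    if not (0 < q25 < median < q75):
        raise ValueError("need 0 < q25 < median < q75")
    mu = math.log(median)
    sigma = math.log(q75 / q25) / (2 * _Z75)
    return mu, sigma


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of the synthetic study region.

    ``attribute_marginals`` holds the target category probabilities for the
    site-level attributes; ``births_distribution`` the (median, q25, q75) of
    the right-skewed annual live-birth distribution. Defaults reproduce the
    regression-sample marginals of the study population.
    """

    n_sites: int = 702
    n_nodes: int = 1500
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 650.0, 870.0)  # km
    attribute_marginals: Mapping[str, Mapping[str, float] | float] = field(
        default_factory=lambda: {
            "ownership": {"nonprofit": 0.3989, "public": 0.4316, "private": 0.1695},
            "pediatrics": 0.3946,
            "teaching": {"no": 0.3362, "yes": 0.6638, "university": 0.0},
            "density": {"low": 0.0499, "medium": 0.4160, "high": 0.5341},
        }
    )
    births_distribution: tuple[float, float, float] = (683.0, 450.0, 1126.0)
    fertility_mean: float = 1.48
    fertility_sd: float = 0.12
    n_areas: int = 120
    knn: int = 3
    rgg_radius_factor: float = 1.2  # radius = factor * sqrt(area / n_nodes)
    speed_kmh: float = 60.0
    detour_factor: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_nodes < max(2, self.n_sites):
            raise ValueError("n_nodes must be >= max(2, n_sites)")
        x0, y0, x1, y1 = self.bbox
        if not (x1 > x0 and y1 > y0):
            raise ValueError("bbox must have positive area")
        for name in ("ownership", "teaching", "density"):
            probs = self.attribute_marginals[name]
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} marginals sum to {total}, expected 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} marginals must be non-negative")
        p_ped = self.attribute_marginals["pediatrics"]
        if not (0.0 <= p_ped <= 1.0):
            raise ValueError("pediatrics marginal must be a probability")


@dataclass(frozen=True)
class TrueModel:
    """Generating logistic model for obstetrics-department closure.

    Coefficients are log-odds; ``intercept=None`` means "calibrate at
    simulation time so the mean closure probability equals ``target_rate``".
    Reference levels: private ownership, no pediatrics, non-teaching, low
    population density.
    """

    intercept: float | None = None
    beta_births: float = 0.0
    beta_pediatrics: float = 0.0
    beta_density_medium: float = 0.0
    beta_density_high: float = 0.0
    beta_fertility: float = 0.0
    beta_mintime: float = 0.0
    beta_ownership_nonprofit: float = 0.0
    beta_ownership_public: float = 0.0
    beta_teaching_yes: float = 0.0
    target_rate: float = 0.1026

    def __post_init__(self) -> None:
        for name in (
            "beta_births",
            "beta_pediatrics",
            "beta_density_medium",
            "beta_density_high",
            "beta_fertility",
            "beta_mintime",
            "beta_ownership_nonprofit",
            "beta_ownership_public",
            "beta_teaching_yes",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.intercept is not None and not math.isfinite(self.intercept):
            raise ValueError("intercept must be finite")

    def nonzero_effects(self) -> dict[str, float]:
        out = {}
        for name in (
            "beta_births",
            "beta_pediatrics",
            "beta_density_medium",
            "beta_density_high",
            "beta_fertility",
            "beta_mintime",
            "beta_ownership_nonprofit",
            "beta_ownership_public",
            "beta_teaching_yes",
        ):
            val = getattr(self, name)
            if val != 0.0:
                out[name] = val
        return out


def final_model_preset() -> TrueModel:
    """Generating model with the published final-model odds ratios.

    OR 0.995 per live birth, 0.357 for pediatrics, 0.24/0.251 for
    medium/high vs low density, 0.157 per fertility-rate unit, 0.95 per
    minute of nearest-competitor travel time; ownership and teaching null.
    """
    return TrueModel(
        beta_births=math.log(0.995),
        beta_pediatrics=math.log(0.357),
        beta_density_medium=math.log(0.24),
        beta_density_high=math.log(0.251),
        beta_fertility=math.log(0.157),
        beta_mintime=math.log(0.95),
    )


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------


def generate_network(config: RegionConfig) -> RoadNetwork:
    """Random planar road surrogate: geometric graph + k-NN augmentation.

    Nodes are uniform in the bbox; edges join pairs within the geometric
    radius, augmented with each node's k nearest neighbors; remaining
    components are bridged through their closest node pairs so the result is
    always connected. Edge weight = Euclidean km × detour factor / speed,
    in minutes.
    """
    if config.knn < 1 and config.rgg_radius_factor <= 0:
        raise ValueError(
            "unsatisfiable connectivity parameters: need knn >= 1 or a positive radius"
        )
    rng = np.random.default_rng(config.seed)
    x0, y0, x1, y1 = config.bbox
    n = config.n_nodes
    xy = np.column_stack(
        [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
    )
    area = (x1 - x0) * (y1 - y0)
    radius = config.rgg_radius_factor * math.sqrt(area / n)

    g = nx.Graph()
    for i in range(n):
        g.add_node(i, x=float(xy[i, 0]), y=float(xy[i, 1]))

    tree = cKDTree(xy)
    minutes_per_km = 60.0 * config.detour_factor / config.speed_kmh

    def add_edge(i: int, j: int) -> None:
        if i == j or g.has_edge(i, j):
            return
        d = float(np.hypot(*(xy[i] - xy[j])))
        g.add_edge(i, j, **{TIME_ATTR: max(d * minutes_per_km, 1e-9)})

    if radius > 0:
        for i, j in tree.query_pairs(radius):
            add_edge(int(i), int(j))
    if config.knn >= 1 and n > 1:
        k = min(config.knn + 1, n)
        _, idx = tree.query(xy, k=k)
        for i in range(n):
            for j in np.atleast_1d(idx[i])[1:]:
                add_edge(i, int(j))

    # Bridge remaining components through their closest node pairs.
    comps = [np.fromiter(c, int) for c in nx.connected_components(g)]
    while len(comps) > 1:
        comps.sort(key=lambda c: (len(c), int(c.min())))
        base = comps[0]
        best = (math.inf, -1, -1, -1)
        for ci in range(1, len(comps)):
            other = comps[ci]
            d = np.linalg.norm(xy[base][:, None, :] - xy[other][None, :, :], axis=2)
            ai, bi = np.unravel_index(int(d.argmin()), d.shape)
            if d[ai, bi] < best[0]:
                best = (float(d[ai, bi]), int(base[ai]), int(other[bi]), ci)
        _, i, j, ci = best
        add_edge(i, j)
        comps[ci] = np.concatenate([comps[ci], base])
        comps.pop(0)

    net = RoadNetwork(g)
    if not net.is_connected():  # pragma: no cover - defensive; bridging guarantees it
        raise RuntimeError("network generation failed to produce a connected graph")
    return net


# ---------------------------------------------------------------------------
# Area attributes and hospital placement
# ---------------------------------------------------------------------------


def _draw_categorical(rng: np.random.Generator, probs: Mapping[str, float], size: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[lv] for lv in levels], float)
    p = p / p.sum()
    return np.array(levels)[rng.choice(len(levels), size=size, p=p)]


def _quota_categorical(
    rng: np.random.Generator, probs: Mapping[str, float], size: int
) -> np.ndarray:
    """Category labels in exact largest-remainder quota counts, shuffled.

    Used for area-level strata, where the study region's marginal composition
    is fixed rather than sampled.
    """
    levels = list(probs)
    p = np.array([probs[lv] for lv in levels], float)
    p = p / p.sum()
    quota = p * size
    counts = np.floor(quota).astype(int)
    remainder = size - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    labels = np.repeat(np.array(levels), counts)
    return labels[rng.permutation(size)]


def assign_areas(
    network: RoadNetwork, config: RegionConfig, rng: np.random.Generator
) -> tuple[dict[object, str], pd.DataFrame]:
    """Partition nodes into area cells and draw per-area density and fertility.

    Areas mirror postal-code linkage: a coarse subset of nodes seeds a Voronoi
    partition of the network (by travel time); each cell gets one density
    stratum (drawn from the density marginals, then a raw value within the
    stratum band) and one fertility rate.
    """
    n_areas = min(config.n_areas, network.n_nodes)
    order, _ = network.coords()
    seeds = rng.choice(len(order), size=n_areas, replace=False)
    centers = [order[i] for i in sorted(seeds)]
    cells = nx.voronoi_cells(network.graph, set(centers), weight=TIME_ATTR)

    strata = _quota_categorical(rng, config.attribute_marginals["density"], n_areas)
    density_raw = np.empty(n_areas)
    for i, s in enumerate(strata):
        if s == "low":
            density_raw[i] = rng.uniform(20.0, 100.0)
        elif s == "medium":
            density_raw[i] = rng.uniform(100.0 + 1e-6, 1000.0)
        else:
            density_raw[i] = rng.uniform(1000.0 + 1e-6, 4500.0)
    fertility = np.clip(
        rng.normal(config.fertility_mean, config.fertility_sd, size=n_areas), 0.8, 2.2
    )

    node_to_area: dict[object, str] = {}
    records = []
    for i, center in enumerate(centers):
        area_id = f"A{i:04d}"
        records.append(
            {
                "postal_area": area_id,
                "density_raw": float(density_raw[i]),
                "fertility_rate": float(fertility[i]),
            }
        )
        for v in cells.get(center, ()):
            node_to_area[v] = area_id
    areas = pd.DataFrame(records)
    return node_to_area, areas


def _split_birth_count(rng: np.random.Generator, total: int) -> dict[str, int]:
    """Distribute one site's live births over the OPS 9-262 subcodes."""
    if total <= 0:
        return {}
    main = int(round(total * rng.uniform(0.85, 0.98)))
    main = min(main, total)
    rest = total - main
    out = {"9-262.0": main}
    if rest > 0:
        a = rng.integers(0, rest + 1)
        if a:
            out["9-262.1"] = int(a)
        if rest - a:
            out["9-262"] = int(rest - a)
    return out


def place_hospitals(
    network: RoadNetwork, config: RegionConfig
) -> tuple[list[HospitalRecord], pd.DataFrame]:
    """Baseline-year hospital registry snapped to network nodes.

    Returns the registry and the area-attribute table (postal_area,
    density_raw, fertility_rate). Sites occupy distinct nodes; categorical
    attributes and live births are drawn from the configured marginals.
    """
    if not network.is_connected():
        raise ValueError("network must be connected before placing hospitals")
    if config.n_sites > network.n_nodes:
        raise ValueError("n_sites exceeds the number of network nodes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    node_to_area, areas = assign_areas(network, config, rng)
    order, _ = network.coords()
    site_nodes = [order[i] for i in rng.choice(len(order), size=config.n_sites, replace=False)]

    ownership = _draw_categorical(rng, config.attribute_marginals["ownership"], config.n_sites)
    teaching = _draw_categorical(rng, config.attribute_marginals["teaching"], config.n_sites)
    pediatrics = rng.random(config.n_sites) < config.attribute_marginals["pediatrics"]
    mu, sigma = lognormal_from_median_iqr(*config.births_distribution)
    births = np.maximum(1, np.round(rng.lognormal(mu, sigma, size=config.n_sites))).astype(int)

    registry = []
    for i, node in enumerate(site_nodes):
        departments = {"2400"}
        if pediatrics[i]:
            departments |= set(PEDIATRICS_DEPT_CODES)
        registry.append(
            HospitalRecord(
                site_id=f"S{i:04d}",
                year=BASELINE_YEAR,
                location=node,
                postal_area=node_to_area[node],
                departments=frozenset(departments),
                procedures=_split_birth_count(rng, int(births[i])),
                ownership=str(ownership[i]),
                teaching=str(teaching[i]),
            )
        )
    return registry, areas


# ---------------------------------------------------------------------------
# Closure simulation
# ---------------------------------------------------------------------------

_EFFECT_COLUMNS = {
    "beta_births": "live_births",
    "beta_fertility": "fertility_rate",
    "beta_mintime": "min_interfacility_time",
}


def linear_predictor(model: TrueModel, frame: pd.DataFrame, intercept: float = 0.0) -> np.ndarray:
    """Log-odds of closure for each cohort row under the generating model."""
    eta = np.full(len(frame), intercept, dtype=float)
    for beta_name, col in _EFFECT_COLUMNS.items():
        eta += getattr(model, beta_name) * frame[col].to_numpy(float)
    eta += model.beta_pediatrics * frame["has_pediatrics"].to_numpy(bool)
    dens = np.asarray(frame["density_category"].astype(str))
    eta += model.beta_density_medium * (dens == "medium")
    eta += model.beta_density_high * (dens == "high")
    own = np.asarray(frame["ownership"].astype(str))
    eta += model.beta_ownership_nonprofit * (own == "nonprofit")
    eta += model.beta_ownership_public * (own == "public")
    teach = np.asarray(frame["teaching"].astype(str))
    eta += model.beta_teaching_yes * (teach == "yes")
    return eta


def calibrate_intercept(eta_without_intercept: np.ndarray, target_rate: float) -> float:
    """Intercept c such that mean(expit(c + eta)) equals the target event rate."""
    if not (0 < target_rate < 1):
        raise ValueError("target_rate must be in (0, 1)")
    eta = np.asarray(eta_without_intercept, float)

    def f(c: float) -> float:
        return float(np.mean(expit(c + eta))) - target_rate

    lo, hi = -50.0, 50.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def closure_probabilities(model: TrueModel, covariates: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Per-site closure probabilities and the (possibly calibrated) intercept."""
    eta0 = linear_predictor(model, covariates, intercept=0.0)
    if model.intercept is None:
        intercept = calibrate_intercept(eta0, model.target_rate)
    else:
        intercept = model.intercept
    return expit(intercept + eta0), intercept


_REQUIRED_COVARIATES = (
    "live_births",
    "has_pediatrics",
    "ownership",
    "teaching",
    "density_category",
    "fertility_rate",
    "min_interfacility_time",
)


def simulate_closures(
    registry: Sequence[HospitalRecord],
    covariates: pd.DataFrame,
    true_model: TrueModel,
    seed: int,
) -> tuple[np.ndarray, list[HospitalRecord]]:
    """Draw independent closure flags and derive the follow-up registry.

    ``covariates`` must hold one row per registry record (matched by
    ``site_id``) with every model covariate populated. Closed sites keep their
    record in the follow-up year but lose the obstetrics department and all
    birth procedures; open sites keep both (the generator simulates department
    closures only — whole-hospital closures are a feature of real registries).
    """
    cov = covariates.set_index("site_id") if "site_id" in covariates else covariates
    for col in _REQUIRED_COVARIATES:
        if col not in cov.columns:
            raise ValueError(f"missing covariate column {col!r}")
    missing_ids = [rec.site_id for rec in registry if rec.site_id not in cov.index]
    if missing_ids:
        raise ValueError(f"site {missing_ids[0]}: no covariate row")
    ordered = cov.loc[[rec.site_id for rec in registry]].reset_index()
    na_mask = ordered[list(_REQUIRED_COVARIATES)].isna()
    if na_mask.to_numpy().any():
        row_idx = int(np.where(na_mask.any(axis=1))[0][0])
        col = na_mask.columns[int(np.where(na_mask.iloc[row_idx])[0][0])]
        raise ValueError(
            f"site {registry[row_idx].site_id}: missing covariate {col!r}"
        )
    probs, _ = closure_probabilities(true_model, ordered)
    rng = np.random.default_rng(seed)
    closed = rng.random(len(registry)) < probs

    followup = []
    for rec, is_closed in zip(registry, closed):
        if is_closed:
            departments = frozenset(rec.departments - OBSTETRICS_DEPT_CODES) or frozenset({"0100"})
            procedures = {
                c: n for c, n in rec.procedures.items() if c not in LIVE_BIRTH_CODES
            }
        else:
            departments = rec.departments
            procedures = dict(rec.procedures)
        followup.append(
            replace(
                rec,
                year=FOLLOWUP_YEAR,
                departments=departments,
                procedures=procedures,
            )
        )
    return closed, followup


# ---------------------------------------------------------------------------
# One-call cohort simulation (the fast path for replicate experiments)
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: RegionConfig,
    model: TrueModel,
    seed: int,
    network: RoadNetwork | None = None,
) -> pd.DataFrame:
    """Generate one regression-ready cohort DataFrame under the true model.

    A network is generated from the config unless one is supplied (replicate
    experiments reuse a fixed network and redraw sites/attributes/outcomes).
    """
    cfg = replace(config, seed=seed)
    if network is None:
        network = generate_network(cfg)
    registry, areas = place_hospitals(network, cfg)
    attrs = dict(zip(areas["postal_area"], zip(areas["density_raw"], areas["fertility_rate"])))

    site_nodes = {rec.site_id: rec.location for rec in registry}
    min_times = min_interfacility_time(network, site_nodes)

    rows = []
    for rec in registry:
        density_raw, fertility = attrs[rec.postal_area]
        rows.append(
            {
                "site_id": rec.site_id,
                "live_births": sum(
                    n for c, n in rec.procedures.items() if c in LIVE_BIRTH_CODES
                ),
                "has_pediatrics": bool(rec.departments & PEDIATRICS_DEPT_CODES),
                "ownership": rec.ownership,
                "teaching": rec.teaching,
                "density_raw": density_raw,
                "density_category": categorize_density(density_raw),
                "fertility_rate": fertility,
                "min_interfacility_time": min_times[rec.site_id],
            }
        )
    frame = pd.DataFrame(rows)
    child_seed = int(np.random.SeedSequence([seed, 2]).generate_state(1)[0] % (2**31))
    closed, _ = simulate_closures(registry, frame, model, seed=child_seed)
    frame["closed_by_followup"] = closed
    return frame
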