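"""From coded hospital registries to the closure-analysis cohort.

This module turns two reporting-year registries of hospital sites into the
analysis cohort used by the closure model:

* identify obstetric sites (obstetrics/gynecology department *and* at least one
  documented live birth, coded via the OPS 9-262 subsection),
* link the two years on the stable site id and flag departments closed by the
  follow-up year, distinguishing whole-hospital closures,
* derive the covariates: live births per year, pediatrics availability,
  ownership, teaching status, population-density and fertility categories, and
  the competition covariate (minimal car travel time to the nearest other
  obstetric site on the road network),
* apply the regression exclusions (university hospitals, whole-hospital
  closures).

All functions are deterministic: re-running on the same inputs is bit-identical.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import TIME_ATTR, RoadNetwork

#: OPS codes documenting measures accompanying birth; their counts proxy the
#: annual number of live births at a site.
LIVE_BIRTH_CODES = frozenset({"9-262", "9-262.0", "9-262.1", "9-262.x", "9-262.y"})

#: Specialist-department codes counting as obstetrics and/or gynecology.
OBSTETRICS_DEPT_CODES = frozenset({"2400", "2500"})

#: Specialist-department codes counting as pediatrics.
PEDIATRICS_DEPT_CODES = frozenset({"1000"})

#: Facility types that never provide inpatient obstetric services.
EXCLUDED_FACILITY_TYPES = frozenset({"day_care", "rehabilitation"})

_OPS_CODE_RE = re.compile(r"^\d-\d{2,3}(\.[0-9a-z]{1,2})?$")

BASELINE_YEAR = 2014
FOLLOWUP_YEAR = 2019

OWNERSHIP_LEVELS = ("nonprofit", "public", "private")
TEACHING_LEVELS = ("no", "yes", "university")
DENSITY_LEVELS = ("low", "medium", "high")
FERTILITY_LEVELS = ("low", "medium", "high")

#: Density cutpoints (inhabitants/km²): low ≤ 100 < medium ≤ 1000 < high.
#: The published three-tier classification leaves (500, 1000] unassigned; the
#: medium band is extended to 1000 so the categories partition the domain.
DENSITY_CUTPOINTS = (100.0, 1000.0)

#: Fertility cutpoints (children/woman): low ≤ 1.3 < medium ≤ 1.6 < high.
FERTILITY_CUTPOINTS = (1.3, 1.6)


@dataclass
class HospitalRecord:
    """One hospital site in one reporting year, as coded in a registry."""

    site_id: str
    year: int
    location: object  # road-network node id
    postal_area: str
    departments: frozenset[str]
    procedures: dict[str, int]
    ownership: str
    teaching: str
    whole_hospital_closed: bool = False
    facility_type: str = "acute"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be nonempty")
        if self.ownership not in OWNERSHIP_LEVELS:
            raise ValueError(f"unknown ownership {self.ownership!r} for site {self.site_id}")
        if self.teaching not in TEACHING_LEVELS:
            raise ValueError(f"unknown teaching status {self.teaching!r} for site {self.site_id}")
        for code, count in self.procedures.items():
            if count < 0:
                raise ValueError(f"negative procedure count for {code!r} at site {self.site_id}")


@dataclass
class CohortRow:
    """Linked two-year analysis unit: one baseline obstetric site."""

    site_id: str
    live_births: int
    has_pediatrics: bool
    ownership: str
    teaching: str
    density_raw: float
    density_category: str
    fertility_rate: float
    fertility_category: str
    min_interfacility_time: float
    closed_by_followup: bool
    total_hospital_closure: bool
    location: object = None
    postal_area: str | None = None

    def __post_init__(self) -> None:
        if self.live_births < 1:
            raise ValueError(
                f"site {self.site_id}: obstetric cohort rows require live_births >= 1"
            )
        if self.density_category != categorize_density(self.density_raw):
            raise ValueError(
                f"site {self.site_id}: density_category inconsistent with density_raw"
            )


def count_live_births(record: HospitalRecord) -> int:
    """Live births documented at a site: sum of counts over the OPS 9-262 codes.

    Codes outside the listed subsection contribute nothing; malformed code
    strings are skipped with a warning.
    """
    total = 0
    for code, count in record.procedures.items():
        if not _OPS_CODE_RE.match(code):
            warnings.warn(
                f"site {record.site_id}: malformed procedure code {code!r} skipped",
                stacklevel=2,
            )
            continue
        if code in LIVE_BIRTH_CODES:
            total += int(count)
    return total


def is_obstetric_site(record: HospitalRecord) -> bool:
    if record.facility_type in EXCLUDED_FACILITY_TYPES:
        return False
    if not (record.departments & OBSTETRICS_DEPT_CODES):
        return False
    return count_live_births(record) >= 1


def identify_obstetric_sites(registry: Iterable[HospitalRecord]) -> list[HospitalRecord]:
    """Keep sites with an obstetrics/gynecology department and ≥1 documented live birth.

    Day-care and rehabilitation facilities are excluded regardless of coding.
    """
    return [rec for rec in registry if is_obstetric_site(rec)]


def categorize_density(density_raw: float) -> str:
    """Three-tier population-density category (inhabitants/km²).

    low ≤ 100; medium in (100, 1000]; high > 1000. Boundaries are closed on
    the left category, matching the published "≤" rules.
    """
    if density_raw < 0 or not math.isfinite(density_raw):
        raise ValueError(f"population density must be finite and >= 0, got {density_raw}")
    if density_raw <= DENSITY_CUTPOINTS[0]:
        return "low"
    if density_raw <= DENSITY_CUTPOINTS[1]:
        return "medium"
    return "high"


def categorize_fertility(rate: float) -> str:
    """Three-tier fertility category (children/woman): ≤1.3, (1.3, 1.6], >1.6."""
    if not (rate > 0) or not math.isfinite(rate):
        raise ValueError(f"fertility rate must be finite and > 0, got {rate}")
    if rate <= FERTILITY_CUTPOINTS[0]:
        return "low"
    if rate <= FERTILITY_CUTPOINTS[1]:
        return "medium"
    return "high"


def min_interfacility_time(
    network: RoadNetwork, site_nodes: Mapping[str, object]
) -> dict[str, float]:
    """Minimal travel time (minutes) from each site to the nearest *other* site.

    Exact single-sweep algorithm: one multi-source Dijkstra from all site nodes
    yields each node's graph-Voronoi cell and its distance to the nearest site;
    for every edge crossing a cell boundary the quantity
    ``d(site_a, u) + w(u, v) + d(site_b, v)`` is an upper bound on the
    site-to-site distance and the minimum over boundary edges adjacent to a
    cell is exactly that site's nearest-other-site distance. Sites unreachable
    from every other site get ``+inf`` with a warning.
    """
    items = list(site_nodes.items())
    if len(items) == 0:
        return {}
    if len(items) == 1:
        sid = items[0][0]
        warnings.warn(f"single obstetric site {sid}: no other site reachable", stacklevel=2)
        return {sid: math.inf}

    g = network.graph
    node_to_sites: dict[object, list[str]] = {}
    for sid, node in items:
        if node not in g:
            raise ValueError(f"site {sid}: node {node!r} not in network")
        node_to_sites.setdefault(node, []).append(sid)

    result: dict[str, float] = {}
    # Co-located sites are each other's nearest neighbor at distance 0.
    for node, sids in node_to_sites.items():
        if len(sids) > 1:
            for sid in sids:
                result[sid] = 0.0

    centers = set(node_to_sites)
    best: dict[object, float] = {c: math.inf for c in centers}
    if len(centers) == 1:
        # All sites co-located: already handled above.
        pass
    else:
        cells = nx.voronoi_cells(g, centers, weight=TIME_ATTR)
        dist = nx.multi_source_dijkstra_path_length(g, centers, weight=TIME_ATTR)
        label: dict[object, object] = {}
        for center, cell in cells.items():
            if center == "unreachable":
                continue
            for v in cell:
                label[v] = center
        for u, v, w in g.edges(data=TIME_ATTR):
            lu, lv = label.get(u), label.get(v)
            if lu is None or lv is None or lu == lv:
                continue
            cand = dist[u] + w + dist[v]
            if cand < best[lu]:
                best[lu] = cand
            if cand < best[lv]:
                best[lv] = cand

    for node, sids in node_to_sites.items():
        for sid in sids:
            if sid in result:
                continue
            t = best[node]
            if math.isinf(t):
                warnings.warn(
                    f"site {sid}: unreachable from every other obstetric site", stacklevel=2
                )
            result[sid] = t
    return {sid: result[sid] for sid, _ in items}


def _check_unique_site_ids(registry: Sequence[HospitalRecord], year_label: str) -> None:
    seen: set[str] = set()
    for rec in registry:
        if rec.site_id in seen:
            raise ValueError(f"duplicate site_id {rec.site_id!r} in {year_label} registry")
        seen.add(rec.site_id)


def build_closure_cohort(
    baseline_registry: Sequence[HospitalRecord],
    followup_registry: Sequence[HospitalRecord],
    area_attributes: Mapping[str, tuple[float, float]],
    network: RoadNetwork | None = None,
    followup_full_registry: Sequence[HospitalRecord] | None = None,
) -> list[CohortRow]:
    """Link the two obstetric registries into one cohort row per baseline site.

    ``closed_by_followup`` is true iff the site is absent from the follow-up
    obstetric set. ``total_hospital_closure`` is true iff the site vanished
    entirely from the follow-up full registry (or carries the whole-closure
    flag there); pass ``followup_full_registry`` (before obstetric filtering)
    to distinguish department closures from whole-hospital closures.

    ``area_attributes`` maps postal area code → (population density in
    inhabitants/km², fertility rate in children/woman).
    """
    _check_unique_site_ids(baseline_registry, "baseline")
    _check_unique_site_ids(followup_registry, "follow-up")

    followup_obstetric_ids = {rec.site_id for rec in followup_registry}
    if followup_full_registry is not None:
        followup_all_ids = {rec.site_id for rec in followup_full_registry}
        whole_closed_flagged = {
            rec.site_id for rec in followup_full_registry if rec.whole_hospital_closed
        }
    else:
        followup_all_ids = {rec.site_id for rec in followup_registry}
        whole_closed_flagged = set()

    if network is not None:
        site_nodes = {rec.site_id: rec.location for rec in baseline_registry}
        min_times = min_interfacility_time(network, site_nodes)
    else:
        min_times = {rec.site_id: math.nan for rec in baseline_registry}

    rows: list[CohortRow] = []
    for rec in baseline_registry:
        for field_name in ("postal_area", "ownership", "teaching"):
            if not getattr(rec, field_name):
                raise ValueError(f"site {rec.site_id}: missing covariate field {field_name!r}")
        if rec.postal_area not in area_attributes:
            raise ValueError(
                f"site {rec.site_id}: no area attributes for postal area {rec.postal_area!r}"
            )
        density_raw, fertility = area_attributes[rec.postal_area]
        closed = rec.site_id not in followup_obstetric_ids
        total = closed and (
            rec.site_id not in followup_all_ids or rec.site_id in whole_closed_flagged
        )
        rows.append(
            CohortRow(
                site_id=rec.site_id,
                live_births=count_live_births(rec),
                has_pediatrics=bool(rec.departments & PEDIATRICS_DEPT_CODES),
                ownership=rec.ownership,
                teaching=rec.teaching,
                density_raw=float(density_raw),
                density_category=categorize_density(float(density_raw)),
                fertility_rate=float(fertility),
                fertility_category=categorize_fertility(float(fertility)),
                min_interfacility_time=float(min_times[rec.site_id]),
                closed_by_followup=closed,
                total_hospital_closure=total,
                location=rec.location,
                postal_area=rec.postal_area,
            )
        )
    return rows


def apply_exclusions(cohort: Sequence[CohortRow]) -> tuple[list[CohortRow], dict[str, int]]:
    """Drop university hospitals and whole-hospital closures before modelling.

    Returns the regression cohort and an exclusion log with the funnel counts.
    """
    kept: list[CohortRow] = []
    n_university = 0
    n_total_closure = 0
    for row in cohort:
        if row.teaching == "university":
            n_university += 1
            continue
        if row.total_hospital_closure:
            n_total_closure += 1
            continue
        kept.append(row)
    log = {
        "input_rows": len(cohort),
        "excluded_university": n_university,
        "excluded_total_closure": n_total_closure,
        "regression_rows": len(kept),
    }
    if not kept:
        warnings.warn("exclusions removed every cohort row", stacklevel=2)
    return kept, log


def cohort_frame(cohort: Sequence[CohortRow]) -> pd.DataFrame:
    """Cohort rows as a DataFrame with ordered categorical covariates."""
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in cohort],
            "live_births": [r.live_births for r in cohort],
            "has_pediatrics": [r.has_pediatrics for r in cohort],
            "ownership": pd.Categorical(
                [r.ownership for r in cohort], categories=list(OWNERSHIP_LEVELS)
            ),
            "teaching": pd.Categorical(
                [r.teaching for r in cohort], categories=list(TEACHING_LEVELS)
            ),
            "density_category": pd.Categorical(
                [r.density_category for r in cohort], categories=list(DENSITY_LEVELS)
            ),
            "density_raw": [r.density_raw for r in cohort],
            "fertility_rate": [r.fertility_rate for r in cohort],
            "fertility_category": pd.Categorical(
                [r.fertility_category for r in cohort], categories=list(FERTILITY_LEVELS)
            ),
            "min_interfacility_time": [r.min_interfacility_time for r in cohort],
            "closed_by_followup": [r.closed_by_followup for r in cohort],
            "total_hospital_closure": [r.total_hospital_closure for r in cohort],
        }
    )
    return df


def closure_share_by_birth_band(
    cohort: Sequence[CohortRow],
    band: tuple[float, float] = (900.0, 1200.0),
) -> dict[str, float]:
    """Share (%) of each pediatrics stratum that closed with births inside ``band``.

    Denominators are the stratum sizes in the full baseline cohort (inclusive
    band boundaries).
    """
    lo, hi = band
    out: dict[str, float] = {}
    for has_ped, key in ((True, "pediatrics"), (False, "no_pediatrics")):
        stratum = [r for r in cohort if r.has_pediatrics == has_ped]
        if not stratum:
            out[key] = math.nan
            continue
        closed_in_band = sum(
            1 for r in stratum if r.closed_by_followup and lo <= r.live_births <= hi
        )
        out[key] = 100.0 * closed_in_band / len(stratum)
    return out


# ---------------------------------------------------------------------------
# Descriptive statistics (year-on-year comparison tables)
# ---------------------------------------------------------------------------


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p (unequal variances)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def chi_squared_test(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-squared on a contingency table, no continuity correction.

    Returns (statistic, p, reliable); ``reliable`` is False when any expected
    cell count is zero (degenerate margin) or below 1.
    """
    table = np.asarray(table, float)
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    reliable = bool((expected >= 1.0).all())
    if (expected == 0).any():
        # Drop degenerate margins to keep the statistic defined, flag as unreliable.
        keep_r = expected.sum(axis=1) > 0
        keep_c = expected.sum(axis=0) > 0
        table = table[np.ix_(keep_r, keep_c)]
        reliable = False
    if table.shape[0] < 2 or table.shape[1] < 2 or (table == table[0, 0]).all():
        # Constant table: statistic 0 by convention.
        return 0.0, 1.0, reliable
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), reliable


def descriptive_table(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    continuous: Sequence[str] = ("live_births", "min_interfacility_time"),
    categorical: Sequence[str] = ("ownership", "has_pediatrics", "teaching", "density_category"),
) -> pd.DataFrame:
    """Two-group descriptive summary with Welch t (continuous) and Pearson
    chi-squared (categorical) group tests.

    Returns one row per variable with medians/IQRs, means/min/max or category
    counts and percentages, plus the test statistic and p-value.
    """
    rows = []
    for var in continuous:
        a = group_a[var].dropna().to_numpy(float)
        b = group_b[var].dropna().to_numpy(float)
        t, p = welch_t_test(a, b)
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                "a_median": float(np.median(a)),
                "a_q25": float(np.percentile(a, 25)),
                "a_q75": float(np.percentile(a, 75)),
                "a_mean": float(np.mean(a)),
                "a_min": float(np.min(a)),
                "a_max": float(np.max(a)),
                "b_median": float(np.median(b)),
                "b_q25": float(np.percentile(b, 25)),
                "b_q75": float(np.percentile(b, 75)),
                "b_mean": float(np.mean(b)),
                "b_min": float(np.min(b)),
                "b_max": float(np.max(b)),
                "test": "welch_t",
                "statistic": t,
                "p_value": p,
                "reliable": True,
            }
        )
    for var in categorical:
        counts_a = group_a[var].value_counts()
        counts_b = group_b[var].value_counts()
        levels = sorted(set(counts_a.index) | set(counts_b.index), key=str)
        table = np.array(
            [[counts_a.get(lv, 0) for lv in levels], [counts_b.get(lv, 0) for lv in levels]],
            dtype=float,
        ).T
        stat, p, reliable = chi_squared_test(table)
        for lv in levels:
            na, nb = int(counts_a.get(lv, 0)), int(counts_b.get(lv, 0))
            rows.append(
                {
                    "variable": f"{var}={lv}",
                    "kind": "categorical",
                    "a_count": na,
                    "a_pct": 100.0 * na / max(len(group_a), 1),
                    "b_count": nb,
                    "b_pct": 100.0 * nb / max(len(group_b), 1),
                    "test": "chi_squared",
                    "statistic": stat,
                    "p_value": p,
                    "reliable": reliable,
                }
            )
    return pd.DataFrame(rows)


def funnel_statistics(
    baseline_obstetric: Sequence[HospitalRecord],
    followup_obstetric: Sequence[HospitalRecord],
    cohort: Sequence[CohortRow],
    regression_cohort: Sequence[CohortRow],
    exclusion_log: Mapping[str, int],
) -> dict[str, float]:
    """Cohort-arithmetic summary of the operationalization funnel.

    All shares are percentages on the printed scale (e.g. 11.38 for 11.38%).
    """
    n_base = len(baseline_obstetric)
    n_follow = len(followup_obstetric)
    n_closed = sum(r.closed_by_followup for r in cohort)
    n_total_closures = sum(r.total_hospital_closure for r in cohort)
    births_base = [count_live_births(r) for r in baseline_obstetric]
    births_follow = [count_live_births(r) for r in followup_obstetric]
    med_base = float(np.median(births_base)) if births_base else math.nan
    med_follow = float(np.median(births_follow)) if births_follow else math.nan
    ped_base = sum(1 for r in baseline_obstetric if r.departments & PEDIATRICS_DEPT_CODES)
    ped_follow = sum(1 for r in followup_obstetric if r.departments & PEDIATRICS_DEPT_CODES)
    band_shares = closure_share_by_birth_band(cohort)
    return {
        "baseline_obstetric_sites": n_base,
        "followup_obstetric_sites": n_follow,
        "department_closures": n_closed,
        "total_hospital_closures": n_total_closures,
        "closure_share_pct": 100.0 * n_closed / n_base if n_base else math.nan,
        "regression_rows": exclusion_log["regression_rows"],
        "excluded_university": exclusion_log["excluded_university"],
        "excluded_total_closure": exclusion_log["excluded_total_closure"],
        "regression_closure_events": sum(r.closed_by_followup for r in regression_cohort),
        "pediatrics_share_baseline_pct": 100.0 * ped_base / n_base if n_base else math.nan,
        "pediatrics_share_followup_pct": 100.0 * ped_follow / n_follow if n_follow else math.nan,
        "median_births_baseline": med_base,
        "median_births_followup": med_follow,
        "median_births_change_pct": 100.0 * (med_follow - med_base) / med_base,
        "band_closure_share_pediatrics_pct": band_shares["pediatrics"],
        "band_closure_share_no_pediatrics_pct": band_shares["no_pediatrics"],
    }
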