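#!/usr/bin/env python
"""Generate the synthetic study region and write its registries.

Builds the default region (702 obstetric sites on a 650x870 km planar road
network), simulates closures from the published-effect preset, and writes
registries, area attributes, and the network under results/region/.
"""

from pathlib import Path


from obstaccess import fileio
from obstaccess.operationalize import (
    build_closure_cohort,
    cohort_frame,
    identify_obstetric_sites,
)
from obstaccess.synthetic_region import (
    RegionConfig,
    final_model_preset,
    generate_network,
    place_hospitals,
    simulate_closures,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "region"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RegionConfig(seed=SEED)
    network = generate_network(cfg)
    registry, areas_df = place_hospitals(network, cfg)
    areas = {
        str(r["postal_area"]): (float(r["density_raw"]), float(r["fertility_rate"]))
        for _, r in areas_df.iterrows()
    }
    cohort = build_closure_cohort(registry, registry, areas, network=network)
    frame = cohort_frame(cohort)
    closed, followup = simulate_closures(registry, frame, final_model_preset(), seed=SEED)

    fileio.write_registry(registry, OUT / "registry_baseline.csv")
    fileio.write_registry(followup, OUT / "registry_followup.csv")
    fileio.write_areas(areas, OUT / "areas.csv")
    fileio.write_network_csv(network, OUT / "network_nodes.csv", OUT / "network_edges.csv")
    fileio.write_network_geojson(network, OUT / "network.geojson")

    n_follow = len(identify_obstetric_sites(followup))
    print(f"region: {network.n_nodes} nodes, {network.n_edges} edges, seed {SEED}")
    print(f"baseline obstetric sites: {len(registry)}")
    print(f"simulated closures: {int(closed.sum())} ({100 * closed.mean():.2f}%)")
    print(f"follow-up obstetric sites: {n_follow}")
    print("ownership shares (%):")
    print((frame["ownership"].value_counts(normalize=True) * 100).round(2).to_string())
    print(
        "live births median (IQR): "
        f"{frame['live_births'].median():.0f} "
        f"({frame['live_births'].quantile(0.25):.0f}, {frame['live_births'].quantile(0.75):.0f})"
    )
    mt = frame["min_interfacility_time"]
    print(
        "nearest-competitor time median (IQR): "
        f"{mt.median():.1f} ({mt.quantile(0.25):.2f}, {mt.quantile(0.75):.2f}) min"
    )
    print(f"artifacts written to {OUT}")


if __name__ == "__main__":
    main()
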