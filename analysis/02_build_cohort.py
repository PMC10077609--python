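#!/usr/bin/env python
"""Run the operationalization funnel on the synthetic benchmark registries.

The benchmark registry pair reproduces the published cohort margins; this
script runs identification -> linkage -> exclusions on it and writes the
funnel statistics (counts, shares, median live-birth change) to
results/funnel.csv.
"""

from pathlib import Path

import pandas as pd

from obstaccess.synthetic_benchmark import build_benchmark_region, run_benchmark_funnel

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    region = build_benchmark_region()
    funnel = run_benchmark_funnel(region)

    pd.Series(funnel).rename("value").to_csv(OUT / "funnel.csv")

    print(f"registry records: baseline {len(region.baseline_registry)}, "
          f"follow-up {len(region.followup_registry)}")
    print(f"obstetric sites: baseline {funnel['baseline_obstetric_sites']:.0f}, "
          f"follow-up {funnel['followup_obstetric_sites']:.0f}")
    print(f"department closures: {funnel['department_closures']:.0f} "
          f"({funnel['closure_share_pct']:.2f}%), of which "
          f"{funnel['total_hospital_closures']:.0f} whole-hospital closures")
    print(f"regression sample: {funnel['regression_rows']:.0f} sites after excluding "
          f"{funnel['excluded_university']:.0f} university hospitals and "
          f"{funnel['excluded_total_closure']:.0f} whole-hospital closures; "
          f"{funnel['regression_closure_events']:.0f} closure events")
    print(f"pediatrics on site: {funnel['pediatrics_share_baseline_pct']:.2f}% -> "
          f"{funnel['pediatrics_share_followup_pct']:.2f}%")
    print(f"median live births: {funnel['median_births_baseline']:.0f} -> "
          f"{funnel['median_births_followup']:.0f} "
          f"({funnel['median_births_change_pct']:+.2f}%)")
    print(f"closures with 900-1,200 births: {funnel['band_closure_share_pediatrics_pct']:.2f}% "
          f"of the pediatrics stratum, {funnel['band_closure_share_no_pediatrics_pct']:.2f}% "
          f"of the no-pediatrics stratum")
    print(f"funnel table written to {OUT / 'funnel.csv'}")


if __name__ == "__main__":
    main()
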