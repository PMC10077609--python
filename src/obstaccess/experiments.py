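"""Replicate experiments: parameter recovery, model selection, calibration.

The published site-level registry is confidential, so the regression
estimates cannot be reproduced number-for-number; what can be checked is
that the whole estimation pipeline *recovers* a known truth. This module
simulates many cohorts from the generating closure model, refits the full
logistic model on each, runs backward stepwise AIC, and aggregates:

* 95% Wald CI coverage of every nonzero generating coefficient,
* term retention/drop frequencies of the stepwise selection,
* whether the final model's AIC improves on the full model's,
* the realized closure rate (calibration target 10.26%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .closure_model import (
    RegressionSpec,
    backward_stepwise_aic,
    fit_logistic,
    LogisticFitError,
)
from .network import RoadNetwork
from .synthetic_region import (
    RegionConfig,
    TrueModel,
    final_model_preset,
    generate_network,
    simulate_cohort,
)

#: Generating coefficient → design-matrix column recovering it.
EFFECT_COLUMNS = {
    "beta_births": "live_births",
    "beta_pediatrics": "has_pediatrics[True]",
    "beta_density_medium": "density_category[medium]",
    "beta_density_high": "density_category[high]",
    "beta_fertility": "fertility_rate",
    "beta_mintime": "min_interfacility_time",
    "beta_ownership_nonprofit": "ownership[nonprofit]",
    "beta_ownership_public": "ownership[public]",
    "beta_teaching_yes": "teaching[yes]",
}

#: Terms the generating preset gives real effects / null effects.
SIGNAL_TERMS = ("has_pediatrics", "density_category", "live_births", "min_interfacility_time")
NULL_TERMS = ("ownership", "teaching")


@dataclass
class RecoveryResult:
    n_replicates: int
    n_fitted: int
    n_failed: int
    coverage: dict[str, float]  # beta name -> CI coverage fraction
    mean_odds_ratio: dict[str, float]  # beta name -> mean fitted OR
    retain_frequency: dict[str, float]  # term -> stepwise retention fraction
    final_aic_le_full: int  # replicates where final AIC <= full AIC
    closure_rates: np.ndarray = field(repr=False, default=None)

    @property
    def mean_closure_rate(self) -> float:
        return float(np.mean(self.closure_rates))


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seed sequence derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_recovery(
    n_replicates: int = 200,
    seed: int = 1,
    config: RegionConfig | None = None,
    model: TrueModel | None = None,
    spec: RegressionSpec | None = None,
    network: RoadNetwork | None = None,
    run_stepwise: bool = True,
) -> RecoveryResult:
    """Simulate → fit → select, replicated; aggregate recovery diagnostics.

    One road network is generated up front and reused; sites, attributes,
    travel times, and outcomes are redrawn per replicate.
    """
    config = config if config is not None else RegionConfig()
    model = model if model is not None else final_model_preset()
    spec = spec if spec is not None else RegressionSpec()
    if network is None:
        network = generate_network(config)

    effects = model.nonzero_effects()
    covered = {name: 0 for name in effects}
    or_sum = {name: 0.0 for name in effects}
    retained = {t.name: 0 for t in spec.terms}
    n_fitted = 0
    n_failed = 0
    final_le_full = 0
    rates = []

    for rep_seed in replicate_seeds(seed, n_replicates):
        cohort = simulate_cohort(config, model, seed=rep_seed, network=network)
        rates.append(float(cohort["closed_by_followup"].mean()))
        try:
            full = fit_logistic(cohort, spec)
        except LogisticFitError:
            n_failed += 1
            continue
        n_fitted += 1
        tab = full.table.set_index("column")
        for name, true_beta in effects.items():
            col = EFFECT_COLUMNS[name]
            row = tab.loc[col]
            lo = row["coef"] - 1.959963984540054 * row["se"]
            hi = row["coef"] + 1.959963984540054 * row["se"]
            if lo <= true_beta <= hi:
                covered[name] += 1
            or_sum[name] += row["odds_ratio"]
        if run_stepwise:
            final, _ = backward_stepwise_aic(cohort, spec)
            for term in final.term_names:
                retained[term] += 1
            if final.aic <= full.aic + 1e-9:
                final_le_full += 1

    denom = max(n_fitted, 1)
    return RecoveryResult(
        n_replicates=n_replicates,
        n_fitted=n_fitted,
        n_failed=n_failed,
        coverage={k: covered[k] / denom for k in effects},
        mean_odds_ratio={k: or_sum[k] / denom for k in effects},
        retain_frequency={k: retained[k] / denom for k in retained},
        final_aic_le_full=final_le_full,
        closure_rates=np.asarray(rates),
    )
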