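"""End-to-end analysis: cohorts -> thresholds -> gates -> per-donor statistics.

Thresholds are estimated once per donor on the fresh, unstimulated sample and
frozen for that donor's cryopreserved/stimulated states, mirroring how the
same manual gates would be applied before and after a perturbation — and
preventing CD16 shedding from silently moving the CD16 gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError
from .metrics import SubsetStats, donor_table, subset_stats
from .panel import Panel, default_panel
from .populations import CohortConfig, default_perturbations, population_specs_for
from .simulate import apply_perturbation, donor_configs_for, sample_donor
from .strategies import CLEAN, apply_strategy, builtin_strategies
from .thresholds import estimate_table_thresholds

FRESH = "fresh"
#: deterministic per-state offsets for perturbation RNG streams
_STATE_SEED_OFFSET = {"cryopreservation": 101, "stim_K562": 202, "stim_IL12_IL18": 303}

DEFAULT_STRATEGIES = (
    "cd16", "nkp80", "cd7_cd16", "cd7_only", "cd300a", "tb4", "quadrants", "cd56dim",
    "cd16_cd123excl", "nkp80_cd123excl", "cd300a_cd123excl", "tb4_cd123excl",
    "nk_reference",
)

#: states computed per condition by default (cryopreservation only for HD)
def default_states(condition: str) -> tuple[str, ...]:
    if condition == "HD":
        return (FRESH, "cryopreservation", "stim_K562", "stim_IL12_IL18")
    return (FRESH, "stim_K562", "stim_IL12_IL18")


@dataclass
class AnalysisResult:
    stats: pd.DataFrame  # long table, see metrics.STATS_COLUMNS
    manifest: dict = field(default_factory=dict)


def analyze_donor(donor_config,
                  population_specs,
                  panel: Panel,
                  strategies: dict,
                  states: tuple[str, ...]) -> list[SubsetStats]:
    """All statistics rows for one donor across its states."""
    perturbations = default_perturbations()
    fresh = sample_donor(donor_config, population_specs, panel)
    model = estimate_table_thresholds(fresh)  # frozen across states

    rows: list[SubsetStats] = []
    registry = builtin_strategies()
    nk_ref_strategy = registry["nk_reference"]
    for state in states:
        if state == FRESH:
            table = fresh
        else:
            if state not in perturbations:
                raise ConfigurationError(f"unknown state {state!r}")
            seed = (donor_config.seed + _STATE_SEED_OFFSET[state]) % (2 ** 31)
            table = apply_perturbation(fresh, perturbations[state],
                                       population_specs, seed=seed)
        nk_ref = apply_strategy(table, nk_ref_strategy, model)["nk_reference"]
        for name, strategy in strategies.items():
            membership = apply_strategy(table, strategy, model)
            for sub in strategy.subsets:
                rows.append(subset_stats(
                    table, membership, sub.name, sub.parent or CLEAN, model,
                    donor_id=donor_config.donor_id, condition=donor_config.condition,
                    state=state, strategy=name, nk_reference=nk_ref))
    return rows


def run_analysis(conditions=("HD",),
                 n_donors: int = 20,
                 n_events: int = 50_000,
                 seed: int = 42,
                 abundance_jitter: float | None = 20_000.0,
                 strategy_names=DEFAULT_STRATEGIES,
                 states_for=default_states,
                 panel: Panel | None = None) -> AnalysisResult:
    """Run the full pipeline over one or more condition cohorts.

    Donors are processed one at a time and discarded, so memory stays flat in
    cohort size.  Per-condition master seeds are offset from ``seed`` so that
    cohorts are independent but jointly reproducible.
    """
    panel = panel or default_panel()
    registry = builtin_strategies()
    unknown = [s for s in strategy_names if s not in registry]
    if unknown:
        raise ConfigurationError(f"unknown strategies: {unknown}")
    strategies = {s: registry[s] for s in strategy_names}

    all_rows: list[SubsetStats] = []
    manifest: dict = {"master_seed": seed, "n_donors": n_donors,
                      "n_events": n_events, "conditions": {}}
    for ci, condition in enumerate(conditions):
        specs = population_specs_for(condition)
        cfg = CohortConfig(condition=condition, n_donors=n_donors,
                           n_events=n_events, seed=(seed + 1000 * ci) % (2 ** 31),
                           abundance_jitter=abundance_jitter)
        states = tuple(states_for(condition))
        donor_cfgs = donor_configs_for(cfg)
        manifest["conditions"][condition] = {
            "master_seed": cfg.seed, "states": list(states),
            "donor_seeds": [dc.seed for dc in donor_cfgs],
        }
        for dc in donor_cfgs:
            all_rows.extend(analyze_donor(dc, specs, panel, strategies, states))
    return AnalysisResult(stats=donor_table(all_rows), manifest=manifest)
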