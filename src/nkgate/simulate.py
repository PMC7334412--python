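"""Synthetic cohort generation.

Draws whole stained-PBMC samples from the population templates in
:mod:`nkgate.populations`: each event gets a population label, a forward
scatter value, and per-marker fluorescence drawn Gaussian on the
arcsinh-transformed scale and mapped back to the raw scale.  Perturbations
(cryopreservation, K562 or IL-12+IL-18 stimulation) act on an existing table
without touching event counts or truth labels: multiplicative MFI shifts,
stochastic CD16 shedding of susceptible (NK) events, and induction of
functional-marker positivity.

Everything is deterministic given the configuration and seeds; per-donor
seeds are derived from a cohort master seed via ``numpy`` seed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PanelMismatchError
from .events import EventTable
from .panel import (
    CD16, CD107A, EOMES, FLUORESCENCE, FSC, DEFAULT_COFACTOR, Panel, default_panel,
)
from .populations import (
    STATE_PARAMS, CohortConfig, DonorConfig, PerturbationSpec, PopulationSpec,
    population_specs_for, validate_populations,
)
from .transform import inverse_transform


def _jittered_abundances(specs: list[PopulationSpec],
                         jitter: float | None,
                         rng: np.random.Generator) -> np.ndarray:
    base = np.array([p.abundance for p in specs], dtype=float)
    if jitter is None:
        return base
    alpha = np.maximum(base * float(jitter), 1e-9)
    drawn = rng.dirichlet(alpha)
    return drawn / drawn.sum()


def sample_donor(donor: DonorConfig,
                 population_specs: list[PopulationSpec],
                 panel: Panel | None = None,
                 *,
                 cofactor: float = DEFAULT_COFACTOR,
                 n_events_override: int | None = None) -> EventTable:
    """Draw one donor's event table with truth labels.

    ``n_events_override`` permits an empty table (0 events); the donor config
    itself must request at least one event.
    """
    panel = panel or default_panel()
    validate_populations(population_specs)
    for p in population_specs:
        unknown = [m for m in p.marker_states if not panel.has_marker(m)]
        if unknown:
            raise PanelMismatchError(
                f"population {p.name!r} references markers not in panel: {unknown}")
    n = donor.n_events if n_events_override is None else n_events_override
    if n_events_override is None and donor.n_events < 1:
        raise ValueError("n_events must be >= 1")
    if n < 0:
        raise ValueError("n_events must be >= 0")

    rng = np.random.default_rng(donor.seed)
    abundances = _jittered_abundances(population_specs, donor.abundance_jitter, rng)
    pop_idx = rng.choice(len(population_specs), size=n, p=abundances)

    names = np.array([p.name for p in population_specs])
    state_loc = {s: v[0] for s, v in STATE_PARAMS.items()}
    state_scale = {s: v[1] for s, v in STATE_PARAMS.items()}

    columns: dict[str, np.ndarray] = {}
    # scatter
    fsc_loc = np.array([p.fsc_location for p in population_specs])[pop_idx]
    fsc_scale = np.array([p.fsc_scale for p in population_specs])[pop_idx]
    columns[panel.channel_for(FSC).channel_id] = rng.normal(fsc_loc, fsc_scale)

    # Eomes truth drawn first so the Eomes channel can match it
    eomes_p = np.array([p.eomes_pos_prob for p in population_specs])[pop_idx]
    eomes_truth = (rng.random(n) < eomes_p).astype(np.int8)

    for ch in panel:
        if ch.role != FLUORESCENCE:
            continue
        if ch.marker == EOMES:
            loc = np.where(eomes_truth == 1, state_loc["pos"], state_loc["neg"])
            scale = np.where(eomes_truth == 1, state_scale["pos"], state_scale["neg"])
        else:
            states = [p.state_of(ch.marker) for p in population_specs]
            loc = np.array([state_loc[s] for s in states])[pop_idx]
            scale = np.array([state_scale[s] for s in states])[pop_idx]
        transformed = rng.normal(loc, scale)
        columns[ch.channel_id] = inverse_transform(transformed, cofactor)

    data = pd.DataFrame(columns, columns=[c.channel_id for c in panel])
    truth = pd.DataFrame({"population": names[pop_idx] if n else np.array([], dtype=str),
                          "eomes_truth": eomes_truth})
    meta = {
        "donor_id": donor.donor_id,
        "condition": donor.condition,
        "seed": donor.seed,
        "cofactor": cofactor,
        "resolved_abundances": dict(zip(names.tolist(), abundances.tolist())),
    }
    return EventTable(data, panel, truth, meta=meta)


def apply_perturbation(table: EventTable,
                       spec: PerturbationSpec,
                       population_specs: list[PopulationSpec],
                       seed: int = 0,
                       *,
                       cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    """Return a perturbed copy of ``table``; the input is untouched.

    Order of operations: multiplicative MFI scaling, functional-marker
    induction (when the spec stimulates), then CD16 shedding of susceptible
    events (responding CD107a+ events shed with doubled probability).
    """
    if table.truth is None:
        raise ValueError("perturbations require truth labels")
    panel = table.panel
    for marker in spec.mfi_scale:
        if not panel.has_marker(marker):
            raise PanelMismatchError(f"mfi_scale references unknown marker {marker!r}")

    out = table.copy()
    rng = np.random.default_rng(seed)
    by_name = {p.name: p for p in population_specs}
    pop = out.truth["population"].to_numpy()
    n = out.n_events

    for marker, factor in spec.mfi_scale.items():
        ch = panel.channel_for(marker)
        out.data[ch.channel_id] = out.data[ch.channel_id] * factor

    state_loc = {s: v[0] for s, v in STATE_PARAMS.items()}
    state_scale = {s: v[1] for s, v in STATE_PARAMS.items()}

    responders: dict[str, np.ndarray] = {}
    if spec.response_induction:
        if spec.stimulus is None:
            raise ConfigurationError("response_induction requires a stimulus name")
        from .panel import FUNCTIONAL_MARKERS
        for marker in FUNCTIONAL_MARKERS:
            probs = np.array([by_name[p].response_prob(spec.stimulus, marker) for p in pop]) \
                if n else np.zeros(0)
            resp = rng.random(n) < probs
            responders[marker] = resp
            if resp.any():
                ch = panel.channel_for(marker)
                vals = out.data[ch.channel_id].to_numpy()
                k = int(resp.sum())
                vals[resp] = inverse_transform(
                    rng.normal(state_loc["pos"], state_scale["pos"], size=k), cofactor)
                out.data[ch.channel_id] = vals

    if spec.shed_fraction > 0 and n:
        susceptible = np.array([by_name[p].cd16_shed_susceptible for p in pop])
        prob = np.where(susceptible, spec.shed_fraction, 0.0)
        cd107a_resp = responders.get(CD107A)
        if cd107a_resp is not None:
            prob = np.where(cd107a_resp, np.minimum(1.0, 2 * prob), prob)
        shed = rng.random(n) < prob
        if shed.any():
            ch = panel.channel_for(CD16)
            vals = out.data[ch.channel_id].to_numpy()
            k = int(shed.sum())
            vals[shed] = inverse_transform(
                rng.normal(state_loc["neg"], state_scale["neg"], size=k), cofactor)
            out.data[ch.channel_id] = vals

    out.meta["perturbation"] = spec.kind
    out._tcache.clear()
    return out


@dataclass
class CohortResult:
    donors: list[tuple[DonorConfig, EventTable]]
    manifest: dict


def donor_seeds(master_seed: int, n_donors: int) -> list[int]:
    """Reproducible per-donor seeds (< 2**31) derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
            for child in ss.spawn(n_donors)]


def donor_configs_for(config: CohortConfig) -> list[DonorConfig]:
    if config.n_donors < 1:
        raise ConfigurationError("n_donors must be >= 1")
    if config.n_events < 1:
        raise ConfigurationError("n_events must be >= 1")
    seeds = donor_seeds(config.seed, config.n_donors)
    return [
        DonorConfig(
            donor_id=f"{config.condition}_{i + 1:02d}", condition=config.condition,
            n_events=config.n_events, abundance_jitter=config.abundance_jitter,
            seed=seeds[i])
        for i in range(config.n_donors)
    ]


def iter_cohort(config: CohortConfig, panel: Panel | None = None):
    """Yield ``(DonorConfig, EventTable)`` one donor at a time (memory-friendly)."""
    panel = panel or default_panel()
    specs = population_specs_for(config.condition, config.abundance_overrides or None)
    for dc in donor_configs_for(config):
        yield dc, sample_donor(dc, specs, panel)


def build_cohort(config: CohortConfig, panel: Panel | None = None) -> CohortResult:
    """Materialize a full cohort plus a manifest of resolved parameters."""
    panel = panel or default_panel()
    specs = population_specs_for(config.condition, config.abundance_overrides or None)
    donors = list(iter_cohort(config, panel))
    manifest = {
        "condition": config.condition,
        "n_donors": config.n_donors,
        "n_events": config.n_events,
        "master_seed": config.seed,
        "abundance_jitter": config.abundance_jitter,
        "configured_abundances": {p.name: p.abundance for p in specs},
        "donors": [
            {"donor_id": dc.donor_id, "seed": dc.seed,
             "resolved_abundances": table.meta["resolved_abundances"]}
            for dc, table in donors
        ],
    }
    return CohortResult(donors=donors, manifest=manifest)
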