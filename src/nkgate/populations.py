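"""Generative parameters: populations, donors, cohorts, perturbations.

The synthetic cohort emulates a stained PBMC sample.  Each population is a
template with one expression state per marker (``neg`` / ``pos`` / ``high``),
an abundance, a forward-scatter size, an Eomes-positivity probability and
per-stimulus functional response probabilities.  Intensities are Gaussian on
the arcsinh-transformed scale and mapped back to the raw scale, the standard
two-state picture of a well-compensated fluorescence channel.

The healthy-donor composition is calibrated so that the automated gates
reproduce the few quantitative anchors known for this system: the
CD56neg NKp80+ gate contains ~20% Eomes-negative (ILC-like) events, about
half of it co-expresses CD16, the CD56neg CD16+NKp80- quadrant is ~50%
CD123+ (pDC/basophil contamination), and NK cells make up 5-15% of viable
lymphocytes.  Disease presets expand the CD56neg NK compartment (largest in
untreated HIV infection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigurationError
from .panel import (
    CD3, CD7, CD14, CD16, CD19, CD56, CD107A, CD123, CD300A,
    IFNG, NKP80, TB4, TNF, VIABILITY,
)

#: (location, scale) of each expression state on the arcsinh-transformed scale.
STATE_PARAMS: dict[str, tuple[float, float]] = {
    "neg": (0.0, 0.25),
    "pos": (3.0, 0.4),
    "high": (4.8, 0.3),
}

K562 = "K562"
IL12_IL18 = "IL12_IL18"
STIMULI = (K562, IL12_IL18)

LYMPHOID = "lymphoid"
MYELOID = "myeloid"
DEAD = "dead"


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    abundance: float
    marker_states: dict[str, str] = field(default_factory=dict)  # markers absent -> "neg"
    fsc_location: float = 60000.0
    fsc_scale: float = 7000.0
    eomes_pos_prob: float = 0.0
    response_probs: dict[tuple[str, str], float] = field(default_factory=dict)
    cd16_shed_susceptible: bool = False
    lineage: str = LYMPHOID
    is_nk: bool = False

    def state_of(self, marker: str) -> str:
        return self.marker_states.get(marker, "neg")

    def response_prob(self, stimulus: str, marker: str) -> float:
        return self.response_probs.get((stimulus, marker), 0.0)


@dataclass(frozen=True)
class DonorConfig:
    donor_id: str
    condition: str = "HD"
    n_events: int = 50_000
    abundance_jitter: float | None = 20_000.0  # Dirichlet concentration; None = no jitter
    seed: int = 0


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str  # cryopreservation | stim_K562 | stim_IL12_IL18
    mfi_scale: dict[str, float] = field(default_factory=dict)
    shed_fraction: float = 0.0
    response_induction: bool = False
    stimulus: str | None = None

    def __post_init__(self):
        for marker, f in self.mfi_scale.items():
            if not f > 0:
                raise ConfigurationError(f"mfi_scale for {marker} must be > 0")
        if not 0.0 <= self.shed_fraction <= 1.0:
            raise ConfigurationError("shed_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    condition: str = "HD"
    n_donors: int = 20
    n_events: int = 50_000
    seed: int = 42
    abundance_jitter: float | None = 20_000.0
    abundance_overrides: dict[str, float] = field(default_factory=dict)


def validate_populations(specs: list[PopulationSpec], tol: float = 1e-9) -> None:
    total = sum(p.abundance for p in specs)
    if abs(total - 1.0) > tol:
        raise ConfigurationError(f"population abundances sum to {total!r}, expected 1")
    for p in specs:
        if not 0.0 <= p.eomes_pos_prob <= 1.0:
            raise ConfigurationError(f"{p.name}: eomes_pos_prob outside [0, 1]")
        for key, prob in p.response_probs.items():
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError(f"{p.name}: response prob {key} outside [0, 1]")
    # pos location must exceed neg location (global state table)
    if STATE_PARAMS["pos"][0] <= STATE_PARAMS["neg"][0]:
        raise ConfigurationError("pos state location must exceed neg state location")


# functional response probabilities --------------------------------------------------

#: CD56dim NK cells: strong degranulation against K562, strong cytokines to IL-12+IL-18.
_DIM_RESPONSES = {
    (K562, CD107A): 0.45, (K562, IFNG): 0.25, (K562, TNF): 0.20,
    (IL12_IL18, CD107A): 0.15, (IL12_IL18, IFNG): 0.55, (IL12_IL18, TNF): 0.30,
}
#: CD56neg NK cells: hypofunctional relative to CD56dim but clearly responsive.
_NEG_RESPONSES = {
    (K562, CD107A): 0.25, (K562, IFNG): 0.12, (K562, TNF): 0.10,
    (IL12_IL18, CD107A): 0.08, (IL12_IL18, IFNG): 0.30, (IL12_IL18, TNF): 0.15,
}
_ILC_RESPONSES = {(s, m): 0.02 for s in STIMULI for m in (CD107A, IFNG, TNF)}


def hd_population_specs() -> list[PopulationSpec]:
    """Healthy-donor PBMC template (fractions of all acquired events)."""
    P = PopulationSpec
    specs = [
        P("Tcell", 0.45, {CD3: "pos", CD7: "pos", CD300A: "pos"}, eomes_pos_prob=0.25),
        P("Bcell", 0.08, {CD19: "pos", CD300A: "pos"}),
        P("Monocyte", 0.12, {CD14: "pos", CD16: "pos", CD300A: "pos"},
          fsc_location=90000.0, lineage=MYELOID),
        # CD123+ contaminants of the CD56neg CD16+ gate: large CD16+ Eomes- cells
        P("pDC", 0.007, {CD123: "pos", CD16: "pos", CD300A: "pos"},
          fsc_location=75000.0, lineage=MYELOID),
        P("Basophil", 0.008, {CD123: "pos", CD16: "pos", CD300A: "pos", TB4: "pos"},
          fsc_location=78000.0, lineage=MYELOID),
        P("NK_bright", 0.008,
          {CD56: "high", NKP80: "pos", CD7: "pos", CD300A: "pos", TB4: "pos"},
          fsc_location=62000.0, eomes_pos_prob=0.98, is_nk=True,
          response_probs=dict(_DIM_RESPONSES)),
        P("NK_dim_CD16pos", 0.072,
          {CD56: "pos", CD16: "pos", NKP80: "pos", CD7: "pos", CD300A: "pos", TB4: "pos"},
          eomes_pos_prob=0.98, is_nk=True, cd16_shed_susceptible=True,
          response_probs=dict(_DIM_RESPONSES)),
        P("NK_dim_CD16neg", 0.006,
          {CD56: "pos", NKP80: "pos", CD7: "pos", CD300A: "pos", TB4: "pos"},
          eomes_pos_prob=0.98, is_nk=True, response_probs=dict(_DIM_RESPONSES)),
        P("NK_neg_CD16pos", 0.00176,
          {CD16: "pos", NKP80: "pos", CD7: "pos", CD300A: "pos", TB4: "pos"},
          eomes_pos_prob=0.98, is_nk=True, cd16_shed_susceptible=True,
          response_probs=dict(_NEG_RESPONSES)),
        P("NK_neg_CD16neg", 0.00176,
          {NKP80: "pos", CD7: "pos", CD300A: "pos", TB4: "pos"},
          eomes_pos_prob=0.98, is_nk=True, response_probs=dict(_NEG_RESPONSES)),
        # ILC-like NKp80+ Eomes- cells: the irreducible impurity of the NKp80 gate
        P("ILC_NKp80pos_CD16pos", 0.00044,
          {CD16: "pos", NKP80: "pos", CD7: "pos", CD300A: "pos", TB4: "pos"},
          fsc_location=62000.0, response_probs=dict(_ILC_RESPONSES)),
        P("ILC_NKp80pos_CD16neg", 0.00044,
          {NKP80: "pos", CD7: "pos", CD300A: "pos", TB4: "pos"},
          fsc_location=62000.0, response_probs=dict(_ILC_RESPONSES)),
        # CD16+ CD7- CD123- lymphoid contaminants (NKT-like / non-classical)
        P("OtherLymph_CD16pos", 0.015,
          {CD16: "pos", CD300A: "pos", TB4: "pos"}, fsc_location=70000.0),
        P("OtherLymph", 0.1796,
          {CD7: "pos", CD300A: "pos", TB4: "pos"}),
        P("Dead", 0.05, {VIABILITY: "pos"}, fsc_location=50000.0, lineage=DEAD),
    ]
    validate_populations(specs)
    return specs


#: Disease presets: multiplicative expansion of the true CD56neg NK populations.
CONDITION_CD56NEG_SCALE: dict[str, float] = {
    "HD": 1.0,
    "HIV_untreated": 12.0,
    "HIV_cART": 4.0,
    "MM": 4.0,
}

_CD56NEG_NK = ("NK_neg_CD16pos", "NK_neg_CD16neg")


def population_specs_for(condition: str,
                         overrides: dict[str, float] | None = None) -> list[PopulationSpec]:
    """Population templates for a condition preset.

    The CD56neg NK abundances are scaled by the preset factor and all
    abundances renormalized to 1.  ``overrides`` replaces abundances by
    population name before renormalization.
    """
    if condition not in CONDITION_CD56NEG_SCALE:
        raise ConfigurationError(
            f"unknown condition {condition!r}; expected one of {sorted(CONDITION_CD56NEG_SCALE)}")
    scale = CONDITION_CD56NEG_SCALE[condition]
    specs = []
    for p in hd_population_specs():
        ab = p.abundance * scale if p.name in _CD56NEG_NK else p.abundance
        if overrides and p.name in overrides:
            ab = overrides[p.name]
        specs.append(replace(p, abundance=ab))
    total = sum(p.abundance for p in specs)
    specs = [replace(p, abundance=p.abundance / total) for p in specs]
    validate_populations(specs)
    return specs


def default_perturbations() -> dict[str, PerturbationSpec]:
    """Cryopreservation and stimulation presets.

    CD16 is shed on activation (metalloproteinase-mediated) and reduced by
    freezing; NKp80 is stable under both.  Responding cells shed CD16
    preferentially (shedding probability doubled for CD107a+ events).
    """
    return {
        "cryopreservation": PerturbationSpec(
            "cryopreservation", mfi_scale={CD16: 0.55}, shed_fraction=0.25),
        "stim_K562": PerturbationSpec(
            "stim_K562", mfi_scale={CD16: 0.4}, shed_fraction=0.5,
            response_induction=True, stimulus=K562),
        "stim_IL12_IL18": PerturbationSpec(
            "stim_IL12_IL18", mfi_scale={CD16: 0.4}, shed_fraction=0.5,
            response_induction=True, stimulus=IL12_IL18),
    }
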