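"""Hierarchical gating strategies.

A strategy is a named rooted tree: an exclusion stage (dump channel: dead
cells and CD3/CD14/CD19-positive events, optionally CD123) followed by
subset-defining predicate nodes.  Predicates are Boolean combinations of
per-marker positivity (transformed value strictly above the channel cutoff;
ties classify negative) and CD56 region membership (neg / dim / bright from
the two CD56 cutoffs).  Child membership is by construction a subset of the
parent's.

The builtin registry covers the strategies compared in this package:

======================  =============================================
name                    subset definition (after exclusion)
======================  =============================================
``cd16``                CD56neg CD16+  (the classical gate)
``nkp80``               CD56neg NKp80+ (the proposed gate)
``cd7_cd16``            CD7+ CD56neg CD16+
``cd7_only``            CD56neg CD7+
``cd300a``              CD56neg CD300a+
``tb4``                 CD56neg 2B4+
``quadrants``           CD16 x NKp80 quadrants within CD56neg
``cd56dim``             CD56dim reference subset
``nk_reference``        NKp80+ or CD56+ ("total NK" denominator)
======================  =============================================

Every named strategy also exists in a ``*_cd123excl`` variant whose dump
channel additionally removes CD123+ events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError
from .events import EventTable
from .panel import (
    CD7, CD16, CD56, CD123, CD300A, EXCLUSION_MARKERS, NKP80, TB4,
)
from .thresholds import ThresholdModel

POSITIVE = "positive"
NEGATIVE = "negative"
CLEAN = "clean"  # name of the exclusion-stage root subset


# --- predicate AST -----------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    """Leaf: marker positivity/negativity against its cutoff."""
    marker: str
    polarity: str = POSITIVE


@dataclass(frozen=True)
class Region:
    """Leaf: three-way CD56-style region membership (neg | dim | bright)."""
    marker: str
    region: str


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


@dataclass(frozen=True)
class Not:
    child: object


def all_markers(node) -> set[str]:
    if isinstance(node, (Marker, Region)):
        return {node.marker}
    if isinstance(node, (And, Or)):
        return set().union(*(all_markers(c) for c in node.children)) if node.children else set()
    if isinstance(node, Not):
        return all_markers(node.child)
    raise TypeError(f"unknown gate node {node!r}")


def evaluate_node(node, table: EventTable, model: ThresholdModel) -> np.ndarray:
    """Vectorized evaluation of a predicate node over all events."""
    if isinstance(node, Marker):
        t = model[node.marker]
        values = table.transformed(node.marker, model.cofactor)
        pos = values > t.cutoff
        return pos if node.polarity == POSITIVE else ~pos
    if isinstance(node, Region):
        t = model[node.marker]
        if t.upper_cutoff is None:
            raise ConfigurationError(f"marker {node.marker!r} has no upper cutoff for regions")
        values = table.transformed(node.marker, model.cofactor)
        if node.region == "neg":
            return values <= t.cutoff
        if node.region == "dim":
            return (values > t.cutoff) & (values <= t.upper_cutoff)
        if node.region == "bright":
            return values > t.upper_cutoff
        raise ConfigurationError(f"unknown region {node.region!r}")
    if isinstance(node, And):
        out = np.ones(table.n_events, dtype=bool)
        for c in node.children:
            out &= evaluate_node(c, table, model)
        return out
    if isinstance(node, Or):
        out = np.zeros(table.n_events, dtype=bool)
        for c in node.children:
            out |= evaluate_node(c, table, model)
        return out
    if isinstance(node, Not):
        return ~evaluate_node(node.child, table, model)
    raise TypeError(f"unknown gate node {node!r}")


# --- strategies --------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetDef:
    name: str
    parent: str | None  # None -> child of the exclusion root
    predicate: object


@dataclass(frozen=True)
class GatingStrategy:
    name: str
    exclusion_markers: tuple = EXCLUSION_MARKERS
    subsets: tuple = field(default_factory=tuple)  # ordered SubsetDefs, parents first

    def referenced_markers(self) -> set[str]:
        markers = set(self.exclusion_markers)
        for s in self.subsets:
            markers |= all_markers(s.predicate)
        return markers

    @property
    def leaf(self) -> str:
        """Name of the last-defined subset (the strategy's subset of interest)."""
        return self.subsets[-1].name


def apply_strategy(table: EventTable,
                   strategy: GatingStrategy,
                   model: ThresholdModel) -> dict[str, np.ndarray]:
    """Evaluate a strategy; returns Boolean membership per subset name.

    The returned map always contains ``"clean"`` (events surviving the
    exclusion stage); every subset's membership is intersected with its
    parent's, so the nesting invariant holds by construction.
    """
    for marker in sorted(strategy.referenced_markers()):
        if marker not in model:
            raise ConfigurationError(
                f"strategy {strategy.name!r} needs a threshold for {marker!r}")
        table.panel.channel_for(marker)

    n = table.n_events
    clean = np.ones(n, dtype=bool)
    for marker in strategy.exclusion_markers:
        t = model[marker]
        clean &= ~(table.transformed(marker, model.cofactor) > t.cutoff)

    membership: dict[str, np.ndarray] = {CLEAN: clean}
    for sub in strategy.subsets:
        parent = membership[sub.parent] if sub.parent else clean
        membership[sub.name] = parent & evaluate_node(sub.predicate, table, model)
    return membership


# --- builtin registry --------------------------------------------------------------

CD56NEG = "cd56neg"

_QUADRANTS = (
    ("cd16pos_nkp80neg", And((Marker(CD16, POSITIVE), Marker(NKP80, NEGATIVE)))),
    ("cd16neg_nkp80pos", And((Marker(CD16, NEGATIVE), Marker(NKP80, POSITIVE)))),
    ("cd16pos_nkp80pos", And((Marker(CD16, POSITIVE), Marker(NKP80, POSITIVE)))),
    ("cd16neg_nkp80neg", And((Marker(CD16, NEGATIVE), Marker(NKP80, NEGATIVE)))),
)


def _cd56neg_strategy(name: str, predicate, leaf: str) -> GatingStrategy:
    return GatingStrategy(name, subsets=(
        SubsetDef(CD56NEG, None, Region(CD56, "neg")),
        SubsetDef(leaf, CD56NEG, predicate),
    ))


def builtin_strategies() -> dict[str, GatingStrategy]:
    """Registry of builtin strategies (standard and +CD123-exclusion variants)."""
    base: dict[str, GatingStrategy] = {
        "cd16": _cd56neg_strategy("cd16", Marker(CD16), "cd16pos"),
        "nkp80": _cd56neg_strategy("nkp80", Marker(NKP80), "nkp80pos"),
        "cd7_cd16": _cd56neg_strategy(
            "cd7_cd16", And((Marker(CD7), Marker(CD16))), "cd7pos_cd16pos"),
        "cd7_only": _cd56neg_strategy("cd7_only", Marker(CD7), "cd7pos"),
        "cd300a": _cd56neg_strategy("cd300a", Marker(CD300A), "cd300apos"),
        "tb4": _cd56neg_strategy("tb4", Marker(TB4), "tb4pos"),
        "quadrants": GatingStrategy("quadrants", subsets=(
            SubsetDef(CD56NEG, None, Region(CD56, "neg")),
            *(SubsetDef(name, CD56NEG, pred) for name, pred in _QUADRANTS),
        )),
        "cd56dim": GatingStrategy("cd56dim", subsets=(
            SubsetDef("cd56dim", None, Region(CD56, "dim")),
        )),
        "nk_reference": GatingStrategy("nk_reference", subsets=(
            SubsetDef("nk_reference", None,
                      Or((Marker(NKP80), Region(CD56, "dim"), Region(CD56, "bright")))),
        )),
    }
    registry = dict(base)
    for name, strat in base.items():
        registry[f"{name}_cd123excl"] = GatingStrategy(
            f"{name}_cd123excl",
            exclusion_markers=tuple(strat.exclusion_markers) + (CD123,),
            subsets=strat.subsets)
    return registry


def get_strategy(name: str) -> GatingStrategy:
    registry = builtin_strategies()
    if name not in registry:
        raise ConfigurationError(
            f"unknown strategy {name!r}; available: {sorted(registry)}")
    return registry[name]


# --- structured-text strategy definitions ------------------------------------------

def _node_from_dict(d) -> object:
    if not isinstance(d, dict) or len(d) != 1:
        raise ConfigurationError(f"malformed gate node: {d!r}")
    (kind, body), = d.items()
    if kind == "marker":
        return Marker(body["name"], body.get("polarity", POSITIVE))
    if kind == "region":
        return Region(body["name"], body["region"])
    if kind == "and":
        return And(tuple(_node_from_dict(c) for c in body))
    if kind == "or":
        return Or(tuple(_node_from_dict(c) for c in body))
    if kind == "not":
        return Not(_node_from_dict(body))
    raise ConfigurationError(f"unknown gate node kind {kind!r}")


def strategy_from_yaml(text: str) -> GatingStrategy:
    """Parse a strategy from YAML, so users can add strategies without code.

    Schema::

        name: my_gate
        exclusion: [Viability, CD3, CD14, CD19]
        subsets:
          - name: cd56neg
            predicate: {region: {name: CD56, region: neg}}
          - name: my_leaf
            parent: cd56neg
            predicate: {marker: {name: NKp80}}
    """
    doc = yaml.safe_load(text)
    subsets = tuple(
        SubsetDef(s["name"], s.get("parent"), _node_from_dict(s["predicate"]))
        for s in doc.get("subsets", []))
    return GatingStrategy(
        doc["name"],
        exclusion_markers=tuple(doc.get("exclusion", EXCLUSION_MARKERS)),
        subsets=subsets)
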