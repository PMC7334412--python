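import numpy as np
import pandas as pd
import pytest

from nkgate.errors import ConfigurationError
from nkgate.events import EventTable
from nkgate.panel import (
    CD3, CD16, CD56, CD123, NKP80, VIABILITY, default_panel,
)
from nkgate.strategies import (
    CLEAN, And, GatingStrategy, Marker, Not, Or, Region, SubsetDef,
    apply_strategy, builtin_strategies, get_strategy, strategy_from_yaml,
)
from nkgate.thresholds import Threshold, ThresholdModel
from nkgate.transform import inverse_transform

from conftest import tiny_table


def fixed_model(panel, cutoff=1.5, upper=4.0) -> ThresholdModel:
    model = ThresholdModel(cofactor=150.0)
    for ch in panel:
        if ch.role == "fluorescence":
            model.thresholds[ch.marker] = Threshold(
                cutoff, "mixture", (0.0, 3.0), 9.0,
                upper_cutoff=upper if ch.marker == CD56 else None)
    return model


# --- brute-force per-event interpreter (independent oracle) ------------------------

def eval_event_oracle(node, values: dict[str, float], model) -> bool:
    if isinstance(node, Marker):
        pos = values[node.marker] > model[node.marker].cutoff
        return pos if node.polarity == "positive" else not pos
    if isinstance(node, Region):
        t = model[node.marker]
        v = values[node.marker]
        if node.region == "neg":
            return v <= t.cutoff
        if node.region == "dim":
            return t.cutoff < v <= t.upper_cutoff
        return v > t.upper_cutoff
    if isinstance(node, And):
        return all(eval_event_oracle(c, values, model) for c in node.children)
    if isinstance(node, Or):
        return any(eval_event_oracle(c, values, model) for c in node.children)
    if isinstance(node, Not):
        return not eval_event_oracle(node.child, values, model)
    raise TypeError(node)


def strategy_oracle(table, strategy, model) -> dict:
    """Event-by-event strategy evaluation in plain Python."""
    out = {CLEAN: []}
    for s in strategy.subsets:
        out[s.name] = []
    for i in range(table.n_events):
        values = {m: float(table.transformed(m, model.cofactor)[i])
                  for m in table.panel.markers if m != "FSC-A"}
        values["FSC-A"] = float(table.marker("FSC-A")[i])
        clean = not any(values[m] > model[m].cutoff for m in strategy.exclusion_markers)
        out[CLEAN].append(clean)
        memb = {CLEAN: clean}
        for s in strategy.subsets:
            parent = memb[s.parent] if s.parent else clean
            memb[s.name] = parent and eval_event_oracle(s.predicate, values, model)
            out[s.name].append(memb[s.name])
    return {k: np.array(v, dtype=bool) for k, v in out.items()}


# --- hand-written examples ---------------------------------------------------------

def raw(t):  # transformed -> raw scale
    return inverse_transform(t, 150.0)


def test_six_event_table_matches_hand_enumeration(panel):
    # events: (Viability, CD3, CD56, CD16, NKp80) transformed values
    rows = [
        (0.0, 0.0, 0.0, 3.0, 0.0),   # clean, CD56neg, CD16+        -> cd16 gate
        (0.0, 0.0, 0.0, 0.0, 3.0),   # clean, CD56neg, NKp80+       -> not cd16 gate
        (3.0, 0.0, 0.0, 3.0, 0.0),   # dead                         -> excluded
        (0.0, 3.0, 0.0, 3.0, 0.0),   # T cell                       -> excluded
        (0.0, 0.0, 3.0, 3.0, 0.0),   # CD56dim                      -> not CD56neg
        (0.0, 0.0, 0.0, 1.5, 0.0),   # CD16 exactly at cutoff: tie -> negative
    ]
    table = tiny_table({
        VIABILITY: [raw(r[0]) for r in rows],
        CD3: [raw(r[1]) for r in rows],
        CD56: [raw(r[2]) for r in rows],
        CD16: [raw(r[3]) for r in rows],
        NKP80: [raw(r[4]) for r in rows],
    }, panel)
    model = fixed_model(panel)
    membership = apply_strategy(table, get_strategy("cd16"), model)
    assert membership[CLEAN].tolist() == [True, True, False, False, True, True]
    assert membership["cd56neg"].tolist() == [True, True, False, False, False, True]
    assert membership["cd16pos"].tolist() == [True, False, False, False, False, False]


def test_viability_positive_event_in_no_subset(panel):
    table = tiny_table({VIABILITY: [raw(3.0)], NKP80: [raw(3.0)]}, panel)
    model = fixed_model(panel)
    for name in ("cd16", "nkp80", "quadrants", "cd56dim"):
        membership = apply_strategy(table, get_strategy(name), model)
        for subset, mask in membership.items():
            assert not mask.any(), (name, subset)


def test_empty_table(panel):
    table = tiny_table({CD16: []}, panel)
    membership = apply_strategy(table, get_strategy("nkp80"), fixed_model(panel))
    assert all(len(v) == 0 for v in membership.values())


def test_missing_threshold_raises(panel):
    model = fixed_model(panel)
    del model.thresholds[NKP80]
    table = tiny_table({CD16: [0.0]}, panel)
    with pytest.raises(ConfigurationError, match="NKp80"):
        apply_strategy(table, get_strategy("nkp80"), model)


# --- registry ----------------------------------------------------------------------

def test_registry_contents():
    registry = builtin_strategies()
    for name in ("cd16", "nkp80", "cd7_cd16", "cd7_only", "cd300a", "tb4",
                 "quadrants", "cd56dim"):
        assert name in registry
        assert f"{name}_cd123excl" in registry
        assert CD123 in registry[f"{name}_cd123excl"].exclusion_markers
        assert CD123 not in registry[name].exclusion_markers


def test_nkp80_strategy_structure():
    strat = get_strategy("nkp80")
    assert strat.subsets[0].predicate == Region(CD56, "neg")
    assert strat.subsets[1].predicate == Marker(NKP80, "positive")
    assert strat.subsets[1].parent == "cd56neg"


def test_unknown_strategy():
    with pytest.raises(ConfigurationError):
        get_strategy("no_such_gate")


# --- invariants --------------------------------------------------------------------

def _random_table(rng, panel, n):
    data = {ch.channel_id: inverse_transform(rng.normal(1.5, 1.5, n), 150.0)
            if ch.role == "fluorescence" else rng.normal(60_000, 10_000, n)
            for ch in panel}
    return EventTable(pd.DataFrame(data, columns=[c.channel_id for c in panel]), panel)


def test_quadrants_partition_cd56neg(panel):
    rng = np.random.default_rng(17)
    table = _random_table(rng, panel, 500)
    model = fixed_model(panel)
    m = apply_strategy(table, get_strategy("quadrants"), model)
    quads = [m["cd16pos_nkp80neg"], m["cd16neg_nkp80pos"],
             m["cd16pos_nkp80pos"], m["cd16neg_nkp80neg"]]
    union = np.zeros(table.n_events, dtype=bool)
    for i, q in enumerate(quads):
        for other in quads[i + 1:]:
            assert not (q & other).any()  # pairwise disjoint
        union |= q
    assert (union == m["cd56neg"]).all()  # exact partition


def test_child_subset_of_parent_on_random_tables(panel):
    rng = np.random.default_rng(29)
    model = fixed_model(panel)
    registry = builtin_strategies()
    for _ in range(25):
        table = _random_table(rng, panel, int(rng.integers(1, 200)))
        for strat in registry.values():
            m = apply_strategy(table, strat, model)
            for s in strat.subsets:
                parent = m[s.parent] if s.parent else m[CLEAN]
                assert not (m[s.name] & ~parent).any()


def test_vectorized_matches_oracle_on_small_tables(panel):
    """Strategy evaluation equals a per-event interpreter on random tables."""
    rng = np.random.default_rng(31)
    model = fixed_model(panel)
    registry = builtin_strategies()
    names = ["cd16", "nkp80", "quadrants", "cd56dim", "nk_reference",
             "cd16_cd123excl", "cd7_cd16"]
    for trial in range(60):
        table = _random_table(rng, panel, int(rng.integers(0, 51)))
        strat = registry[names[trial % len(names)]]
        got = apply_strategy(table, strat, model)
        want = strategy_oracle(table, strat, model)
        for k in want:
            assert (got[k] == want[k]).all(), (strat.name, k)


def test_strategy_from_yaml():
    text = """
name: custom
exclusion: [Viability, CD3]
subsets:
  - name: cd56neg
    predicate: {region: {name: CD56, region: neg}}
  - name: leaf
    parent: cd56neg
    predicate:
      and:
        - {marker: {name: NKp80}}
        - {not: {marker: {name: CD16}}}
"""
    strat = strategy_from_yaml(text)
    assert strat.name == "custom"
    assert strat.exclusion_markers == (VIABILITY, CD3)
    assert strat.subsets[1].predicate == And((Marker(NKP80, "positive"),
                                              Not(Marker(CD16, "positive"))))
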