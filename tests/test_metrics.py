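import math

import numpy as np
import pandas as pd
import pytest

from nkgate.metrics import (
    STATS_COLUMNS, SubsetStats, donor_table, mfi, pct_positive, subset_frequency,
    subset_stats, write_stats_csv,
)
from nkgate.panel import CD123, EOMES
from nkgate.strategies import CLEAN, apply_strategy, get_strategy
from nkgate.thresholds import Threshold, ThresholdModel
from nkgate.transform import inverse_transform

from conftest import tiny_table


def test_subset_frequency_arithmetic():
    parent = np.zeros(20, bool)
    parent[:12] = True
    subset = np.zeros(20, bool)
    subset[:3] = True
    assert subset_frequency(subset, parent) == 25.0
    assert subset_frequency(parent, parent) == 100.0


def test_subset_frequency_empty_parent_is_nan_not_zero():
    out = subset_frequency(np.zeros(5, bool), np.zeros(5, bool))
    assert math.isnan(out)


def test_subset_frequency_requires_nesting():
    with pytest.raises(ValueError):
        subset_frequency(np.array([True, False]), np.array([False, True]))


def _eomes_model():
    model = ThresholdModel(cofactor=150.0)
    model.thresholds[EOMES] = Threshold(1.5, "mixture", (0.0, 3.0), 9.0)
    model.thresholds[CD123] = Threshold(1.5, "mixture", (0.0, 3.0), 9.0)
    return model


def test_pct_positive_from_intensities(panel):
    values = inverse_transform(np.r_[np.full(8, 3.0), np.full(2, 0.0)], 150.0)
    table = tiny_table({EOMES: values}, panel)
    membership = np.ones(10, bool)
    assert pct_positive(table, membership, EOMES, _eomes_model()) == 80.0


def test_pct_positive_prefers_truth_labels(panel):
    values = inverse_transform(np.full(10, 3.0), 150.0)  # all above cutoff
    table = tiny_table({EOMES: values}, panel)
    table.truth = pd.DataFrame({"population": ["x"] * 10,
                                "eomes_truth": [1] * 6 + [0] * 4})
    assert pct_positive(table, np.ones(10, bool), EOMES, _eomes_model()) == 60.0


def test_pct_positive_empty_membership_is_nan(panel):
    table = tiny_table({EOMES: [100.0]}, panel)
    assert math.isnan(pct_positive(table, np.zeros(1, bool), EOMES, _eomes_model()))


def test_mfi_is_median(panel):
    table = tiny_table({"CD16": [1.0, 2.0, 3.0]}, panel)
    assert mfi(table, np.ones(3, bool), "CD16") == 2.0
    assert math.isnan(mfi(table, np.zeros(3, bool), "CD16"))


def test_donor_table_cardinality_and_schema():
    rows = [SubsetStats(donor_id=f"d{d}", condition="HD", state="fresh",
                        strategy=s, subset="leaf", n_events=10)
            for d in range(2) for s in ("a", "b")]
    df = donor_table(rows)
    assert len(df) == 4
    assert list(df.columns) == STATS_COLUMNS


def test_stats_csv_deterministic(tmp_path):
    rows = [SubsetStats(donor_id="d", condition="HD", state="fresh",
                        strategy="a", subset="leaf", n_events=3,
                        freq_of_parent=12.345678)]
    df = donor_table(rows)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_stats_csv(df, p1)
    write_stats_csv(df, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert "12.3457" in p1.read_text()  # 4-decimal serialization


def test_quadrant_frequencies_sum_to_100(small_donor, small_model):
    m = apply_strategy(small_donor, get_strategy("quadrants"), small_model)
    total = sum(subset_frequency(m[q], m["cd56neg"])
                for q in ("cd16pos_nkp80neg", "cd16neg_nkp80pos",
                          "cd16pos_nkp80pos", "cd16neg_nkp80neg"))
    assert total == pytest.approx(100.0, abs=1e-9)


def test_statistics_invariant_under_row_permutation(small_donor, small_model):
    strat = get_strategy("nkp80")
    m = apply_strategy(small_donor, strat, small_model)
    row = subset_stats(small_donor, m, "nkp80pos", "cd56neg", small_model,
                       donor_id="d", condition="HD", state="fresh", strategy="nkp80")

    rng = np.random.default_rng(0)
    perm = rng.permutation(small_donor.n_events)
    shuffled = small_donor.copy()
    shuffled.data = shuffled.data.iloc[perm].reset_index(drop=True)
    shuffled.truth = shuffled.truth.iloc[perm].reset_index(drop=True)
    m2 = apply_strategy(shuffled, strat, small_model)
    row2 = subset_stats(shuffled, m2, "nkp80pos", "cd56neg", small_model,
                        donor_id="d", condition="HD", state="fresh", strategy="nkp80")
    for col in ("n_events", "freq_of_parent", "pct_eomes_pos", "mfi_nkp80", "fsc_median"):
        a, b = getattr(row, col), getattr(row2, col)
        assert a == pytest.approx(b, nan_ok=True), col


def test_eomes_truth_and_intensity_cutoff_agree(small_donor, small_model):
    """Truth-label purity and cutoff-based purity within 3 points (separation)."""
    m = apply_strategy(small_donor, get_strategy("nkp80"), small_model)
    member = m["nkp80pos"]
    by_truth = pct_positive(small_donor, member, EOMES, small_model)
    by_cutoff = pct_positive(small_donor, member, EOMES, small_model,
                             use_truth_for_eomes=False)
    assert abs(by_truth - by_cutoff) <= 3.0
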