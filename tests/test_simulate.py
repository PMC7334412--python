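import numpy as np
import pandas as pd
import pytest

from nkgate.errors import ConfigurationError, PanelMismatchError
from nkgate.panel import CD16, CD56, NKP80, default_panel
from nkgate.populations import (
    STATE_PARAMS, CohortConfig, DonorConfig, PerturbationSpec, PopulationSpec,
    default_perturbations, hd_population_specs, population_specs_for,
)
from nkgate.simulate import apply_perturbation, build_cohort, sample_donor
from nkgate.transform import arcsinh_transform, inverse_transform


def _single_pop_specs(**kwargs):
    spec = PopulationSpec("only", 1.0,
                          {CD56: "pos", CD16: "pos", NKP80: "high"}, **kwargs)
    return [spec]


def test_empty_table_keeps_metadata(hd_specs, panel):
    dc = DonorConfig("d0", seed=1, n_events=1000)
    table = sample_donor(dc, hd_specs, panel, n_events_override=0)
    assert table.n_events == 0
    assert list(table.data.columns) == [c.channel_id for c in panel]
    assert len(table.truth) == 0
    assert table.meta["donor_id"] == "d0"


def test_single_population_marker_medians_match_direct_sampling(panel):
    """Sampled marker medians agree (3 SEM) with direct draws from the stated law."""
    n = 1000
    dc = DonorConfig("d1", seed=7, n_events=n, abundance_jitter=None)
    table = sample_donor(dc, _single_pop_specs(), panel)
    assert (table.truth["population"] == "only").all()

    oracle = np.random.default_rng(999)
    for marker, state in [(CD56, "pos"), (CD16, "pos"), (NKP80, "high"), ("CD3", "neg")]:
        loc, scale = STATE_PARAMS[state]
        direct = inverse_transform(oracle.normal(loc, scale, 200_000), 150.0)
        sem = 1.2533 * np.std(arcsinh_transform(table.marker(marker), 150.0)) / np.sqrt(n)
        got = np.median(arcsinh_transform(table.marker(marker), 150.0))
        want = np.median(arcsinh_transform(direct, 150.0))
        assert abs(got - want) <= 3 * sem


def test_nk_fraction_of_viable_lymphocytes(hd_specs, panel):
    dc = DonorConfig("d42", seed=42, n_events=50_000)
    table = sample_donor(dc, hd_specs, panel)
    by_name = {p.name: p for p in hd_specs}
    lab = table.truth["population"]
    lymph = lab.map(lambda name: by_name[name].lineage == "lymphoid")
    nk = lab.map(lambda name: by_name[name].is_nk)
    frac = nk.sum() / lymph.sum()
    assert 0.05 <= frac <= 0.15


def test_determinism(hd_specs, panel):
    dc = DonorConfig("d", seed=11, n_events=2000)
    t1 = sample_donor(dc, hd_specs, panel)
    t2 = sample_donor(dc, hd_specs, panel)
    pd.testing.assert_frame_equal(t1.data, t2.data)
    pd.testing.assert_frame_equal(t1.truth, t2.truth)


def test_unknown_population_marker_raises(panel):
    bad = [PopulationSpec("only", 1.0, {"CD999": "pos"})]
    with pytest.raises(PanelMismatchError, match="CD999"):
        sample_donor(DonorConfig("d", seed=1, n_events=100), bad, panel)


def test_negative_event_count_raises(hd_specs, panel):
    with pytest.raises(ValueError):
        sample_donor(DonorConfig("d", seed=1, n_events=0), hd_specs, panel)


def test_truth_abundances_recovered_without_jitter(hd_specs, panel):
    """Pooled truth fractions within 3 binomial SD of configured abundances."""
    n_donors, n_events = 10, 20_000
    counts = {}
    for i in range(n_donors):
        dc = DonorConfig(f"d{i}", seed=100 + i, n_events=n_events, abundance_jitter=None)
        table = sample_donor(dc, hd_specs, panel)
        for name, k in table.truth["population"].value_counts().items():
            counts[name] = counts.get(name, 0) + k
    total = n_donors * n_events
    for p in hd_specs:
        sd = np.sqrt(p.abundance * (1 - p.abundance) / total)
        assert abs(counts.get(p.name, 0) / total - p.abundance) <= 3 * sd, p.name


def test_marker_state_separation(panel):
    """P(raw intensity above the state midpoint | pos) >= 0.95 by direct sampling."""
    rng = np.random.default_rng(3)
    loc_neg, _ = STATE_PARAMS["neg"]
    loc_pos, scale_pos = STATE_PARAMS["pos"]
    midpoint = inverse_transform((loc_neg + loc_pos) / 2, 150.0)
    pos_draws = inverse_transform(rng.normal(loc_pos, scale_pos, 100_000), 150.0)
    assert np.mean(pos_draws > midpoint) >= 0.95


# --- perturbations -----------------------------------------------------------------

def test_identity_perturbation_is_noop(small_donor, hd_specs):
    spec = PerturbationSpec("identity")
    out = apply_perturbation(small_donor, spec, hd_specs, seed=1)
    pd.testing.assert_frame_equal(out.data, small_donor.data)
    pd.testing.assert_frame_equal(out.truth, small_donor.truth)


def test_mfi_scale_halves_cd16_median(small_donor, hd_specs):
    spec = PerturbationSpec("halve", mfi_scale={CD16: 0.5})
    out = apply_perturbation(small_donor, spec, hd_specs, seed=1)
    ratio = np.median(out.marker(CD16)) / np.median(small_donor.marker(CD16))
    assert ratio == pytest.approx(0.5, rel=1e-9)


def test_cryopreservation_lowers_cd16_not_nkp80(small_donor, hd_specs):
    cryo = default_perturbations()["cryopreservation"]
    out = apply_perturbation(small_donor, cryo, hd_specs, seed=5)
    nk = small_donor.population_mask("NK_dim_CD16pos")
    assert np.median(out.marker(CD16)[nk]) < np.median(small_donor.marker(CD16)[nk])
    assert np.median(out.marker(NKP80)) == pytest.approx(
        np.median(small_donor.marker(NKP80)))


def test_perturbation_preserves_counts_and_labels(small_donor, hd_specs):
    stim = default_perturbations()["stim_K562"]
    out = apply_perturbation(small_donor, stim, hd_specs, seed=5)
    assert out.n_events == small_donor.n_events
    pd.testing.assert_frame_equal(out.truth, small_donor.truth)
    # and the input itself is untouched
    assert np.median(small_donor.marker(CD16)) > np.median(out.marker(CD16))


def test_unknown_mfi_marker_raises(small_donor, hd_specs):
    with pytest.raises(PanelMismatchError):
        apply_perturbation(small_donor, PerturbationSpec("x", mfi_scale={"CD999": 0.5}),
                           hd_specs, seed=1)


# --- cohorts -----------------------------------------------------------------------

def test_cohort_determinism():
    cfg = CohortConfig(condition="HD", n_donors=2, n_events=500, seed=9)
    c1, c2 = build_cohort(cfg), build_cohort(cfg)
    for (_, t1), (_, t2) in zip(c1.donors, c2.donors):
        pd.testing.assert_frame_equal(t1.data, t2.data)
    assert c1.manifest == c2.manifest


def test_cohort_degenerate_configs():
    with pytest.raises(ConfigurationError):
        build_cohort(CohortConfig(n_donors=0))
    with pytest.raises(ConfigurationError):
        population_specs_for("not_a_condition")


def test_condition_presets_expand_cd56neg():
    abundances = {}
    for cond in ("HD", "HIV_untreated", "HIV_cART", "MM"):
        specs = {p.name: p.abundance for p in population_specs_for(cond)}
        abundances[cond] = specs["NK_neg_CD16pos"] + specs["NK_neg_CD16neg"]
    assert abundances["HIV_untreated"] > abundances["HIV_cART"] > abundances["HD"]
    assert abundances["HIV_cART"] == pytest.approx(abundances["MM"])


def test_hiv_cohort_has_more_cd56neg_nk_than_hd():
    by_name = {p.name: p for p in hd_population_specs()}

    def mean_cd56neg_frac(condition, seed):
        cfg = CohortConfig(condition=condition, n_donors=8, n_events=5000, seed=seed)
        fracs = []
        for _, table in build_cohort(cfg).donors:
            lab = table.truth["population"]
            nk = lab.map(lambda n: by_name[n].is_nk)
            neg = lab.isin(["NK_neg_CD16pos", "NK_neg_CD16neg"])
            fracs.append(neg.sum() / max(nk.sum(), 1))
        return np.mean(fracs)

    assert mean_cd56neg_frac("HIV_untreated", 42) > mean_cd56neg_frac("HD", 42)
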