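"""Figure-analog tables: the package's claims, recomputed on synthetic cohorts.

Each supported figure id turns the long per-donor statistics table produced by
:mod:`nkgate.pipeline` into (a) a wide per-donor table of the quantities the
corresponding panel plots, (b) a summary (mean +/- SEM, or median where the
original panel plots medians), (c) the nonparametric comparisons belonging to
the panel, and (d) named qualitative assertions with pass/fail — e.g. "the
NKp80 gate is purer than the CD16 gate", "stimulation leaves NKp80 MFI
unchanged".  The test used for every number is recorded in the comparison
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import ComparisonResult, group_compare, paired_compare
from .errors import ConfigurationError
from .pipeline import AnalysisResult, FRESH

FIGURE_IDS = ("1A", "1B", "1C", "1D", "2A", "2B", "2C", "3A", "3B", "3C", "3D",
              "4A", "4B", "4C", "5B", "6A", "6B", "S1-cryo", "S-dim-vs-neg")

_LEAF = {
    "cd16": "cd16pos", "nkp80": "nkp80pos", "cd7_cd16": "cd7pos_cd16pos",
    "cd7_only": "cd7pos", "cd300a": "cd300apos", "tb4": "tb4pos",
    "cd56dim": "cd56dim", "nk_reference": "nk_reference",
    "cd16_cd123excl": "cd16pos", "nkp80_cd123excl": "nkp80pos",
    "cd300a_cd123excl": "cd300apos", "tb4_cd123excl": "tb4pos",
}

FUNCTIONAL_COLUMNS = {"CD107a": "pct_cd107a", "IFNg": "pct_ifng", "TNF": "pct_tnf"}


@dataclass
class FigureResult:
    figure_id: str
    description: str
    per_donor: pd.DataFrame  # one row per donor, one column per plotted quantity
    summary: pd.DataFrame
    comparisons: list[ComparisonResult] = field(default_factory=list)
    assertions: dict[str, bool] = field(default_factory=dict)
    summary_stat: str = "mean_sem"

    @property
    def all_assertions_pass(self) -> bool:
        return all(self.assertions.values())


def _stats_frame(analysis) -> pd.DataFrame:
    return analysis.stats if isinstance(analysis, AnalysisResult) else analysis


def _series(df: pd.DataFrame, column: str, *, condition: str = "HD",
            state: str = FRESH, strategy: str, subset: str | None = None) -> pd.Series:
    subset = subset or _LEAF[strategy]
    sel = df[(df["condition"] == condition) & (df["state"] == state)
             & (df["strategy"] == strategy) & (df["subset"] == subset)]
    if sel.empty:
        raise ConfigurationError(
            f"analysis lacks condition={condition!r} state={state!r} "
            f"strategy={strategy!r} subset={subset!r}")
    return sel.set_index("donor_id")[column]


def _summarize(per_donor: pd.DataFrame, stat: str) -> pd.DataFrame:
    rows = []
    for col in per_donor.columns:
        v = per_donor[col].astype(float)
        rows.append({
            "quantity": col, "n": int(v.notna().sum()),
            "mean": v.mean(), "sem": v.sem(), "median": v.median(),
        })
    out = pd.DataFrame(rows)
    out.attrs["summary_stat"] = stat
    return out


def _result(fid, desc, columns: dict[str, pd.Series], comparisons, assertions,
            stat="mean_sem") -> FigureResult:
    per_donor = pd.DataFrame(columns)
    assertions = {k: bool(v) for k, v in assertions.items()}
    return FigureResult(fid, desc, per_donor, _summarize(per_donor, stat),
                        comparisons, assertions, stat)


# --- individual figure builders ----------------------------------------------------

def _fig_1a(df):
    a = _series(df, "pct_eomes_pos", strategy="nkp80")
    b = _series(df, "pct_eomes_pos", strategy="cd16")
    cmp_ = paired_compare(a, b.reindex(a.index), "Eomes+% nkp80 vs cd16")
    return _result("1A", "Eomes+ purity of the CD56neg NKp80+ vs CD56neg CD16+ gate",
                   {"nkp80": a, "cd16": b},
                   [cmp_],
                   {"nkp80_purity_higher": cmp_.direction == "A" and cmp_.significant})


def _fig_1b(df):
    neg = _series(df, "fsc_median_eomes_neg", strategy="cd16")
    pos = _series(df, "fsc_median_eomes_pos", strategy="cd16")
    cmp_ = paired_compare(neg, pos.reindex(neg.index), "FSC median Eomes- vs Eomes+")
    return _result("1B", "Cell size (FSC-A median) of Eomes- vs Eomes+ events "
                         "within the CD56neg CD16+ gate",
                   {"eomes_neg": neg, "eomes_pos": pos},
                   [cmp_],
                   {"eomes_neg_larger": cmp_.direction == "A" and cmp_.significant},
                   stat="median")


def _fig_1c(df):
    cols = {
        "cd16_eomes_pos": _series(df, "pct_cd123_eomes_pos", strategy="cd16"),
        "cd16_eomes_neg": _series(df, "pct_cd123_eomes_neg", strategy="cd16"),
        "nkp80_eomes_pos": _series(df, "pct_cd123_eomes_pos", strategy="nkp80"),
        "nkp80_eomes_neg": _series(df, "pct_cd123_eomes_neg", strategy="nkp80"),
    }
    cmp_ = paired_compare(cols["cd16_eomes_neg"],
                          cols["nkp80_eomes_neg"].reindex(cols["cd16_eomes_neg"].index),
                          "CD123+% of Eomes- events, cd16 vs nkp80 gate")
    return _result("1C", "CD123+ content of Eomes+/- events in the CD16 and NKp80 gates",
                   cols, [cmp_],
                   {"cd16_eomes_neg_cd123_high": cmp_.direction == "A" and cmp_.significant})


def _fig_1d(df):
    cols = {
        "cd16": _series(df, "pct_eomes_pos", strategy="cd16"),
        "cd16_cd123excl": _series(df, "pct_eomes_pos", strategy="cd16_cd123excl"),
        "nkp80": _series(df, "pct_eomes_pos", strategy="nkp80"),
        "nkp80_cd123excl": _series(df, "pct_eomes_pos", strategy="nkp80_cd123excl"),
    }
    idx = cols["cd16"].index
    c1 = paired_compare(cols["cd16_cd123excl"].reindex(idx), cols["cd16"],
                        "cd16 purity with vs without CD123 exclusion")
    c2 = paired_compare(cols["nkp80_cd123excl"].reindex(idx), cols["nkp80"].reindex(idx),
                        "nkp80 purity with vs without CD123 exclusion")
    return _result("1D", "Effect of adding CD123 to the exclusion channel on gate purity",
                   cols, [c1, c2],
                   {"cd123_exclusion_raises_cd16_purity":
                        c1.direction == "A" and c1.significant})


_QUAD_SUBSETS = ("cd16pos_nkp80neg", "cd16neg_nkp80pos", "cd16pos_nkp80pos")


def _quadrant_fig(df, fid, column, desc, low_is: str | None = None,
                  high_is: str | None = None):
    cols = {q: _series(df, column, strategy="quadrants", subset=q)
            for q in _QUAD_SUBSETS}
    idx = cols[_QUAD_SUBSETS[0]].index
    comparisons, assertions = [], {}
    target = low_is or high_is
    if target:
        want = "B" if low_is else "A"
        ok = True
        for other in [q for q in _QUAD_SUBSETS if q != target]:
            c = paired_compare(cols[target].reindex(idx), cols[other].reindex(idx),
                               f"{column}: {target} vs {other}")
            comparisons.append(c)
            ok &= (c.direction == want) and c.significant
        assertions[f"{target}_{'lowest' if low_is else 'highest'}"] = ok
    return _result(fid, desc, cols, comparisons, assertions)


def _fig_2a(df):
    res = _quadrant_fig(df, "2A", "freq_of_parent",
                        "CD16 x NKp80 quadrant frequencies within CD56neg events")
    return res


def _fig_2b(df):
    return _quadrant_fig(df, "2B", "pct_eomes_pos",
                         "Eomes+ content of the CD56neg CD16 x NKp80 quadrants",
                         low_is="cd16pos_nkp80neg")


def _fig_2c(df):
    return _quadrant_fig(df, "2C", "pct_cd123_pos",
                         "CD123+ content of the CD56neg CD16 x NKp80 quadrants",
                         high_is="cd16pos_nkp80neg")


def _alt_marker_fig(df, fid, strategies, desc, expect_ns=(), expect_lower=()):
    cols = {s: _series(df, "pct_eomes_pos", strategy=s) for s in strategies}
    idx = cols["nkp80"].index
    comparisons, assertions = [], {}
    for s in strategies:
        if s == "nkp80":
            continue
        c = paired_compare(cols[s].reindex(idx), cols["nkp80"],
                           f"Eomes+%: {s} vs nkp80")
        comparisons.append(c)
        if s in expect_ns:
            assertions[f"{s}_equivalent_to_nkp80"] = not c.significant
        if s in expect_lower:
            assertions[f"{s}_lower_than_nkp80"] = c.direction == "B" and c.significant
    return _result(fid, desc, cols, comparisons, assertions)


def _fig_3a(df):
    return _alt_marker_fig(df, "3A", ("cd7_cd16", "cd7_only", "cd16", "nkp80"),
                           "Eomes+ purity: CD7-based strategies vs NKp80",
                           expect_ns=("cd7_cd16",), expect_lower=("cd7_only", "cd16"))


def _fig_3b(df):
    return _alt_marker_fig(df, "3B", ("cd300a", "cd16", "nkp80"),
                           "Eomes+ purity: CD300a strategy vs NKp80",
                           expect_lower=("cd300a",))


def _fig_3c(df):
    return _alt_marker_fig(df, "3C", ("tb4", "cd16", "nkp80"),
                           "Eomes+ purity: 2B4 strategy vs NKp80",
                           expect_lower=("tb4",))


def _fig_3d(df):
    cols = {s: _series(df, "pct_eomes_pos", strategy=s)
            for s in ("cd300a", "cd300a_cd123excl", "tb4", "tb4_cd123excl", "nkp80")}
    idx = cols["nkp80"].index
    comparisons, assertions = [], {}
    for base in ("cd300a", "tb4"):
        c = paired_compare(cols[f"{base}_cd123excl"].reindex(idx),
                           cols["nkp80"].reindex(idx),
                           f"Eomes+%: {base}+CD123 exclusion vs nkp80")
        comparisons.append(c)
        assertions[f"{base}_cd123excl_still_lower"] = c.direction == "B" and c.significant
    return _result("3D", "CD300a/2B4 purity with CD123 exclusion remains below NKp80",
                   cols, comparisons, assertions)


_CONDITIONS = ("HD", "HIV_untreated", "HIV_cART", "MM")


def _fig_4a(df):
    cols = {}
    for strat in ("cd16", "nkp80"):
        for cond in _CONDITIONS:
            cols[f"{strat}_{cond}"] = _series(df, "freq_of_nk", condition=cond,
                                              strategy=strat).reset_index(drop=True)
    comparisons, ok = [], True
    pairs = [("HIV_untreated", "HD"), ("HIV_cART", "HD"), ("MM", "HD"),
             ("HIV_untreated", "HIV_cART"), ("HIV_untreated", "MM")]
    for hi, lo in pairs:
        c = group_compare(cols[f"nkp80_{hi}"], cols[f"nkp80_{lo}"],
                          f"nkp80 freq of NK: {hi} vs {lo}")
        comparisons.append(c)
        ok &= c.direction == "A" and c.significant
    return _result("4A", "CD56neg subset frequency (% of total NK) across conditions",
                   cols, comparisons,
                   {"cd56neg_expansion_ordering": ok})


def _fig_4bc(df, fid, conditions, desc):
    cols, comparisons, assertions = {}, [], {}
    for cond in conditions:
        a = _series(df, "pct_eomes_pos", condition=cond, strategy="nkp80")
        b = _series(df, "pct_eomes_pos", condition=cond, strategy="cd16")
        cols[f"nkp80_{cond}"] = a.reset_index(drop=True)
        cols[f"cd16_{cond}"] = b.reset_index(drop=True)
        c = paired_compare(a, b.reindex(a.index), f"Eomes+% nkp80 vs cd16 in {cond}")
        comparisons.append(c)
        assertions[f"nkp80_not_worse_in_{cond}"] = c.direction == "A" or not c.significant
    return _result(fid, desc, cols, comparisons, assertions)


def _fig_4b(df):
    return _fig_4bc(df, "4B", ("HIV_untreated", "HIV_cART"),
                    "Gate purity nkp80 vs cd16 in HIV cohorts")


def _fig_4c(df):
    return _fig_4bc(df, "4C", ("MM",),
                    "Gate purity nkp80 vs cd16 in multiple myeloma")


def _mfi_fig(df, fid, states, desc, nkp80_band=(0.9, 1.1)):
    cols = {}
    for marker_col, label in (("mfi_cd16", "CD16"), ("mfi_nkp80", "NKp80")):
        for state in (FRESH,) + states:
            cols[f"{label}_{state}"] = _series(df, marker_col, state=state,
                                               strategy="nk_reference")
    idx = cols["CD16_fresh"].index
    comparisons, assertions = [], {}
    for state in states:
        c = paired_compare(cols[f"CD16_{state}"].reindex(idx), cols["CD16_fresh"],
                           f"CD16 MFI {state} vs fresh")
        comparisons.append(c)
        assertions[f"cd16_mfi_drops_{state}"] = c.direction == "B" and c.significant
        ratio = (cols[f"NKp80_{state}"].reindex(idx) / cols["NKp80_fresh"]).mean()
        assertions[f"nkp80_mfi_stable_{state}"] = nkp80_band[0] <= ratio <= nkp80_band[1]
        cols[f"NKp80_ratio_{state}"] = cols[f"NKp80_{state}"].reindex(idx) / cols["NKp80_fresh"]
    return _result(fid, desc, cols, comparisons, assertions)


def _fig_5b(df):
    return _mfi_fig(df, "5B", ("stim_K562", "stim_IL12_IL18"),
                    "CD16 and NKp80 MFI on NK cells before/after stimulation")


def _fig_s1(df):
    return _mfi_fig(df, "S1-cryo", ("cryopreservation",),
                    "CD16 and NKp80 MFI on NK cells: fresh vs cryopreserved")


def _functional_fig(df, fid, conditions, desc, assert_sig: bool):
    """Per-stimulus functional readouts of nkp80- vs cd16-gated CD56neg cells.

    Reports both raw percentages and unstimulated-control-subtracted values
    (suffix ``_bgsub``).
    """
    cols, comparisons, assertions = {}, [], {}
    for cond in conditions:
        for state in ("stim_K562", "stim_IL12_IL18"):
            for marker, col in FUNCTIONAL_COLUMNS.items():
                a = _series(df, col, condition=cond, state=state, strategy="nkp80")
                b = _series(df, col, condition=cond, state=state, strategy="cd16")
                a0 = _series(df, col, condition=cond, state=FRESH, strategy="nkp80")
                b0 = _series(df, col, condition=cond, state=FRESH, strategy="cd16")
                key = f"{cond}_{state}_{marker}"
                cols[f"nkp80_{key}"] = a.reset_index(drop=True)
                cols[f"cd16_{key}"] = b.reset_index(drop=True)
                cols[f"nkp80_{key}_bgsub"] = (a - a0.reindex(a.index)).reset_index(drop=True)
                cols[f"cd16_{key}_bgsub"] = (b - b0.reindex(b.index)).reset_index(drop=True)
                c = paired_compare(a, b.reindex(a.index), f"{marker}+% nkp80 vs cd16 "
                                                          f"({cond}, {state})")
                comparisons.append(c)
                if marker in ("IFNg", "TNF"):
                    good = c.direction == "A" and (c.significant or not assert_sig)
                    assertions[f"nkp80_higher_{key}"] = good
    return _result(fid, desc, cols, comparisons, assertions, stat="median")


def _fig_6a(df):
    return _functional_fig(df, "6A", ("HIV_untreated", "HIV_cART"),
                           "Functional readouts of CD56neg cells, HIV cohorts",
                           assert_sig=False)


def _fig_6b(df):
    return _functional_fig(df, "6B", ("HD",),
                           "Functional readouts of CD56neg cells, healthy donors",
                           assert_sig=True)


def _fig_dim_vs_neg(df):
    cols, comparisons, assertions = {}, [], {}
    for state in ("stim_K562", "stim_IL12_IL18"):
        for marker, col in FUNCTIONAL_COLUMNS.items():
            dim = _series(df, col, state=state, strategy="cd56dim")
            neg = _series(df, col, state=state, strategy="nkp80")
            key = f"{state}_{marker}"
            cols[f"cd56dim_{key}"] = dim
            cols[f"cd56neg_{key}"] = neg.reindex(dim.index)
            c = paired_compare(dim, neg.reindex(dim.index),
                               f"{marker}+% cd56dim vs cd56neg ({state})")
            comparisons.append(c)
            assertions[f"dim_higher_{key}"] = c.direction == "A" and c.significant
    return _result("S-dim-vs-neg",
                   "CD56dim vs CD56neg (NKp80-gated) functional readouts",
                   cols, comparisons, assertions, stat="median")


_BUILDERS = {
    "1A": _fig_1a, "1B": _fig_1b, "1C": _fig_1c, "1D": _fig_1d,
    "2A": _fig_2a, "2B": _fig_2b, "2C": _fig_2c,
    "3A": _fig_3a, "3B": _fig_3b, "3C": _fig_3c, "3D": _fig_3d,
    "4A": _fig_4a, "4B": _fig_4b, "4C": _fig_4c,
    "5B": _fig_5b, "6A": _fig_6a, "6B": _fig_6b,
    "S1-cryo": _fig_s1, "S-dim-vs-neg": _fig_dim_vs_neg,
}


def reproduce(figure_id: str, analysis) -> FigureResult:
    """Build the figure-analog result for one figure id.

    ``analysis`` is an :class:`~nkgate.pipeline.AnalysisResult` (or its long
    stats frame) that must contain the conditions and states the figure
    needs; a missing condition raises :class:`ConfigurationError`.
    """
    if figure_id not in _BUILDERS:
        raise ConfigurationError(
            f"unknown figure id {figure_id!r}; supported: {list(FIGURE_IDS)}")
    return _BUILDERS[figure_id](_stats_frame(analysis))


def render(result: FigureResult, path) -> None:
    """Plot per-donor dots with the panel's summary bars; write an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in result.per_donor.columns if not c.endswith("_bgsub")]
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(cols)), 4))
    rng = np.random.default_rng(0)
    for i, col in enumerate(cols):
        v = result.per_donor[col].dropna().to_numpy()
        if result.summary_stat == "median":
            ax.bar(i, np.median(v) if v.size else np.nan, color="0.8", width=0.6)
        else:
            sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
            ax.bar(i, v.mean() if v.size else np.nan, yerr=sem, color="0.8",
                   width=0.6, capsize=3)
        ax.scatter(i + rng.uniform(-0.15, 0.15, v.size), v, s=10, color="k", zorder=3)
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels(cols, rotation=60, ha="right", fontsize=7)
    ax.set_title(f"{result.figure_id}: {result.description}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
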