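"""Per-donor, per-subset summary statistics.

Frequencies are percentages of a parent gate; "purity" throughout the package
means the percentage of Eomes+ events inside a gated subset (Eomes being the
transcription-factor ground truth separating NK cells from other innate
lymphoid cells).  MFI is the median raw-scale fluorescence intensity.
Undefined statistics (empty gates) propagate as NaN, never as zero — empty
CD56neg gates do occur in healthy donors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .events import EventTable
from .panel import CD16, CD107A, CD123, EOMES, FSC, IFNG, NKP80, TNF
from .thresholds import ThresholdModel


def subset_frequency(membership: np.ndarray, parent_membership: np.ndarray) -> float:
    """100 * |subset| / |parent|; NaN when the parent is empty.

    ``membership`` must be a subset of ``parent_membership``.
    """
    membership = np.asarray(membership, bool)
    parent_membership = np.asarray(parent_membership, bool)
    if (membership & ~parent_membership).any():
        raise ValueError("membership is not a subset of parent_membership")
    n_parent = int(parent_membership.sum())
    if n_parent == 0:
        return float("nan")
    return 100.0 * float(membership.sum()) / n_parent


def pct_positive(table: EventTable,
                 membership: np.ndarray,
                 marker: str,
                 model: ThresholdModel,
                 *,
                 use_truth_for_eomes: bool = True) -> float:
    """Percentage of member events positive for ``marker``.

    For Eomes the truth label is used when the table carries one (the
    intracellular stain is the ground truth in the synthetic model); for all
    other markers positivity is the transformed value above the cutoff.
    NaN when the membership is empty.
    """
    membership = np.asarray(membership, bool)
    n = int(membership.sum())
    if n == 0:
        return float("nan")
    if marker == EOMES and use_truth_for_eomes and table.truth is not None:
        pos = table.truth["eomes_truth"].to_numpy().astype(bool)
    else:
        t = model[marker]
        pos = table.transformed(marker, model.cofactor) > t.cutoff
    return 100.0 * float((pos & membership).sum()) / n


def mfi(table: EventTable, membership: np.ndarray, marker: str) -> float:
    """Median raw-scale intensity of member events; NaN when empty."""
    membership = np.asarray(membership, bool)
    if not membership.any():
        return float("nan")
    return float(np.median(table.marker(marker)[membership]))


@dataclass
class SubsetStats:
    """One (donor, condition, strategy, subset) row of the long results table."""

    donor_id: str
    condition: str
    state: str  # fresh | cryopreservation | stim_K562 | stim_IL12_IL18
    strategy: str
    subset: str
    n_events: int
    freq_of_parent: float = float("nan")
    freq_of_nk: float = float("nan")
    pct_eomes_pos: float = float("nan")
    pct_cd123_pos: float = float("nan")
    mfi_cd16: float = float("nan")
    mfi_nkp80: float = float("nan")
    fsc_median: float = float("nan")
    fsc_median_eomes_pos: float = float("nan")
    fsc_median_eomes_neg: float = float("nan")
    pct_cd123_eomes_pos: float = float("nan")
    pct_cd123_eomes_neg: float = float("nan")
    pct_cd107a: float = float("nan")
    pct_ifng: float = float("nan")
    pct_tnf: float = float("nan")


#: Column order of the serialized long table (documented schema).
STATS_COLUMNS = list(SubsetStats("", "", "", "", "", 0).__dict__)

PERCENT_COLUMNS = [c for c in STATS_COLUMNS
                   if c.startswith(("freq", "pct"))]


def subset_stats(table: EventTable,
                 membership: dict[str, np.ndarray],
                 subset: str,
                 parent: str,
                 model: ThresholdModel,
                 *,
                 donor_id: str,
                 condition: str,
                 state: str,
                 strategy: str,
                 nk_reference: np.ndarray | None = None) -> SubsetStats:
    """Compute the full statistics row for one gated subset."""
    m = membership[subset]
    row = SubsetStats(donor_id=donor_id, condition=condition, state=state,
                      strategy=strategy, subset=subset, n_events=int(m.sum()))
    row.freq_of_parent = subset_frequency(m, membership[parent])
    if nk_reference is not None:
        # the reference is an independent gate, not a parent: intersect for the ratio
        n_ref = int(np.asarray(nk_reference, bool).sum())
        row.freq_of_nk = float("nan") if n_ref == 0 else 100.0 * int(m.sum()) / n_ref
    row.pct_eomes_pos = pct_positive(table, m, EOMES, model)
    row.pct_cd123_pos = pct_positive(table, m, CD123, model)
    row.mfi_cd16 = mfi(table, m, CD16)
    row.mfi_nkp80 = mfi(table, m, NKP80)
    row.fsc_median = mfi(table, m, FSC)
    row.pct_cd107a = pct_positive(table, m, CD107A, model)
    row.pct_ifng = pct_positive(table, m, IFNG, model)
    row.pct_tnf = pct_positive(table, m, TNF, model)
    if table.truth is not None and row.n_events:
        eomes = table.truth["eomes_truth"].to_numpy().astype(bool)
        row.fsc_median_eomes_pos = mfi(table, m & eomes, FSC)
        row.fsc_median_eomes_neg = mfi(table, m & ~eomes, FSC)
        row.pct_cd123_eomes_pos = pct_positive(table, m & eomes, CD123, model)
        row.pct_cd123_eomes_neg = pct_positive(table, m & ~eomes, CD123, model)
    return row


def donor_table(rows: list[SubsetStats]) -> pd.DataFrame:
    """Long-format table, one row per (donor, condition, state, strategy, subset)."""
    df = pd.DataFrame([r.__dict__ for r in rows], columns=STATS_COLUMNS)
    return df


def write_stats_csv(df: pd.DataFrame, path) -> None:
    """Serialize with 4-decimal percentages; missing values as empty fields."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(4)
    out.to_csv(path, index=False)


def read_stats_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"stats file missing columns: {missing}")
    return df
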