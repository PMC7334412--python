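"""The event table: events x channels matrix plus panel metadata and truth labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import FLUORESCENCE, DEFAULT_COFACTOR, Panel
from .transform import arcsinh_transform

#: Column names of the truth sidecar.
TRUTH_COLUMNS = ["population", "eomes_truth"]


@dataclass
class EventTable:
    """Universal currency of the pipeline.

    Parameters
    ----------
    data
        events x channels frame; columns are panel ``channel_id``s, values on
        the raw (untransformed) scale.
    panel
        Channel metadata.
    truth
        Optional per-event ground truth (``population`` label and binary
        ``eomes_truth``); present for synthetic data, absent for user FCS files.
    """

    data: pd.DataFrame
    panel: Panel
    truth: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict, repr=False, compare=False)
    _tcache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        expected = [c.channel_id for c in self.panel]
        if list(self.data.columns) != expected:
            # reorder / validate
            self.data = self.data[expected]
        if self.truth is not None and len(self.truth) != len(self.data):
            raise ValueError("truth sidecar length does not match event count")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def marker(self, marker: str) -> np.ndarray:
        """Raw-scale values for a marker."""
        ch = self.panel.channel_for(marker)
        return self.data[ch.channel_id].to_numpy()

    def transformed(self, marker: str, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
        """arcsinh-transformed values for fluorescence markers; scatter is returned raw."""
        ch = self.panel.channel_for(marker)
        key = (marker, cofactor)
        if key not in self._tcache:
            raw = self.data[ch.channel_id].to_numpy()
            if ch.role == FLUORESCENCE:
                self._tcache[key] = arcsinh_transform(raw, cofactor)
            else:
                self._tcache[key] = raw.astype(float)
        return self._tcache[key]

    def copy(self) -> "EventTable":
        truth = None if self.truth is None else self.truth.copy()
        return EventTable(self.data.copy(), self.panel, truth, meta=dict(self.meta))

    def population_mask(self, *names: str) -> np.ndarray:
        if self.truth is None:
            raise ValueError("event table carries no truth labels")
        return self.truth["population"].isin(names).to_numpy()
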