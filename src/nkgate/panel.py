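"""Channel/marker panel definitions.

A panel maps short acquisition channel ids (what an FCS file calls ``$PnN``)
to marker names (``$PnS``) and roles.  The default panel covers the markers
needed for NK-subset immunophenotyping: lineage exclusion (viability, CD3,
CD14, CD19), subsetting (CD56, CD16, NKp80, CD7, CD300a, 2B4), contamination
(CD123), the Eomes transcription-factor stain, functional readouts (CD107a,
IFNg, TNF) and forward scatter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import PanelMismatchError

SCATTER = "scatter"
FLUORESCENCE = "fluorescence"

#: Default arcsinh cofactor for fluorescence channels (conventional flow).
DEFAULT_COFACTOR = 150.0


@dataclass(frozen=True)
class ChannelDef:
    channel_id: str
    marker: str
    role: str  # "scatter" | "fluorescence"


class Panel:
    """Ordered collection of :class:`ChannelDef` with unique channel ids."""

    def __init__(self, channels: Iterable[ChannelDef]):
        self.channels = list(channels)
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise PanelMismatchError("duplicate channel_id in panel")
        self._by_marker = {c.marker: c for c in self.channels}

    def __iter__(self):
        return iter(self.channels)

    def __len__(self):
        return len(self.channels)

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels]

    def has_marker(self, marker: str) -> bool:
        return marker in self._by_marker

    def channel_for(self, marker: str) -> ChannelDef:
        try:
            return self._by_marker[marker]
        except KeyError:
            raise PanelMismatchError(f"marker {marker!r} not present in panel") from None

    def fluorescence_markers(self) -> list[str]:
        return [c.marker for c in self.channels if c.role == FLUORESCENCE]

    def require(self, markers: Iterable[str]) -> None:
        missing = [m for m in markers if m not in self._by_marker]
        if missing:
            raise PanelMismatchError(f"markers missing from panel: {missing}")


#: Marker names used throughout the package.
FSC = "FSC-A"
VIABILITY = "Viability"
CD3 = "CD3"
CD14 = "CD14"
CD19 = "CD19"
CD56 = "CD56"
CD16 = "CD16"
NKP80 = "NKp80"
CD7 = "CD7"
CD300A = "CD300a"
TB4 = "2B4"
CD123 = "CD123"
EOMES = "Eomes"
CD107A = "CD107a"
IFNG = "IFNg"
TNF = "TNF"

FUNCTIONAL_MARKERS = (CD107A, IFNG, TNF)
EXCLUSION_MARKERS = (VIABILITY, CD3, CD14, CD19)


def default_panel() -> Panel:
    """The 16-channel default panel."""
    fluor = [VIABILITY, CD3, CD14, CD19, CD56, CD16, NKP80, CD7,
             CD300A, TB4, CD123, EOMES, CD107A, IFNG, TNF]
    channels = [ChannelDef("FSC-A", FSC, SCATTER)]
    channels += [ChannelDef(f"FL{i + 1:02d}", m, FLUORESCENCE) for i, m in enumerate(fluor)]
    return Panel(channels)
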