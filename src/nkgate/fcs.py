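"""Minimal FCS 3.1 reading and writing.

Implements the subset of the flow-cytometry standard file format the
pipeline needs: list-mode data, float32 (write) and float/integer (read)
datatypes, linear amplification (``$PnE = 0,0``), one data set per file.
Channel short names (``$PnN``) carry the panel channel id and stain names
(``$PnS``) the marker.  Ground-truth labels cannot live in an FCS file (the
format has no categorical channel), so they travel in a companion CSV keyed
by event index.

Writing is byte-deterministic for fixed input: no timestamps or
machine-dependent keywords are emitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import NKGateError, PanelMismatchError
from .events import EventTable
from .panel import ChannelDef, FLUORESCENCE, Panel, SCATTER

DELIM = "/"
_TEXT_START = 256


def write_fcs(table: EventTable, path) -> None:
    """Write an event table as an FCS 3.1 file (float32, little-endian)."""
    n_events, n_par = table.n_events, len(table.panel)
    data = np.ascontiguousarray(table.data.to_numpy(dtype="<f4"))
    data_bytes = data.tobytes()

    def text_for(begin_data: int, end_data: int) -> bytes:
        pairs = [
            ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
            ("$BEGINDATA", f"{begin_data:010d}"), ("$ENDDATA", f"{end_data:010d}"),
            ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"), ("$MODE", "L"),
            ("$NEXTDATA", "0"), ("$PAR", str(n_par)), ("$TOT", str(n_events)),
        ]
        for i, ch in enumerate(table.panel, start=1):
            pairs += [(f"$P{i}B", "32"), (f"$P{i}E", "0,0"),
                      (f"$P{i}N", ch.channel_id), (f"$P{i}S", ch.marker),
                      (f"$P{i}R", "262144")]
        body = DELIM + DELIM.join(f"{k}{DELIM}{v}" for k, v in pairs) + DELIM
        return body.encode("ascii")

    text = text_for(0, 0)
    text_end = _TEXT_START + len(text) - 1
    begin_data = _TEXT_START + len(text)
    end_data = begin_data + len(data_bytes) - 1 if data_bytes else begin_data
    text = text_for(begin_data, end_data)  # widths fixed by zero-padding

    def hdr_off(v: int) -> bytes:
        return (str(v) if v <= 99_999_999 else "0").rjust(8).encode("ascii")

    header = b"FCS3.1  " + hdr_off(_TEXT_START) + hdr_off(text_end) \
        + hdr_off(begin_data) + hdr_off(end_data) + hdr_off(0) + hdr_off(0)
    with open(path, "wb") as fh:
        fh.write(header.ljust(_TEXT_START, b" "))
        fh.write(text)
        fh.write(data_bytes)


def _parse_text(raw: bytes) -> dict[str, str]:
    text = raw.decode("ascii", errors="replace")
    delim = text[0]
    parts = text[1:].rstrip(delim).split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path, panel: Panel | None = None) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    When ``panel`` is given, file channels are mapped to panel markers
    ($PnS preferred, $PnN fallback) and every panel marker must be present.
    Without a panel, one is reconstructed from the file's own keywords.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58 or not blob[:6] in (b"FCS3.1", b"FCS3.0"):
        raise NKGateError(f"{path}: not an FCS 3.0/3.1 file")

    def off(i: int) -> int:
        field = blob[10 + 8 * i: 18 + 8 * i].decode("ascii").strip()
        return int(field) if field else 0

    text_start, text_end = off(0), off(1)
    if text_end <= text_start or text_end >= len(blob):
        raise NKGateError(f"{path}: truncated or corrupt header")
    kw = _parse_text(blob[text_start:text_end + 1])

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    data_start = off(2) or int(kw.get("$BEGINDATA", 0))
    data_end = off(3) or int(kw.get("$ENDDATA", 0))
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    bits = {int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise NKGateError(f"{path}: mixed $PnB widths are not supported")
    nbits = bits.pop()
    if datatype == "F":
        if nbits != 32:
            raise NKGateError(f"{path}: float data must be 32-bit")
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "I":
        if nbits not in (8, 16, 32):
            raise NKGateError(f"{path}: unsupported integer width {nbits}")
        dtype = np.dtype(f"{endian}u{nbits // 8}")
    else:
        raise NKGateError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_values = n_par * n_tot
    raw = blob[data_start:data_end + 1]
    if len(raw) < n_values * dtype.itemsize:
        raise NKGateError(f"{path}: data segment shorter than $TOT x $PAR values")
    values = np.frombuffer(raw[:n_values * dtype.itemsize], dtype=dtype)
    matrix = values.reshape(n_tot, n_par).astype(float) if n_tot else \
        np.empty((0, n_par))

    file_names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    file_stains = [kw.get(f"$P{i}S", "") for i in range(1, n_par + 1)]

    if panel is None:
        channels = [ChannelDef(file_names[i], file_stains[i] or file_names[i],
                               SCATTER if "FSC" in file_names[i].upper()
                               or "SSC" in file_names[i].upper() else FLUORESCENCE)
                    for i in range(n_par)]
        panel = Panel(channels)
        order = list(range(n_par))
    else:
        order = []
        for ch in panel:
            if ch.marker in file_stains:
                order.append(file_stains.index(ch.marker))
            elif ch.channel_id in file_names:
                order.append(file_names.index(ch.channel_id))
            else:
                raise PanelMismatchError(
                    f"{path}: marker {ch.marker!r} (channel {ch.channel_id!r}) "
                    f"not found in file")
        matrix = matrix[:, order]

    data = pd.DataFrame(matrix, columns=[c.channel_id for c in panel])
    return EventTable(data, panel)


# --- truth sidecar -----------------------------------------------------------------

def write_truth_csv(table: EventTable, path) -> None:
    if table.truth is None:
        raise ValueError("event table has no truth labels to write")
    out = table.truth.copy()
    out.insert(0, "event_index", np.arange(len(out)))
    out.to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("event_index", "population", "eomes_truth"):
        if col not in df.columns:
            raise NKGateError(f"{path}: truth sidecar missing column {col!r}")
    return df.sort_values("event_index").reset_index(drop=True)[
        ["population", "eomes_truth"]]
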