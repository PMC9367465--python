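"""Minimal FCS 3.1 export of simulated cytometry events.

Delimited text is the package's canonical format; this module writes a
small, standard-conformant flow-cytometry file (list-mode, float32,
little-endian) so simulated events can be opened in cytometry viewers.
A matching reader is provided for round-trip verification.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_fcs", "read_fcs", "DEFAULT_CHANNELS"]

#: Default channel name -> event-table column mapping.
DEFAULT_CHANNELS = {
    "FV": "total_intensity",
    "FV-AREA": "dye_area",
    "BF-AREA": "cell_area",
    "DNA": "dna_intensity",
    "DNA-AREA": "dna_area",
}

_DELIM = "/"


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for key, value in keywords.items():
        parts.append(f"{key}{_DELIM}{value}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(events: pd.DataFrame, path, channels: dict[str, str] | None = None) -> Path:
    """Write events as an FCS 3.1 file.

    Parameters are taken from ``channels`` (channel name -> column);
    data are stored as little-endian float32 in list mode.  Raises on
    an empty event set.
    """
    if len(events) == 0:
        raise ValueError("cannot export an empty event set")
    if channels is None:
        channels = {k: v for k, v in DEFAULT_CHANNELS.items() if v in events.columns}
    if not channels:
        raise ValueError("no exportable channels found")
    data = np.ascontiguousarray(
        events[list(channels.values())].to_numpy(dtype="<f4")
    )
    n_events, n_par = data.shape

    keywords = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "0",
        "$ENDDATA": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(channels, start=1):
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}R"] = str(int(np.ceil(max(float(data[:, i - 1].max()), 1.0))))

    # data offsets depend on the TEXT length; iterate until stable
    header_len = 58
    data_begin = data_end = 0
    for _ in range(4):
        keywords["$BEGINDATA"] = str(data_begin)
        keywords["$ENDDATA"] = str(data_end)
        text = _text_segment(keywords)
        new_begin = header_len + len(text)
        new_end = new_begin + data.nbytes - 1
        if (new_begin, new_end) == (data_begin, data_end):
            break
        data_begin, data_end = new_begin, new_end
    text = _text_segment(keywords)
    text_begin = header_len
    text_end = header_len + len(text) - 1

    header = b"FCS3.1    " + b"".join(
        f"{off:>8d}".encode("ascii")
        for off in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == header_len

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())
    return path


def read_fcs(path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read an FCS file written by :func:`write_fcs`.

    Returns the TEXT-segment keywords and a DataFrame with one column
    per channel ($PnN names).  Supports list-mode float32/float64 data.
    """
    raw = Path(path).read_bytes()
    if not raw.startswith(b"FCS3"):
        raise ValueError("not an FCS 3.x file")
    offsets = [int(raw[10 + 8 * i : 18 + 8 * i]) for i in range(4)]
    text_begin, text_end, data_begin, data_end = offsets
    text = raw[text_begin : text_end + 1].decode("ascii")
    delim = text[0]
    tokens = text[1:].split(delim)
    keywords = {
        tokens[i]: tokens[i + 1] for i in range(0, len(tokens) - 1, 2)
    }
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    dtype = {"F": "<f4", "D": "<f8"}[keywords["$DATATYPE"]]
    if keywords.get("$BYTEORD", "1,2,3,4") == "4,3,2,1":
        dtype = dtype.replace("<", ">")
    data = np.frombuffer(
        raw[data_begin : data_end + 1], dtype=dtype
    ).reshape(n_tot, n_par)
    names = [keywords[f"$P{i}N"] for i in range(1, n_par + 1)]
    return keywords, pd.DataFrame(data, columns=names)
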