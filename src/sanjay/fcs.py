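"""Minimal FCS 3.0/3.1 reading and writing.

Flow cytometers ship event data as FCS files: an ASCII header with segment
offsets, a delimited TEXT segment of ``$KEYWORD`` metadata, and a packed
binary DATA segment holding the events x channels matrix.  This module reads
the primary dataset of list-mode (``$MODE L``) files with floating-point
(``$DATATYPE F``/``D``) or integer (``I``) storage in either byte order, and
writes small single-dataset files for round-trip fixtures.  Compensation and
intensity transforms are deliberately not applied: raw values pass through.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_fcs", "write_fcs", "FCSParseError"]


class FCSParseError(ValueError):
    """Raised when a file does not parse as FCS 3.0/3.1 list-mode data."""


_DTYPES = {"F": "f4", "D": "f8", "I": "u4"}


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    # Keywords and values alternate between delimiters; a doubled delimiter
    # escapes a literal one, which none of our keywords use.
    parts = raw.decode("latin-1").strip(delim).split(delim)
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read the primary dataset of an FCS 3.0/3.1 file.

    Returns
    -------
    values : ndarray of shape (n_events, n_channels), float64
    channel_names : list of str
        ``$PnN`` short names (falling back to ``$PnS`` or ``Pn``).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FCSParseError(f"{path}: too short to be an FCS file")
    version = raw[:6].decode("latin-1", "replace")
    if not version.startswith("FCS3"):
        raise FCSParseError(f"{path}: unsupported FCS version {version!r}")

    def _offset(a: int, b: int) -> int:
        field = raw[a:b].decode("latin-1").strip() or "0"
        return int(field)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(raw[text_start : text_end + 1])

    if data_start == 0:  # large files store DATA offsets in TEXT only
        data_start = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSParseError(f"{path}: only list mode ($MODE L) is supported, got {mode}")
    dtype_code = text.get("$DATATYPE", "").upper()
    if dtype_code not in _DTYPES:
        raise FCSParseError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if dtype_code == "I":
        widths = {int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if widths != {32}:
            raise FCSParseError(f"{path}: only 32-bit integer data supported")
    dt = np.dtype(endian + _DTYPES[dtype_code])

    n_bytes = n_tot * n_par * dt.itemsize
    blob = raw[data_start : data_start + n_bytes]
    if len(blob) < n_bytes:
        raise FCSParseError(f"{path}: DATA segment truncated ({len(blob)} < {n_bytes} bytes)")
    values = np.frombuffer(blob, dtype=dt).reshape(n_tot, n_par).astype(np.float64)

    names = []
    for i in range(1, n_par + 1):
        names.append(text.get(f"$P{i}N") or text.get(f"$P{i}S") or f"P{i}")
    return values, names


def write_fcs(path: str | Path, values: np.ndarray, channel_names: list[str] | None = None) -> None:
    """Write a single-dataset FCS 3.0 file ($DATATYPE F, $MODE L, little-endian).

    Intended for round-trip fixtures; values are stored as float32.
    """
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("values must be a non-empty 2D array")
    n_tot, n_par = values.shape
    if channel_names is None:
        channel_names = [f"P{i}" for i in range(1, n_par + 1)]
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must match the number of columns")

    d = "/"
    kw: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(channel_names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(values)) + 1)))

    header_len = 58
    text_start = header_len
    # TEXT length is stable: offsets are written as fixed-width decimal fields.
    body = d + d.join(f"{k}{d}{v}" for k, v in sorted(kw.items())) + d
    probe = body + f"{d}$BEGINDATA{d}{0:010d}{d}$ENDDATA{d}{0:010d}{d}"
    data_start = text_start + len(probe)
    data_end = data_start + values.nbytes - 1
    text = body + f"{d}$BEGINDATA{d}{data_start:010d}{d}$ENDDATA{d}{data_end:010d}{d}"
    text_end = text_start + len(text) - 1

    header = (
        "FCS3.0    "
        + f"{text_start:>8d}{text_end:>8d}"
        + f"{data_start:>8d}{data_end:>8d}"
        + f"{0:>8d}{0:>8d}"
    )
    assert len(header) == header_len
    payload = values.astype("<f4").tobytes()
    Path(path).write_bytes(header.encode("ascii") + text.encode("latin-1") + payload)
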