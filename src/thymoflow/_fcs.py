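"""Minimal FCS 3.1 reader/writer.

Supports list-mode ($MODE L) floating-point data ($DATATYPE F or D) with a
single data set per file, which is all the pipeline needs. The analysis
segment and spillover keywords are ignored. Non-standard keywords TRANSFORM
and COFACTOR record the intensity-scale state so that a transformed table
survives a round trip.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError

_DELIM = "/"
_HEADER_LEN = 58
_TEXT_START = 256


def _fmt_offset(value: int) -> bytes:
    s = str(value)
    if len(s) > 8:
        raise FormatError("segment offset exceeds the 8-character FCS header field")
    return s.rjust(8).encode("ascii")


def write_fcs(path, markers, data, *, detectors=None, sample_id="", extra_keywords=None):
    """Write a float32 FCS 3.1 file with one event matrix.

    ``data`` is an (events x channels) array; ``markers`` name the channels
    ($PnN). ``extra_keywords`` is a mapping of non-standard TEXT keywords.
    """
    data = np.ascontiguousarray(data, dtype="<f4")
    n_events, n_par = (data.shape if data.ndim == 2 else (0, len(markers)))
    if n_par != len(markers):
        raise FormatError("channel count does not match marker list")

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # zero-padded to fixed width so the TEXT length is offset-independent
        "$BEGINDATA": "0" * 12,
        "$ENDDATA": "0" * 12,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, marker in enumerate(markers, start=1):
        kw[f"$P{i}N"] = str(marker)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        rng = float(data[:, i - 1].max()) if n_events else 0.0
        kw[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)
        if detectors is not None and detectors[i - 1]:
            kw[f"$P{i}S"] = str(detectors[i - 1])
    if sample_id:
        kw["SAMPLEID"] = str(sample_id)
    for key, value in (extra_keywords or {}).items():
        kw[key] = str(value)

    for key, value in kw.items():
        if _DELIM in key or _DELIM in value:
            raise FormatError(f"delimiter {_DELIM!r} not allowed in keyword {key!r}")
        if value == "":
            raise FormatError(f"empty value for keyword {key!r}")

    def render():
        return _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kw.items()) + _DELIM

    text_start = _TEXT_START
    text_end = text_start + len(render()) - 1
    data_start = text_end + 1
    n_bytes = data.nbytes
    data_end = data_start + n_bytes - 1 if n_bytes else 0
    kw["$BEGINDATA"] = str(data_start).zfill(12)
    kw["$ENDDATA"] = str(data_end).zfill(12)
    text = render()

    header = b"FCS3.1    " + b"".join(
        _fmt_offset(v) for v in (text_start, text_end, data_start, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - _HEADER_LEN))
        fh.write(text.encode("ascii"))
        fh.write(data.tobytes())
    return path


def read_fcs(path):
    """Read an FCS 3.0/3.1 file; returns (markers, detectors, data, keywords)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER_LEN or not raw[:6].startswith(b"FCS3"):
        raise FormatError(f"{path}: not an FCS 3.x file")
    try:
        offsets = [int(raw[10 + 8 * i : 18 + 8 * i]) for i in range(4)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FCS header offsets") from exc
    text_start, text_end, data_start, data_end = offsets

    try:
        text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    except IndexError as exc:  # pragma: no cover - defensive
        raise FormatError(f"{path}: TEXT segment out of bounds") from exc
    if not text:
        raise FormatError(f"{path}: empty TEXT segment")
    delim = text[0]
    parts = text[1:].split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        raise FormatError(f"{path}: TEXT segment has an odd number of fields")
    kw = {parts[i]: parts[i + 1] for i in range(0, len(parts), 2)}

    if kw.get("$MODE", "L") != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) data is supported")
    dtype_code = kw.get("$DATATYPE", "F")
    if dtype_code not in ("F", "D"):
        raise FormatError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    dtype = np.dtype(f"{endian}f{'4' if dtype_code == 'F' else '8'}")

    n_par = int(kw["$PAR"])
    n_events = int(kw["$TOT"])
    markers = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    detectors = [kw.get(f"$P{i}S", "") for i in range(1, n_par + 1)]

    if not data_start:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    n_bytes = n_events * n_par * dtype.itemsize
    buf = raw[data_start : data_start + n_bytes]
    if len(buf) != n_bytes:
        raise FormatError(f"{path}: DATA segment truncated")
    data = np.frombuffer(buf, dtype=dtype).astype(np.float64).reshape(n_events, n_par)
    return markers, detectors, data, kw
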