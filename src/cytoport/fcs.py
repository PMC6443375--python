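"""FCS 3.0/3.1 reading and FCS 3.1 writing.

The FCS container is a HEADER (version string + ASCII byte offsets), a
delimited TEXT segment of keyword/value pairs, and a binary DATA segment
holding the event matrix.  The reader accepts list-mode ($MODE L) float
($DATATYPE F) and integer ($DATATYPE I) data in either byte order and
linearizes log-amplified integer channels declared via $PnE.  The writer
always emits FCS 3.1, little-endian float32, linear scale ($PnE "0,0") —
one canonical output dialect; the reader handles the rest.
"""

from __future__ import annotations

import logging
import math
import os

import numpy as np

from .errors import InvalidSampleError, MalformedFileError, UnsupportedModeError
from .model import ChannelMeta, Sample

log = logging.getLogger(__name__)

DELIM = b"/"

REQUIRED_KEYWORDS = ("$TOT", "$PAR", "$DATATYPE", "$BYTEORD", "$MODE")


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if len(raw) < 2:
        raise MalformedFileError("TEXT segment too short")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # split on single delimiters; doubled delimiters are escaped literals
    tokens: list[str] = []
    pieces = body.split(delim)
    cur: list[str] = []
    i = 0
    while i < len(pieces):
        cur.append(pieces[i].decode("utf-8", errors="replace"))
        # an empty following piece means the delimiter was doubled (escape)
        if i + 1 < len(pieces) and pieces[i + 1] == b"":
            cur.append(delim.decode())
            i += 2
            # keep accumulating into the same token
            continue
        tokens.append("".join(cur))
        cur = []
        i += 1
    if cur:
        tokens.append("".join(cur))
    if len(tokens) % 2 != 0:
        raise MalformedFileError("TEXT segment has an odd number of tokens")
    kw: dict[str, str] = {}
    for k, v in zip(tokens[0::2], tokens[1::2]):
        key = k.strip()
        if key.startswith("$"):
            key = key.upper()
        kw[key] = v
    return kw


def _header_offsets(header: bytes) -> tuple[str, list[int]]:
    version = header[0:6].decode("ascii", errors="replace")
    fields = []
    for i in range(6):
        chunk = header[10 + 8 * i: 18 + 8 * i].strip() or b"0"
        try:
            fields.append(int(chunk))
        except ValueError:
            raise MalformedFileError(f"non-numeric HEADER offset field {chunk!r}")
    return version, fields


def read_fcs(path: str, sample_id: str | None = None) -> Sample:
    """Read one FCS 3.0/3.1 dataset into a :class:`Sample`.

    Integer data are converted to float; log-amplified integer channels
    ($PnE = "f1,f2" with f1 > 0) are linearized as f2 * 10^(f1 * x / $PnR).
    The $SPILLOVER/$SPILL keyword, when present, is kept verbatim in the
    keyword map for the compensation module to consume.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise MalformedFileError(f"{path}: file shorter than an FCS HEADER")
    version, off = _header_offsets(blob[:58])
    if not version.startswith("FCS3.0") and not version.startswith("FCS3.1"):
        raise MalformedFileError(f"{path}: unsupported FCS version {version!r}")
    text_beg, text_end, data_beg, data_end = off[0], off[1], off[2], off[3]
    if text_beg <= 0 or text_end < text_beg:
        raise MalformedFileError(f"{path}: invalid TEXT offsets")
    kw = _parse_text_segment(blob[text_beg:text_end + 1])

    for req in REQUIRED_KEYWORDS:
        if req not in kw:
            raise MalformedFileError(f"{path}: missing required keyword {req}")
    if kw["$MODE"].strip().upper() != "L":
        raise UnsupportedModeError(
            f"{path}: $MODE {kw['$MODE']!r} unsupported (list mode only)")

    n_events = int(kw["$TOT"])
    n_par = int(kw["$PAR"])
    datatype = kw["$DATATYPE"].strip().upper()
    byteord = kw["$BYTEORD"].strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise MalformedFileError(f"{path}: unsupported $BYTEORD {byteord!r}")

    if data_beg == 0 and "$BEGINDATA" in kw:
        data_beg = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    if data_beg <= 0 or data_end < data_beg - 1:
        raise MalformedFileError(f"{path}: invalid DATA offsets")
    payload = blob[data_beg:data_end + 1]

    channels: list[ChannelMeta] = []
    widths: list[int] = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N", f"P{i}")
        marker = kw.get(f"$P{i}S", "")
        rng = float(kw.get(f"$P{i}R", 262144))
        channels.append(ChannelMeta(name=name, marker=marker, range=rng))
        widths.append(int(kw.get(f"$P{i}B", 32)))

    if datatype == "F":
        if any(w != 32 for w in widths):
            raise MalformedFileError(f"{path}: $DATATYPE F requires $PnB 32")
        need = n_events * n_par * 4
        if len(payload) < need:
            raise MalformedFileError(
                f"{path}: DATA segment holds {len(payload)} bytes, need {need}")
        events = np.frombuffer(payload[:need], dtype=f"{endian}f4").astype(
            np.float64).reshape(n_events, n_par)
    elif datatype == "I":
        if any(w not in (8, 16, 32, 64) for w in widths):
            raise MalformedFileError(
                f"{path}: integer $PnB widths must be 8/16/32/64, got {widths}")
        if len(set(widths)) == 1:
            w = widths[0] // 8
            need = n_events * n_par * w
            if len(payload) < need:
                raise MalformedFileError(f"{path}: DATA segment truncated")
            events = np.frombuffer(payload[:need], dtype=f"{endian}u{w}").astype(
                np.float64).reshape(n_events, n_par)
        else:
            dt = np.dtype([(f"c{i}", f"{endian}u{w // 8}") for i, w in enumerate(widths)])
            need = n_events * dt.itemsize
            if len(payload) < need:
                raise MalformedFileError(f"{path}: DATA segment truncated")
            rec = np.frombuffer(payload[:need], dtype=dt)
            events = np.column_stack([rec[f"c{i}"].astype(np.float64)
                                      for i in range(n_par)])
    else:
        raise MalformedFileError(
            f"{path}: $DATATYPE {datatype!r} unsupported (F or I only)")

    # linearize log-amplified integer channels
    for i, ch in enumerate(channels):
        pne = kw.get(f"$P{i + 1}E", "0,0")
        try:
            f1, f2 = (float(t) for t in pne.split(","))
        except ValueError:
            raise MalformedFileError(f"{path}: malformed $P{i + 1}E {pne!r}")
        if f1 > 0:
            if f2 == 0:
                f2 = 1.0  # common instrument quirk: f2=0 means 1
            events[:, i] = f2 * 10.0 ** (f1 * events[:, i] / ch.range)
            log.info("%s: channel %s linearized from $PnE=%s", path, ch.name, pne)

    if events.size and not np.all(np.isfinite(events)):
        raise MalformedFileError(f"{path}: non-finite values in DATA segment")

    sid = sample_id or kw.get("$FIL") or os.path.basename(path)
    return Sample(sample_id=sid, events=events, channels=channels, keywords=kw)


# keys the writer owns; user keywords with these names are recomputed
_STRUCTURAL = {"$BEGINANALYSIS", "$ENDANALYSIS", "$BEGINSTEXT", "$ENDSTEXT",
               "$BEGINDATA", "$ENDDATA", "$NEXTDATA", "$TOT", "$PAR",
               "$DATATYPE", "$MODE", "$BYTEORD", "$FIL"}


def _escape(value: str) -> bytes:
    return value.replace("/", "//").encode("utf-8")


def write_fcs(sample: Sample, path: str) -> None:
    """Write a Sample as FCS 3.1 (little-endian float32, linear $PnE).

    $PnR is max(1, ceil(column max)); marker labels become $PnS; user
    keywords (e.g. $SPILLOVER) are carried through except structural ones
    the writer recomputes.
    """
    if len(sample.channels) == 0:
        raise InvalidSampleError("cannot write a sample with zero channels")
    events = np.ascontiguousarray(sample.events, dtype="<f4")
    n_events, n_par = events.shape

    pairs: list[tuple[str, str]] = []
    pairs.append(("$BEGINANALYSIS", "0"))
    pairs.append(("$ENDANALYSIS", "0"))
    pairs.append(("$BEGINSTEXT", "0"))
    pairs.append(("$ENDSTEXT", "0"))
    pairs.append(("$BEGINDATA", "{BEGINDATA}"))
    pairs.append(("$ENDDATA", "{ENDDATA}"))
    pairs.append(("$NEXTDATA", "0"))
    pairs.append(("$MODE", "L"))
    pairs.append(("$DATATYPE", "F"))
    pairs.append(("$BYTEORD", "1,2,3,4"))
    pairs.append(("$TOT", str(n_events)))
    pairs.append(("$PAR", str(n_par)))
    pairs.append(("$FIL", sample.sample_id))
    for i, ch in enumerate(sample.channels, start=1):
        pairs.append((f"$P{i}N", ch.name))
        if ch.marker:
            pairs.append((f"$P{i}S", ch.marker))
        pairs.append((f"$P{i}B", "32"))
        pairs.append((f"$P{i}E", "0,0"))
        col_max = float(events[:, i - 1].max()) if n_events else 0.0
        pairs.append((f"$P{i}R", str(max(1, math.ceil(col_max)))))
    owned = {k for k, _ in pairs} | _STRUCTURAL
    for k, v in sample.keywords.items():
        if k not in owned and not (k.startswith("$P") and k[-1] in "NSBER"):
            pairs.append((k, v))

    def render(begindata: int, enddata: int) -> bytes:
        out = [DELIM]
        for k, v in pairs:
            if "{" in v:  # zero-padded so TEXT length is offset-independent
                v = v.format(BEGINDATA=f"{begindata:08d}", ENDDATA=f"{enddata:08d}")
            out.append(_escape(k))
            out.append(DELIM)
            out.append(_escape(v if v != "" else " "))
            out.append(DELIM)
        return b"".join(out)

    # two-pass: offsets rendered with fixed 8-digit fields so length is stable
    header_len = 58
    text = render(10 ** 7, 10 ** 7)  # placeholder with 8-digit numbers
    text_beg = header_len
    text_end = text_beg + len(text) - 1
    data_beg = text_end + 1
    data_len = events.nbytes
    data_end = data_beg + data_len - 1 if data_len else data_beg
    text = render(data_beg, data_end)
    if len(text) != text_end - text_beg + 1:
        raise AssertionError("TEXT length changed between passes")

    def f8(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            raise InvalidSampleError("segment offset exceeds FCS HEADER field width")
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1" + b"    " + f8(text_beg) + f8(text_end)
    if data_end <= 99999999:
        header += f8(data_beg) + f8(data_end)
    else:
        header += f8(0) + f8(0)
    header += f8(0) + f8(0)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        if data_len:
            fh.write(events.tobytes())
        fh.write(b"00000000")  # CRC not computed
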