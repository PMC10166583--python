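"""Reading and writing FCS 3.0/3.1 flow-cytometry files.

An FCS file is a HEADER (format version plus ASCII byte offsets), a TEXT
segment of delimiter-separated keyword/value pairs, and a binary DATA
segment of events x parameters. This module reads FCS 3.0 and 3.1 list-mode
files with float (``$DATATYPE=F``), double (``D``) or integer (``I``) data
and writes FCS 3.1 float files. Channel metadata is exposed through
:class:`ChannelDescriptor`; a whole file is held as an :class:`EventMatrix`.

Log-amplified channels (``$PnE`` with ``f1 > 0``) are returned raw; de-log
scaling is a transform-stage decision and is deliberately not applied here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelDescriptor",
    "EventMatrix",
    "FcsFormatError",
    "read_fcs",
    "write_fcs",
    "harmonize_channels",
]

#: channel roles recognised throughout the pipeline
CHANNEL_ROLES = ("backbone", "infinity", "isotype", "passthrough", "scatter", "time")


class FcsFormatError(ValueError):
    """Raised when a file violates the FCS 3.0/3.1 structure we support."""


@dataclass
class ChannelDescriptor:
    """One detector/parameter of an FCS file.

    Parameters
    ----------
    short_name
        ``$PnN`` — the unique detector name.
    stain_name
        ``$PnS`` — the stain/marker label, if present.
    range
        ``$PnR`` — the stated full-scale range.
    amplification
        ``$PnE`` as ``(f1, f2)``; ``(0, 0)`` means linear acquisition,
        ``f1 > 0`` means the stored values are log-amplified over ``f1``
        decades with ``f2`` at the bottom of scale.
    role
        Pipeline role, one of ``backbone | infinity | isotype |
        passthrough | scatter | time``.
    """

    short_name: str
    stain_name: str | None = None
    range: float = 262144.0
    amplification: tuple[float, float] = (0.0, 0.0)
    role: str = "passthrough"

    def __post_init__(self) -> None:
        if not self.short_name:
            raise ValueError("channel short_name ($PnN) must be non-empty")
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")

    @property
    def is_log_amplified(self) -> bool:
        return self.amplification[0] > 0


@dataclass
class EventMatrix:
    """In-memory form of one FCS file: events x channels plus metadata.

    ``data`` is a dense float array with one row per event and one column per
    entry of ``channels``; ``keywords`` preserves every TEXT-segment keyword
    verbatim so a round trip loses nothing the instrument wrote.
    """

    data: np.ndarray
    channels: list[ChannelDescriptor]
    keywords: dict[str, str] = field(default_factory=dict)
    source_path: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("event data must be 2-D (events x channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channels)} channel descriptors"
            )
        names = [c.short_name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel short names must be unique within a file")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.short_name for c in self.channels]

    def column(self, name: str) -> np.ndarray:
        """Return the data column for channel ``name`` (``$PnN`` exact)."""
        return self.data[:, self.channel_names.index(name)]

    def resolve_channel(self, name: str) -> int:
        """Resolve ``name`` to a column index.

        Resolution order: exact ``$PnN`` match, then exact ``$PnS`` match,
        then case-insensitive ``$PnN``; each fallback is logged so silent
        mis-matches cannot creep into a panel.
        """
        names = self.channel_names
        if name in names:
            return names.index(name)
        stains = [c.stain_name for c in self.channels]
        if name in stains:
            idx = stains.index(name)
            logger.info(
                "channel %r matched via $PnS fallback to $PnN %r in %s",
                name, names[idx], self.source_path or "<memory>",
            )
            return idx
        lowered = [n.lower() for n in names]
        if name.lower() in lowered:
            idx = lowered.index(name.lower())
            logger.info(
                "channel %r matched case-insensitively to $PnN %r in %s",
                name, names[idx], self.source_path or "<memory>",
            )
            return idx
        raise KeyError(
            f"channel {name!r} not found in {self.source_path or '<memory>'} "
            f"(available: {names})"
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    """Split a TEXT segment into keywords, honouring doubled-delimiter escapes."""
    if len(raw) < 2:
        raise FcsFormatError("TEXT segment too short")
    delim = raw[0:1]
    body = raw[1:]
    # strip the single trailing delimiter if present
    if body.endswith(delim):
        body = body[:-1]
    # split on single delimiters; doubled delimiters are escaped literals,
    # which after a plain split appear as empty fields between tokens
    parts = body.split(delim)
    # rebuild honouring escapes: an empty part means two adjacent delimiters
    tokens: list[bytes] = []
    cur = parts[0]
    i = 1
    while i < len(parts):
        if parts[i] == b"":
            # doubled delimiter: literal delimiter inside the current token
            if i + 1 < len(parts):
                cur = cur + delim + parts[i + 1]
                i += 2
            else:
                cur = cur + delim
                i += 1
        else:
            tokens.append(cur)
            cur = parts[i]
            i += 1
    tokens.append(cur)
    if len(tokens) % 2 != 0:
        raise FcsFormatError("TEXT segment has an odd number of fields")
    kw: dict[str, str] = {}
    for k, v in zip(tokens[0::2], tokens[1::2]):
        kw[k.decode("utf-8", "replace").strip()] = v.decode("utf-8", "replace")
    return kw


def _header_offset(raw: bytes) -> int:
    s = raw.decode("ascii", "replace").strip()
    return int(s) if s else 0


def read_fcs(path: str | Path) -> EventMatrix:
    """Read one FCS 3.0/3.1 file into an :class:`EventMatrix`.

    Only list-mode (``$MODE=L``) files with ``$DATATYPE`` ``F``, ``D`` or
    ``I`` are supported; integer data is widened to float. If the file holds
    several chained datasets (``$NEXTDATA != 0``) only the first is read and
    a warning is emitted. All TEXT keywords are preserved verbatim.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FcsFormatError(f"{path}: file too short for an FCS header")
    version = blob[0:6].decode("ascii", "replace")
    if version not in _SUPPORTED_VERSIONS:
        raise FcsFormatError(
            f"{path}: unsupported magic {version!r}; expected FCS3.0 or FCS3.1"
        )
    text_begin = _header_offset(blob[10:18])
    text_end = _header_offset(blob[18:26])
    data_begin = _header_offset(blob[26:34])
    data_end = _header_offset(blob[34:42])
    if not (0 < text_begin < text_end < len(blob)):
        raise FcsFormatError(f"{path}: invalid TEXT offsets {text_begin}..{text_end}")
    keywords = _parse_text_segment(blob[text_begin : text_end + 1])

    # data offsets: HEADER values, falling back to / cross-checked against TEXT
    kw_begin = int(keywords.get("$BEGINDATA", "0") or 0)
    kw_end = int(keywords.get("$ENDDATA", "0") or 0)
    if data_begin == 0:
        data_begin, data_end = kw_begin, kw_end
    elif kw_begin and kw_begin != data_begin:
        raise FcsFormatError(
            f"{path}: HEADER data offset {data_begin} disagrees with "
            f"$BEGINDATA {kw_begin}"
        )
    elif kw_end and kw_end != data_end:
        raise FcsFormatError(
            f"{path}: HEADER data end {data_end} disagrees with $ENDDATA {kw_end}"
        )
    if not (0 < data_begin <= data_end < len(blob)):
        raise FcsFormatError(f"{path}: invalid DATA offsets {data_begin}..{data_end}")

    mode = keywords.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise FcsFormatError(f"{path}: $MODE={mode!r} unsupported; only list mode")
    datatype = keywords.get("$DATATYPE", "").strip().upper()
    if datatype not in ("F", "D", "I"):
        raise FcsFormatError(
            f"{path}: $DATATYPE={datatype!r} unsupported (need F, D or I)"
        )
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    byteord = keywords.get("$BYTEORD", "1,2,3,4").strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FcsFormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    raw = blob[data_begin : data_end + 1]
    if datatype == "F":
        dtype = np.dtype(endian + "f4")
        expected = n_tot * n_par * 4
        if len(raw) < expected:
            raise FcsFormatError(
                f"{path}: DATA segment holds {len(raw)} bytes but $TOT={n_tot}, "
                f"$PAR={n_par} require {expected}"
            )
        data = np.frombuffer(raw[:expected], dtype=dtype).astype(np.float64)
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
        expected = n_tot * n_par * 8
        if len(raw) < expected:
            raise FcsFormatError(
                f"{path}: DATA segment holds {len(raw)} bytes but needs {expected}"
            )
        data = np.frombuffer(raw[:expected], dtype=dtype).astype(np.float64)
    else:  # integer: per-channel widths from $PnB
        bits = [int(keywords[f"$P{i}B"]) for i in range(1, n_par + 1)]
        if any(b not in (8, 16, 32, 64) for b in bits):
            raise FcsFormatError(f"{path}: unsupported $PnB widths {bits}")
        row_bytes = sum(b // 8 for b in bits)
        expected = n_tot * row_bytes
        if len(raw) < expected:
            raise FcsFormatError(
                f"{path}: DATA segment holds {len(raw)} bytes but $TOT={n_tot} "
                f"rows of {row_bytes} bytes require {expected}"
            )
        if len(set(bits)) == 1:
            dtype = np.dtype(endian + f"u{bits[0] // 8}")
            data = np.frombuffer(raw[:expected], dtype=dtype).astype(np.float64)
        else:
            fields = [(f"p{i}", endian + f"u{b // 8}") for i, b in enumerate(bits)]
            rec = np.frombuffer(raw[:expected], dtype=np.dtype(fields))
            data = np.stack(
                [rec[f"p{i}"].astype(np.float64) for i in range(n_par)], axis=1
            ).ravel()
    data = data.reshape(n_tot, n_par)
    if not np.all(np.isfinite(data)):
        raise FcsFormatError(f"{path}: non-finite values in DATA segment")

    channels = []
    for i in range(1, n_par + 1):
        pne = keywords.get(f"$P{i}E", "0,0")
        try:
            f1, f2 = (float(x) for x in pne.split(","))
        except ValueError:
            f1, f2 = 0.0, 0.0
        channels.append(
            ChannelDescriptor(
                short_name=keywords.get(f"$P{i}N", f"P{i}"),
                stain_name=keywords.get(f"$P{i}S") or None,
                range=float(keywords.get(f"$P{i}R", "262144") or 262144),
                amplification=(f1, f2),
            )
        )

    nextdata = int(keywords.get("$NEXTDATA", "0") or 0)
    if nextdata != 0:
        warnings.warn(
            f"{path}: file chains additional datasets ($NEXTDATA={nextdata}); "
            "only the first dataset was read",
            stacklevel=2,
        )
    return EventMatrix(
        data=data, channels=channels, keywords=keywords, source_path=str(path)
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _escape(value: str, delim: str) -> str:
    return value.replace(delim, delim * 2)


def write_fcs(matrix: EventMatrix, path: str | Path) -> Path:
    """Write ``matrix`` as an FCS 3.1 file (float32, little-endian, list mode).

    Reading the result back reproduces the data to float32 precision, the
    channel order, and every user keyword (keywords containing the delimiter
    are escaped by doubling it, per the standard).
    """
    path = Path(path)
    data = np.asarray(matrix.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot write non-finite event values to FCS")
    n_tot, n_par = data.shape
    delim = "/"

    kw: dict[str, str] = {}
    # user keywords first (required ones below overwrite stale copies)
    for k, v in matrix.keywords.items():
        if not k.startswith("$"):
            kw[k] = v
    kw["$MODE"] = "L"
    kw["$DATATYPE"] = "F"
    kw["$BYTEORD"] = "1,2,3,4"
    kw["$PAR"] = str(n_par)
    kw["$TOT"] = str(n_tot)
    kw["$NEXTDATA"] = "0"
    for i, ch in enumerate(matrix.channels, start=1):
        kw[f"$P{i}N"] = ch.short_name
        if ch.stain_name:
            kw[f"$P{i}S"] = ch.stain_name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = f"{ch.amplification[0]:g},{ch.amplification[1]:g}"
        kw[f"$P{i}R"] = f"{ch.range:g}"

    # assemble TEXT with placeholder offsets, then fix the widths
    def render_text(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = str(begin_data)
        items["$ENDDATA"] = str(end_data)
        items["$BEGINANALYSIS"] = "0"
        items["$ENDANALYSIS"] = "0"
        items["$BEGINSTEXT"] = "0"
        items["$ENDSTEXT"] = "0"
        out = [delim]
        for k, v in items.items():
            out.append(_escape(str(k), delim))
            out.append(delim)
            out.append(_escape(str(v), delim))
            out.append(delim)
        return "".join(out).encode("utf-8")

    header_len = 58
    # iterate: text length depends on the offset digits it embeds
    begin_data = end_data = 0
    for _ in range(8):
        text = render_text(begin_data, end_data)
        text_begin = header_len
        text_end = text_begin + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + max(n_tot * n_par * 4, 1) - 1
        if n_tot == 0:
            new_end = new_begin  # degenerate empty DATA segment of 1 byte
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = render_text(begin_data, end_data)
    text_begin = header_len
    text_end = text_begin + len(text) - 1

    def hdr_field(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for HEADER; $BEGINDATA/$ENDDATA carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    "
    header += hdr_field(text_begin) + hdr_field(text_end)
    header += hdr_field(begin_data) + hdr_field(end_data)
    header += hdr_field(0) + hdr_field(0)
    assert len(header) == header_len

    payload = data.astype("<f4").tobytes()
    if n_tot == 0:
        payload = b"\x00"  # keep begin<=end valid for the empty file

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)
    return path


# ---------------------------------------------------------------------------
# panel harmonization
# ---------------------------------------------------------------------------


def harmonize_channels(
    files: Sequence[EventMatrix], backbone_names: Sequence[str]
) -> list[EventMatrix]:
    """Reorder every file's backbone columns into the shared order.

    Each backbone name is resolved per file ($PnN exact, then $PnS, then
    case-insensitive $PnN). Backbone columns come first in the given order,
    followed by each file's remaining channels in their original order.
    Backbone descriptors get ``role='backbone'``.
    """
    out: list[EventMatrix] = []
    for m in files:
        try:
            bb_idx = [m.resolve_channel(n) for n in backbone_names]
        except KeyError as exc:
            raise KeyError(
                f"backbone channel missing from {m.source_path or '<memory>'}: {exc}"
            ) from exc
        rest = [i for i in range(len(m.channels)) if i not in bb_idx]
        order = bb_idx + rest
        channels = []
        for pos, i in enumerate(order):
            ch = m.channels[i]
            if pos < len(bb_idx):
                ch = replace(ch, short_name=backbone_names[pos], role="backbone")
            channels.append(ch)
        out.append(
            EventMatrix(
                data=m.data[:, order],
                channels=channels,
                keywords=dict(m.keywords),
                source_path=m.source_path,
            )
        )
    return out
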