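"""Reading and writing ABIF-format trace containers (.fsa/.ab1).

ABIF is the Applied Biosystems binary container: a 128-byte header whose
bytes 0-3 are the magic ``ABIF``, a directory of 28-byte entries keyed by a
4-character tag name plus an integer tag number, and big-endian payloads.
Only the subset needed for fragment-analysis traces is implemented: the
reader decodes the common numeric element types and returns raw bytes for
anything exotic; the writer emits minimal, spec-conformant files used as
fixtures and simulator output.

Payloads of four bytes or fewer are stored inline in the entry's offset
field, as the format requires.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    AbifCorruptionError,
    AbifFormatError,
    ChannelNotFoundError,
    CoMigrationError,
    GlycotraceError,
)
from .types import RawTrace

MAGIC = b"ABIF"
_ENTRY = struct.Struct(">4sihhiiii")  # name, number, etype, esize, count, dsize, offset, handle
_HEADER_SIZE = 128

#: element type code -> (struct format char, element size in bytes)
_ELEM_FMT = {
    1: ("B", 1),   # unsigned byte
    2: ("b", 1),   # char / signed byte
    3: ("H", 2),   # unsigned short
    4: ("h", 2),   # short
    5: ("i", 4),   # long
    7: ("f", 4),   # float
    8: ("d", 8),   # double
    13: ("B", 1),  # bool
}


def parse_tag_spec(spec: str) -> tuple[str, int]:
    """Parse ``"DATA,1"`` / ``"DATA 1"`` into a (name, number) pair."""
    for sep in (",", " "):
        if sep in spec:
            name, num = spec.split(sep, 1)
            return name.strip(), int(num)
    raise GlycotraceError(f"cannot parse tag spec {spec!r}; expected 'NAME,number'")


@dataclass(frozen=True)
class TagEntry:
    name: str
    number: int
    elem_type: int
    elem_size: int
    elem_count: int
    data: object  # decoded sequence for known types, raw bytes otherwise

    @property
    def key(self) -> tuple[str, int]:
        return (self.name, self.number)


@dataclass
class AbifRecord:
    """Fully indexed ABIF file: version, directory entries, provenance."""

    version: int
    directory: list[TagEntry]
    provenance: str = "synthetic"
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for entry in self.directory:
            if entry.key in self._index:
                raise AbifCorruptionError(
                    f"duplicate directory entry {entry.name},{entry.number}")
            self._index[entry.key] = entry

    def get(self, name: str, number: int) -> TagEntry:
        try:
            return self._index[(name, number)]
        except KeyError:
            raise ChannelNotFoundError(
                f"tag {name},{number} not found; available DATA tags: "
                f"{self.data_tags()}") from None

    def has(self, name: str, number: int) -> bool:
        return (name, number) in self._index

    def data_tags(self) -> list[str]:
        return [f"{e.name},{e.number}" for e in self.directory if e.name == "DATA"]


def _decode_payload(etype: int, esize: int, count: int, payload: bytes, tag: str):
    if etype in _ELEM_FMT:
        char, size = _ELEM_FMT[etype]
        if size != esize:
            raise AbifCorruptionError(
                f"tag {tag}: element size {esize} inconsistent with type {etype}")
        try:
            return list(struct.unpack(f">{count}{char}", payload[: count * size]))
        except struct.error as exc:
            raise AbifCorruptionError(f"tag {tag}: payload decode failed: {exc}") from exc
    return payload  # unknown element type: keep raw bytes


def read_abif(path) -> AbifRecord:
    """Read and fully index an ABIF file.

    Raises
    ------
    AbifFormatError
        When the file does not start with the ``ABIF`` magic.
    AbifCorruptionError
        When the directory or any payload is truncated, naming the tag.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 6 or blob[:4] != MAGIC:
        raise AbifFormatError(f"{path}: not an ABIF file (bad magic)")
    version = struct.unpack(">h", blob[4:6])[0]
    if len(blob) < 6 + _ENTRY.size:
        raise AbifCorruptionError(f"{path}: header truncated before tdir entry")
    tname, tnum, tetype, tesize, tcount, tdsize, toffset, _ = _ENTRY.unpack(
        blob[6: 6 + _ENTRY.size])
    if tname != b"tdir":
        raise AbifCorruptionError(f"{path}: missing tdir root directory entry")
    dir_bytes = tcount * _ENTRY.size
    if tdsize != dir_bytes:
        raise AbifCorruptionError(
            f"{path}: tdir size {tdsize} != {tcount} entries x {_ENTRY.size}")
    if toffset < 0 or toffset + dir_bytes > len(blob):
        raise AbifCorruptionError(f"{path}: directory truncated (tag tdir)")

    entries: list[TagEntry] = []
    for i in range(tcount):
        off = toffset + i * _ENTRY.size
        name_b, number, etype, esize, count, dsize, doffset, _ = _ENTRY.unpack(
            blob[off: off + _ENTRY.size])
        name = name_b.decode("ascii", errors="replace")
        tag = f"{name},{number}"
        if dsize != count * esize:
            raise AbifCorruptionError(
                f"{path}: tag {tag}: data size {dsize} != count {count} x size {esize}")
        if dsize <= 4:
            # inline storage: the offset field holds the payload bytes
            payload = struct.pack(">i", doffset)[:dsize]
        else:
            if doffset < 0 or doffset + dsize > len(blob):
                raise AbifCorruptionError(f"{path}: payload truncated (tag {tag})")
            payload = blob[doffset: doffset + dsize]
        entries.append(TagEntry(name, number, etype, esize, count,
                                _decode_payload(etype, esize, count, payload, tag)))
    return AbifRecord(version=version, directory=entries, provenance=str(path))


def extract_channels(record: AbifRecord,
                     glycan_tag: str = "DATA,1",
                     ladder_tag: str = "DATA,105",
                     sample_id: str = "") -> tuple[RawTrace, RawTrace]:
    """Extract the glycan and size-standard channels as co-migrating traces.

    Raises :class:`ChannelNotFoundError` listing the available DATA tags when
    a channel is absent, and :class:`CoMigrationError` when the two channels
    have different lengths (they must share one scan axis).
    """
    traces = []
    for spec in (glycan_tag, ladder_tag):
        name, number = parse_tag_spec(spec)
        entry = record.get(name, number)
        if isinstance(entry.data, (bytes, bytearray)):
            raise GlycotraceError(
                f"tag {spec}: element type {entry.elem_type} is not numeric")
        traces.append(RawTrace(np.asarray(entry.data, dtype=float),
                               channel_tag=spec, sample_id=sample_id))
    glycan, ladder = traces
    if len(glycan) != len(ladder):
        raise CoMigrationError(
            f"channels must co-migrate: {glycan_tag} has {len(glycan)} scans, "
            f"{ladder_tag} has {len(ladder)}")
    return glycan, ladder


_WRITE_RANGES = {4: (-(2 ** 15), 2 ** 15 - 1), 5: (-(2 ** 31), 2 ** 31 - 1)}


def write_abif(channels: Mapping[str, Sequence[int]], path, *,
               elem_type: int = 4, version: int = 101) -> Path:
    """Write a minimal ABIF file with the given integer channels.

    ``channels`` maps tag specs (``"DATA,1"``) to integer sequences.  The
    writer emits big-endian short (type 4) arrays by default; values outside
    the element type's range raise rather than overflow silently.
    """
    if elem_type not in _WRITE_RANGES:
        raise GlycotraceError(f"writer supports element types 4 and 5, not {elem_type}")
    lo, hi = _WRITE_RANGES[elem_type]
    char, esize = _ELEM_FMT[elem_type]
    if not channels:
        raise GlycotraceError("no channels to write")

    payloads: list[tuple[str, int, bytes, int]] = []
    for spec, values in channels.items():
        name, number = parse_tag_spec(spec)
        vals = [int(v) for v in np.asarray(values).tolist()]
        if len(vals) == 0:
            raise GlycotraceError(f"channel {spec} is empty")
        bad = [v for v in vals if not (lo <= v <= hi)]
        if bad:
            raise GlycotraceError(
                f"channel {spec}: value {bad[0]} outside element type {elem_type} "
                f"range [{lo}, {hi}]")
        payloads.append((name, number, struct.pack(f">{len(vals)}{char}", *vals), len(vals)))

    # layout: 128-byte header | payloads (>4 bytes each) | directory
    body = bytearray()
    entries = []
    offset = _HEADER_SIZE
    for name, number, blob, count in payloads:
        dsize = len(blob)
        if dsize <= 4:
            inline = struct.unpack(">i", blob.ljust(4, b"\x00"))[0]
            entries.append((name, number, elem_type, esize, count, dsize, inline))
        else:
            entries.append((name, number, elem_type, esize, count, dsize, offset))
            body += blob
            offset += dsize
    dir_offset = offset
    directory = bytearray()
    for name, number, etype, esz, count, dsize, doff in entries:
        directory += _ENTRY.pack(name.encode("ascii"), number, etype, esz,
                                 count, dsize, doff, 0)

    header = bytearray(_HEADER_SIZE)
    header[0:4] = MAGIC
    header[4:6] = struct.pack(">h", version)
    header[6: 6 + _ENTRY.size] = _ENTRY.pack(
        b"tdir", 1, 1023, _ENTRY.size, len(entries), len(directory), dir_offset, 0)

    path = Path(path)
    path.write_bytes(bytes(header) + bytes(body) + bytes(directory))
    return path


def read_trace_tsv(path, sample_id: str = "", channel_tag: str = "tsv") -> RawTrace:
    """Plain-text fallback: two-column (scan, intensity) trace."""
    try:
        arr = np.loadtxt(path, ndmin=2)
    except ValueError:
        arr = np.loadtxt(path, ndmin=2, skiprows=1)  # tolerate a header line
    if arr.shape[1] < 2:
        raise GlycotraceError(f"{path}: expected two columns (scan, intensity)")
    return RawTrace(arr[:, 1], channel_tag=channel_tag, sample_id=sample_id)
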