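"""Byte-exact run-length codec for PBWT columns and the .pbwt container.

Each run of identical alleles is emitted as single-byte tokens: the top
bit carries the allele value, bits 6-5 select the unit (00 -> 1,
01 -> 64, 10 -> 2048, 11 reserved) and bits 4-0 the unit count (1..31).
A run is decomposed greedily largest-unit-first, so a run of length
64 < r < 2048 typically costs two bytes.  The encoding is canonical:
a given column has exactly one valid payload.

The container layout is fixed little-endian:

    magic  b"PBWT1"
    header <u32 M> <u32 N> <u32 C> <u32 flags>      (flags bit0: sites,
                                                     bit1: d checkpoints)
    body   [site table] [N column records] [checkpoint records]
    crc32  <u32> of the body

Column record: <u32 c_k> <u32 payload_len> payload.  Checkpoint record:
<u32 k> M x u32 a values, then (if present) zigzag-varint encoded d
deltas (d[0], then d[i]-d[i-1]).
"""

from __future__ import annotations

import gzip
import io
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CodecError, ContainerError
from .panel import SITE_COLUMNS

MAGIC = b"PBWT1"
_UNITS = np.array([1, 64, 2048, 0], dtype=np.int64)  # index 3 reserved


def rle_encode(column) -> bytes:
    """Encode one binary column as a canonical run-length byte payload."""
    col = np.asarray(column)
    if col.size and not np.isin(col, (0, 1)).all():
        raise CodecError("column contains non-binary values")
    col = col.astype(np.uint8, copy=False)
    m = col.shape[0]
    if m == 0:
        return b""
    change = np.flatnonzero(col[1:] != col[:-1])
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [m])))
    values = col[starts]
    out = bytearray()
    for val, run in zip(values, lengths):
        base = 0x80 if val else 0x00
        r = int(run)
        for unit_code, unit in ((2, 2048), (1, 64), (0, 1)):
            n_units = r // unit
            r -= n_units * unit
            while n_units > 0:
                cnt = min(n_units, 31)
                out.append(base | (unit_code << 5) | cnt)
                n_units -= cnt
    return bytes(out)


def rle_tokens(payload: bytes):
    """Decode a payload into (values, lengths) run token arrays.

    Tokens sharing a value bit are *not* merged; callers that need
    maximal runs should merge.  Raises CodecError on reserved unit codes
    or zero counts.
    """
    tok = np.frombuffer(payload, dtype=np.uint8)
    values = (tok >> 7).astype(np.uint8)
    unit_code = (tok >> 5) & 0x3
    counts = (tok & 0x1F).astype(np.int64)
    if np.any(unit_code == 3):
        raise CodecError("reserved unit code 11 in payload")
    if np.any(counts == 0):
        raise CodecError("zero-count token in payload")
    lengths = counts * _UNITS[unit_code]
    return values, lengths


def rle_decode(payload: bytes, m: int) -> np.ndarray:
    """Exact inverse of :func:`rle_encode`; decoded length must equal m."""
    if len(payload) == 0:
        if m != 0:
            raise CodecError(f"empty payload for column of {m} alleles")
        return np.zeros(0, dtype=np.uint8)
    values, lengths = rle_tokens(payload)
    total = int(lengths.sum())
    if total != m:
        raise CodecError(f"payload decodes to {total} alleles, expected {m}")
    return np.repeat(values, lengths)


# ---------------------------------------------------------------------------
# varint helpers (d-checkpoint deltas)
# ---------------------------------------------------------------------------


def _zigzag(x: int) -> int:
    return (x << 1) ^ (x >> 63)


def _unzigzag(z: int) -> int:
    return (z >> 1) ^ -(z & 1)


def _write_varints(values, out: bytearray) -> None:
    prev = 0
    for v in values:
        z = _zigzag(int(v) - prev)
        prev = int(v)
        while True:
            byte = z & 0x7F
            z >>= 7
            if z:
                out.append(byte | 0x80)
            else:
                out.append(byte)
                break


def _read_varints(buf: memoryview, offset: int, n: int):
    vals = np.empty(n, dtype=np.int32)
    prev = 0
    for i in range(n):
        z = 0
        shift = 0
        while True:
            if offset >= len(buf):
                raise ContainerError("truncated varint block")
            byte = buf[offset]
            offset += 1
            z |= (byte & 0x7F) << shift
            shift += 7
            if not byte & 0x80:
                break
        prev += _unzigzag(z)
        vals[i] = prev
    return vals, offset


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


def _serialize(index) -> bytes:
    body = bytearray()
    has_sites = index.sites is not None
    has_d = bool(index.d_checkpoints)
    if has_sites:
        chroms = index.sites["chrom"].astype(str).to_numpy()
        poss = index.sites["pos"].to_numpy()
        refs = index.sites["ref"].astype(str).to_numpy()
        alts = index.sites["alt"].astype(str).to_numpy()
        body += struct.pack("<I", len(index.sites))
        for chrom, pos, ref, alt in zip(chroms, poss, refs, alts):
            for s in (chrom, ref, alt):
                b = s.encode()
                body += struct.pack("<H", len(b)) + b
            body += struct.pack("<q", int(pos))
    for c, payload in zip(index.c, index.payloads):
        body += struct.pack("<II", int(c), len(payload))
        body += payload
    cps = sorted(index.a_checkpoints)
    body += struct.pack("<I", len(cps))
    for k in cps:
        body += struct.pack("<I", k)
        body += index.a_checkpoints[k].astype("<u4").tobytes()
        if has_d:
            dbuf = bytearray()
            _write_varints(index.d_checkpoints[k], dbuf)
            body += struct.pack("<I", len(dbuf)) + dbuf
    flags = (1 if has_sites else 0) | (2 if has_d else 0)
    header = MAGIC + struct.pack(
        "<IIII", index.M, index.N, index.checkpoint_interval, flags
    )
    return header + bytes(body) + struct.pack("<I", zlib.crc32(bytes(body)))


def write_pbwt(index, destination) -> None:
    """Write a PBWT index to a path or binary file object."""
    blob = _serialize(index)
    if hasattr(destination, "write"):
        destination.write(blob)
    else:
        Path(destination).write_bytes(blob)


def read_pbwt(source):
    """Read a .pbwt container back into a :class:`~pbwtkit.core.PBWTIndex`."""
    from .core import PBWTIndex  # cycle: core builds indexes, codec stores them

    if hasattr(source, "read"):
        blob = source.read()
    else:
        blob = Path(source).read_bytes()
    if len(blob) < len(MAGIC) + 16 + 4:
        raise ContainerError("file too short to be a .pbwt container")
    if blob[:4] == MAGIC[:4] and blob[: len(MAGIC)] != MAGIC:
        raise ContainerError(
            f"unsupported container version {blob[4:5]!r} (expected {MAGIC[4:5]!r})"
        )
    if blob[: len(MAGIC)] != MAGIC:
        raise ContainerError("bad magic: not a .pbwt container")
    off = len(MAGIC)
    M, N, C, flags = struct.unpack_from("<IIII", blob, off)
    off += 16
    body = blob[off:-4]
    (crc_stored,) = struct.unpack_from("<I", blob, len(blob) - 4)
    if zlib.crc32(body) != crc_stored:
        raise ContainerError("checksum failure: container body is corrupted")
    buf = memoryview(body)
    pos = 0

    def need(n):
        nonlocal pos
        if pos + n > len(buf):
            raise ContainerError("truncated container body")
        old = pos
        pos += n
        return old

    sites = None
    if flags & 1:
        (n_sites,) = struct.unpack_from("<I", buf, need(4))
        recs = []
        for _ in range(n_sites):
            fields = []
            for _f in range(3):
                (ln,) = struct.unpack_from("<H", buf, need(2))
                fields.append(bytes(buf[need(ln) : pos]).decode())
            (p,) = struct.unpack_from("<q", buf, need(8))
            recs.append((fields[0], p, fields[1], fields[2]))
        sites = pd.DataFrame(recs, columns=list(SITE_COLUMNS))

    c = np.empty(N, dtype=np.int64)
    payloads = []
    for k in range(N):
        ck, plen = struct.unpack_from("<II", buf, need(8))
        if ck > M:
            raise ContainerError(f"column {k}: zero count {ck} exceeds M={M}")
        c[k] = ck
        payloads.append(bytes(buf[need(plen) : pos]))

    (n_cp,) = struct.unpack_from("<I", buf, need(4))
    a_checkpoints = {}
    d_checkpoints = {}
    for _ in range(n_cp):
        (k,) = struct.unpack_from("<I", buf, need(4))
        a = np.frombuffer(buf, dtype="<u4", count=M, offset=need(4 * M)).astype(
            np.int32
        )
        a_checkpoints[k] = a
        if flags & 2:
            (dlen,) = struct.unpack_from("<I", buf, need(4))
            dvals, _ = _read_varints(buf, need(dlen), M)
            d_checkpoints[k] = dvals
    if pos != len(buf):
        raise ContainerError(f"{len(buf) - pos} trailing bytes in container body")

    return PBWTIndex(
        M=M,
        N=N,
        checkpoint_interval=C,
        c=c,
        payloads=payloads,
        a_checkpoints=a_checkpoints,
        d_checkpoints=d_checkpoints,
        sites=sites,
    )


# ---------------------------------------------------------------------------
# size accounting
# ---------------------------------------------------------------------------


@dataclass
class SizeStats:
    """Byte accounting for a PBWT index, with an optional gzip baseline."""

    total_bytes: int
    payload_bytes: int
    checkpoint_bytes: int
    site_table_bytes: int
    bytes_per_site: float
    gzip_bytes: int | None = None

    @property
    def gzip_ratio(self) -> float | None:
        """gzip(raw text) size divided by PBWT payload size."""
        if self.gzip_bytes is None or self.payload_bytes == 0:
            return None
        return self.gzip_bytes / self.payload_bytes

    def __str__(self) -> str:
        lines = [
            f"total container bytes   {self.total_bytes}",
            f"column payload bytes    {self.payload_bytes}",
            f"checkpoint bytes        {self.checkpoint_bytes}",
            f"site table bytes        {self.site_table_bytes}",
            f"payload bytes per site  {self.bytes_per_site:.3f}",
        ]
        if self.gzip_bytes is not None:
            lines.append(f"gzip baseline bytes     {self.gzip_bytes}")
            lines.append(f"gzip / PBWT ratio       {self.gzip_ratio:.2f}")
        return "\n".join(lines)


def size_stats(index, raw_text: bytes | None = None) -> SizeStats:
    """Deterministic byte accounting; optionally compare with gzip -6 of raw text."""
    blob = _serialize(index)
    payload_bytes = sum(len(p) for p in index.payloads)
    header = len(MAGIC) + 16
    column_overhead = 8 * index.N
    site_bytes = 0
    if index.sites is not None:
        site_bytes = 4 + sum(
            2 + len(str(c)) + 2 + len(str(r)) + 2 + len(str(a)) + 8
            for c, r, a in zip(
                index.sites["chrom"], index.sites["ref"], index.sites["alt"]
            )
        )
    checkpoint_bytes = (
        len(blob) - header - site_bytes - column_overhead - payload_bytes - 4
    )
    gz = len(gzip.compress(raw_text, compresslevel=6)) if raw_text is not None else None
    return SizeStats(
        total_bytes=len(blob),
        payload_bytes=payload_bytes,
        checkpoint_bytes=checkpoint_bytes,
        site_table_bytes=site_bytes,
        bytes_per_site=payload_bytes / index.N if index.N else 0.0,
        gzip_bytes=gz,
    )


def raw_text_baseline(panel) -> bytes:
    """The raw-text dialect used for gzip comparisons: one 0/1 line per sequence."""
    buf = io.BytesIO()
    for i in range(panel.M):
        buf.write(panel.alleles[i] + ord("0"))
        buf.write(b"\n")
    return buf.getvalue()
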