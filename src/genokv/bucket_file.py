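"""On-disk bucket format: header, sparse index, chunked sorted records.

Layout (all integers big-endian, bit-exact across platforms)::

    magic            8 bytes   b"PSDRDBKT"
    format_version   4 bytes   uint32
    schema_hash     16 bytes   md5 of the canonical schema text
    record_size      4 bytes   uint32, bytes per record
    chunk_size       4 bytes   uint32, records per chunk
    record_count     8 bytes   uint64
    index_entry_count 4 bytes  uint32  == ceil(record_count / chunk_size)
    index entries    index_entry_count * (key_size + 4) bytes
                     each: first key of the chunk + uint32 chunk ordinal
    payload          record_count * record_size bytes, in chunks

The payload is strictly ascending and key-unique; every chunk except
possibly the last holds exactly ``chunk_size`` records.  The sparse index
holds one entry per chunk, so locating a record costs a binary search over
the (in-memory) index plus one chunk read plus an in-chunk binary search.

Writes are atomic: the file is assembled in a temporary sibling and moved
into place with ``os.replace``, so a failed write never leaves a bucket
half-valid and readers of a bucket being replaced keep the old bytes.
"""

from __future__ import annotations

import os
import struct
from bisect import bisect_right
from typing import Iterable, Iterator, List, Optional

from .errors import (
    CorruptionError,
    IncompatibleFileError,
    IntegrityError,
)
from .schema import RecordSchema

MAGIC = b"PSDRDBKT"
FORMAT_VERSION = 1
_HEADER = struct.Struct(">8sI16sIIQI")
HEADER_LEN = _HEADER.size  # 48
_ORDINAL = struct.Struct(">I")


class BucketFile:
    """Read handle over one bucket file; header + sparse index in memory."""

    def __init__(self, path, schema: RecordSchema):
        self.path = os.fspath(path)
        self.schema = schema
        self.bytes_read = 0  # instrumentation: lazy-open contract
        self._fh = open(self.path, "rb")
        try:
            self._read_header_and_index()
        except Exception:
            self._fh.close()
            raise

    # ------------------------------------------------------------------
    def _read(self, n: int) -> bytes:
        data = self._fh.read(n)
        self.bytes_read += len(data)
        return data

    def _read_header_and_index(self) -> None:
        raw = self._read(HEADER_LEN)
        if len(raw) < HEADER_LEN:
            raise CorruptionError(f"{self.path}: file shorter than header")
        (magic, version, schema_hash, record_size, chunk_size,
         record_count, index_entry_count) = _HEADER.unpack(raw)
        if magic != MAGIC:
            raise IncompatibleFileError(f"{self.path}: bad magic {magic!r}")
        if version != FORMAT_VERSION:
            raise IncompatibleFileError(
                f"{self.path}: format version {version}, expected {FORMAT_VERSION}"
            )
        if schema_hash != self.schema.schema_hash():
            raise IncompatibleFileError(
                f"{self.path}: schema hash mismatch (file written with a "
                f"different schema than {self.schema.name!r})"
            )
        if record_size != self.schema.record_size:
            raise IncompatibleFileError(
                f"{self.path}: record_size {record_size} != "
                f"schema {self.schema.record_size}"
            )
        expected_entries = -(-record_count // chunk_size) if record_count else 0
        if index_entry_count != expected_entries:
            raise CorruptionError(
                f"{self.path}: index_entry_count {index_entry_count}, "
                f"expected {expected_entries}"
            )
        self.record_size = record_size
        self.chunk_size = chunk_size
        self.record_count = record_count
        self.index_entry_count = index_entry_count

        ks = self.schema.key_size
        entry_len = ks + 4
        self.index_len = index_entry_count * entry_len
        self.data_offset = HEADER_LEN + self.index_len

        idx_raw = self._read(self.index_len)
        if len(idx_raw) < self.index_len:
            raise CorruptionError(f"{self.path}: truncated index")
        self.first_keys: List[bytes] = []
        for i in range(index_entry_count):
            off = i * entry_len
            key = idx_raw[off : off + ks]
            (ordinal,) = _ORDINAL.unpack(idx_raw[off + ks : off + entry_len])
            if ordinal != i:
                raise CorruptionError(
                    f"{self.path}: index entry {i} has ordinal {ordinal}"
                )
            if self.first_keys and key <= self.first_keys[-1]:
                raise CorruptionError(
                    f"{self.path}: index first_keys not strictly ascending"
                )
            self.first_keys.append(key)

        actual = os.fstat(self._fh.fileno()).st_size
        expected = self.data_offset + record_count * record_size
        if actual != expected:
            raise CorruptionError(
                f"{self.path}: file length {actual}, header implies {expected}"
            )

    # ------------------------------------------------------------------
    @property
    def n_chunks(self) -> int:
        return self.index_entry_count

    def records_in_chunk(self, ordinal: int) -> int:
        if ordinal < self.n_chunks - 1:
            return self.chunk_size
        return self.record_count - (self.n_chunks - 1) * self.chunk_size

    def locate_chunk(self, key: bytes) -> Optional[int]:
        """Ordinal of the chunk whose key range could contain ``key``.

        Binary search over index entries; keys before the first entry map to
        chunk 0, keys past the end clamp to the last chunk.  ``None`` for an
        empty bucket.
        """
        if self.record_count == 0:
            return None
        pos = bisect_right(self.first_keys, key) - 1
        return max(pos, 0)

    def read_chunk_raw(self, ordinal: int) -> bytes:
        if not (0 <= ordinal < self.n_chunks):
            raise IndexError(
                f"chunk ordinal {ordinal} out of range [0, {self.n_chunks})"
            )
        n = self.records_in_chunk(ordinal)
        self._fh.seek(self.data_offset + ordinal * self.chunk_size * self.record_size)
        raw = self._read(n * self.record_size)
        if len(raw) != n * self.record_size:
            raise CorruptionError(f"{self.path}: short read in chunk {ordinal}")
        return raw

    def read_chunk(self, ordinal: int) -> List[bytes]:
        raw = self.read_chunk_raw(ordinal)
        rs = self.record_size
        return [raw[i : i + rs] for i in range(0, len(raw), rs)]

    def iter_chunks(self) -> Iterator[List[bytes]]:
        for c in range(self.n_chunks):
            yield self.read_chunk(c)

    def iter_records(self) -> Iterator[bytes]:
        for chunk in self.iter_chunks():
            yield from chunk

    def read_all(self) -> List[bytes]:
        return list(self.iter_records())

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False


def write_bucket(path, schema: RecordSchema, records: Iterable[bytes],
                 chunk_size: int) -> None:
    """Write a sorted, key-unique stream of encoded records as a bucket file.

    The input must be strictly ascending by key with duplicates already
    resolved; violations raise :class:`IntegrityError` and leave no file
    behind (an existing file at ``path`` is untouched).
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    path = os.fspath(path)
    rs = schema.record_size
    ks = schema.key_size
    tmp_payload = path + ".payload.tmp"
    tmp_final = path + ".tmp"

    first_keys: List[bytes] = []
    record_count = 0
    last_key: Optional[bytes] = None
    chunk: List[bytes] = []

    try:
        with open(tmp_payload, "wb") as payload:
            for rec in records:
                if len(rec) != rs:
                    raise IntegrityError(
                        f"record of {len(rec)} bytes, schema requires {rs}"
                    )
                key = rec[:ks]
                if last_key is not None and key <= last_key:
                    raise IntegrityError(
                        "input stream not strictly ascending by key "
                        "(unsorted or duplicate key)"
                    )
                last_key = key
                if not chunk:
                    first_keys.append(key)
                chunk.append(rec)
                record_count += 1
                if len(chunk) == chunk_size:
                    payload.write(b"".join(chunk))
                    chunk = []
            if chunk:
                payload.write(b"".join(chunk))

        with open(tmp_final, "wb") as out:
            out.write(_HEADER.pack(
                MAGIC, FORMAT_VERSION, schema.schema_hash(), rs,
                chunk_size, record_count, len(first_keys),
            ))
            for i, key in enumerate(first_keys):
                out.write(key)
                out.write(_ORDINAL.pack(i))
            with open(tmp_payload, "rb") as payload:
                while True:
                    buf = payload.read(1 << 20)
                    if not buf:
                        break
                    out.write(buf)
            out.flush()
            os.fsync(out.fileno())
        os.replace(tmp_final, path)
    finally:
        for tmp in (tmp_payload, tmp_final):
            if os.path.exists(tmp):
                os.unlink(tmp)


def open_bucket(path, schema: RecordSchema) -> BucketFile:
    """Open a bucket file: header and sparse index resident, payload lazy."""
    return BucketFile(path, schema)


def audit_bucket(bucket: BucketFile) -> None:
    """Full-file audit: index first_keys, strict key order, record count.

    Raises :class:`CorruptionError` on any inconsistency.
    """
    ks = bucket.schema.key_size
    seen = 0
    last_key = None
    for c in range(bucket.n_chunks):
        chunk = bucket.read_chunk(c)
        if not chunk:
            raise CorruptionError(f"{bucket.path}: empty chunk {c}")
        if chunk[0][:ks] != bucket.first_keys[c]:
            raise CorruptionError(
                f"{bucket.path}: index first_key of chunk {c} does not match "
                "the chunk's first record"
            )
        if c < bucket.n_chunks - 1 and len(chunk) != bucket.chunk_size:
            raise CorruptionError(
                f"{bucket.path}: non-final chunk {c} holds {len(chunk)} records"
            )
        for rec in chunk:
            key = rec[:ks]
            if last_key is not None and key <= last_key:
                raise CorruptionError(
                    f"{bucket.path}: records not strictly ascending in chunk {c}"
                )
            last_key = key
            seen += 1
    if seen != bucket.record_count:
        raise CorruptionError(
            f"{bucket.path}: scanned {seen} records, header says "
            f"{bucket.record_count}"
        )
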