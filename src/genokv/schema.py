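"""Record schemas and the order-preserving fixed-width binary codec.

A record is a tuple of fixed-width fields, split into *key parts* followed by
*value parts*.  Encoding produces a byte string of constant length
(``record_size``) whose leading ``key_size`` bytes are the key.  The codec is
designed so that **bytewise lexicographic comparison of encoded keys equals
comparison of the decoded key tuples**:

* unsigned integers are stored big-endian;
* signed integers are stored big-endian after adding a bias of ``2**(8w-1)``
  (two's-complement order does not survive memcmp, biased order does);
* fixed-width ASCII compares like the underlying characters.

Floats (IEEE-754 big-endian) are allowed in value parts only, where no
ordering guarantee is needed.  Because every record of a schema occupies the
same number of bytes, a file of records supports O(1) seeks to the i-th
record, binary search inside a block, and a sparse (per-chunk) index.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass
from typing import Sequence

from .errors import FieldRangeError, SchemaError

KINDS = ("unsigned-int", "signed-int", "float32", "float64", "fixed-ascii")
_ORDERABLE_KINDS = ("unsigned-int", "signed-int", "fixed-ascii")

# struct codes for the fast path (unsigned widths only; signed ints need the
# bias transform and take the generic path)
_UINT_CODES = {1: "B", 2: "H", 4: "I", 8: "Q"}


@dataclass(frozen=True)
class FieldSpec:
    """One fixed-width field of a record schema.

    Parameters
    ----------
    name : str
        Field name, unique within the schema.
    role : {'key', 'value'}
        Whether the field participates in the record key.
    position : int
        1-based ordinal within its role (key part 1..k, value part 1..v).
    width : int
        Width in bytes (>= 1).  Forced to 4 for float32 and 8 for float64.
    kind : str
        One of ``unsigned-int``, ``signed-int``, ``float32``, ``float64``,
        ``fixed-ascii``.
    """

    name: str
    role: str
    position: int
    width: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown field kind {self.kind!r}")
        if self.role not in ("key", "value"):
            raise SchemaError(f"field role must be 'key' or 'value', got {self.role!r}")
        if self.width < 1:
            raise SchemaError(f"field {self.name!r}: width must be >= 1")
        if self.kind == "float32" and self.width != 4:
            raise SchemaError(f"field {self.name!r}: float32 requires width 4")
        if self.kind == "float64" and self.width != 8:
            raise SchemaError(f"field {self.name!r}: float64 requires width 8")
        if self.role == "key" and self.kind not in _ORDERABLE_KINDS:
            raise SchemaError(
                f"key part {self.name!r} must be an orderable kind, not {self.kind}"
            )


def _encoder(spec: FieldSpec):
    w = spec.width
    if spec.kind == "unsigned-int":
        hi = (1 << (8 * w)) - 1

        def enc(v, _w=w, _hi=hi, _name=spec.name):
            if not (0 <= v <= _hi):
                raise FieldRangeError(
                    f"field {_name!r}: {v} out of range [0, {_hi}]"
                )
            return v.to_bytes(_w, "big")

        return enc
    if spec.kind == "signed-int":
        bias = 1 << (8 * w - 1)

        def enc(v, _w=w, _bias=bias, _name=spec.name):
            if not (-_bias <= v <= _bias - 1):
                raise FieldRangeError(
                    f"field {_name!r}: {v} out of range [{-_bias}, {_bias - 1}]"
                )
            return (v + _bias).to_bytes(_w, "big")

        return enc
    if spec.kind == "float32":
        return struct.Struct(">f").pack
    if spec.kind == "float64":
        return struct.Struct(">d").pack
    # fixed-ascii: caller supplies exactly `width` characters (pads itself);
    # latin-1 keeps the byte<->char mapping lossless for all 256 values
    def enc(v, _w=w, _name=spec.name):
        try:
            b = v.encode("latin-1") if isinstance(v, str) else bytes(v)
        except UnicodeEncodeError:
            raise FieldRangeError(
                f"field {_name!r}: non-byte character in ascii value"
            ) from None
        if len(b) != _w:
            raise FieldRangeError(
                f"field {_name!r}: ascii value must be exactly {_w} bytes, got {len(b)}"
            )
        return b

    return enc


def _decoder(spec: FieldSpec):
    w = spec.width
    if spec.kind == "unsigned-int":
        return lambda b: int.from_bytes(b, "big")
    if spec.kind == "signed-int":
        bias = 1 << (8 * w - 1)
        return lambda b, _bias=bias: int.from_bytes(b, "big") - _bias
    if spec.kind == "float32":
        unpack = struct.Struct(">f").unpack
        return lambda b: unpack(b)[0]
    if spec.kind == "float64":
        unpack = struct.Struct(">d").unpack
        return lambda b: unpack(b)[0]
    return lambda b: b.decode("latin-1")


class RecordSchema:
    """An ordered list of key parts followed by value parts.

    All records of a schema encode to exactly ``record_size`` bytes, the
    first ``key_size`` of which are the key.  Construction validates the
    part ordering (key parts first, ordinals 1..k contiguous).
    """

    def __init__(self, name: str, fields: Sequence[FieldSpec]):
        fields = tuple(fields)
        if not fields:
            raise SchemaError("schema needs at least one field")
        keys = [f for f in fields if f.role == "key"]
        values = [f for f in fields if f.role == "value"]
        if not keys:
            raise SchemaError("schema needs at least one key part")
        if tuple(fields) != tuple(keys) + tuple(values):
            raise SchemaError("key parts must precede all value parts")
        for seq in (keys, values):
            if [f.position for f in seq] != list(range(1, len(seq) + 1)):
                raise SchemaError("part ordinals must be 1..k with no gaps")
        seen = set()
        for f in fields:
            if f.name in seen:
                raise SchemaError(f"duplicate field name {f.name!r}")
            seen.add(f.name)

        self.name = name
        self.fields = fields
        self.key_fields = tuple(keys)
        self.value_fields = tuple(values)
        self.key_size = sum(f.width for f in keys)
        self.value_size = sum(f.width for f in values)
        self.record_size = self.key_size + self.value_size

        self._encoders = [_encoder(f) for f in fields]
        self._decoders = [_decoder(f) for f in fields]
        self._offsets = []
        off = 0
        for f in fields:
            self._offsets.append(off)
            off += f.width

        self._fast = self._build_fast_struct()
        # struct's 's' code pads/truncates silently; enforce exact widths
        self._ascii_widths = [
            (i, f.width) for i, f in enumerate(fields) if f.kind == "fixed-ascii"
        ]

    # -- fast path ---------------------------------------------------------
    def _build_fast_struct(self):
        """Single struct.Struct covering the whole record, when possible."""
        fmt = ">"
        for f in self.fields:
            if f.kind == "unsigned-int" and f.width in _UINT_CODES:
                fmt += _UINT_CODES[f.width]
            elif f.kind == "float32":
                fmt += "f"
            elif f.kind == "float64":
                fmt += "d"
            elif f.kind == "fixed-ascii":
                fmt += f"{f.width}s"
            else:
                return None
        return struct.Struct(fmt)

    # -- codec -------------------------------------------------------------
    def encode(self, values: Sequence) -> bytes:
        if len(values) != len(self.fields):
            raise SchemaError(
                f"schema {self.name!r} has {len(self.fields)} fields, "
                f"got {len(values)} values"
            )
        if self._fast is not None:
            try:
                prepared = tuple(
                    v.encode("latin-1") if isinstance(v, str) else v for v in values
                )
                for i, w in self._ascii_widths:
                    if len(prepared[i]) != w:
                        raise struct.error
                return self._fast.pack(*prepared)
            except (struct.error, OverflowError, AttributeError, TypeError):
                pass  # fall through for a precise per-field error
        return b"".join(enc(v) for enc, v in zip(self._encoders, values))

    def decode(self, raw: bytes) -> tuple:
        if len(raw) != self.record_size:
            raise SchemaError(
                f"expected {self.record_size} bytes, got {len(raw)}"
            )
        out = []
        for f, dec, off in zip(self.fields, self._decoders, self._offsets):
            out.append(dec(raw[off : off + f.width]))
        return tuple(out)

    def encode_key(self, key_values: Sequence) -> bytes:
        """Encode a full key tuple (all key parts) to ``key_size`` bytes."""
        if len(key_values) != len(self.key_fields):
            raise SchemaError(
                f"schema {self.name!r} has {len(self.key_fields)} key parts, "
                f"got {len(key_values)} values"
            )
        return b"".join(
            enc(v) for enc, v in zip(self._encoders, key_values)
        )

    def decode_key(self, raw: bytes) -> tuple:
        if len(raw) != self.key_size:
            raise SchemaError(f"expected {self.key_size} key bytes, got {len(raw)}")
        out = []
        for f, dec, off in zip(self.key_fields, self._decoders, self._offsets):
            out.append(dec(raw[off : off + f.width]))
        return tuple(out)

    def key_of(self, raw: bytes) -> bytes:
        return raw[: self.key_size]

    def partial_key(self, values: Sequence, fill: int = 0x00) -> bytes:
        """Encode the leading key parts and pad the rest with ``fill``.

        With ``fill=0x00`` this is the smallest key sharing the prefix, with
        ``fill=0xff`` the largest — together they bound a prefix range such
        as "all records of chromosome c with start in [x, y]".
        """
        if not 0 < len(values) <= len(self.key_fields):
            raise SchemaError(
                f"need 1..{len(self.key_fields)} leading key parts, "
                f"got {len(values)}"
            )
        enc = b"".join(
            e(v) for e, v in zip(self._encoders, values)
        )
        return enc + bytes([fill]) * (self.key_size - len(enc))

    # -- bounds ------------------------------------------------------------
    def min_key(self) -> bytes:
        return b"\x00" * self.key_size

    def max_key(self) -> bytes:
        return b"\xff" * self.key_size

    # -- serialisation -----------------------------------------------------
    def to_config_text(self) -> str:
        lines = [f"schema\t{self.name}"]
        for f in self.fields:
            lines.append(f"{f.role}\t{f.name}\t{f.kind}\t{f.width}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "RecordSchema":
        name = "unnamed"
        fields = []
        counters = {"key": 0, "value": 0}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "schema":
                name = parts[1]
                continue
            role, fname, kind, width = parts[0], parts[1], parts[2], int(parts[3])
            counters[role] += 1
            fields.append(FieldSpec(fname, role, counters[role], width, kind))
        return cls(name, fields)

    def schema_hash(self) -> bytes:
        """16-byte digest of the canonical schema text (file compatibility)."""
        return hashlib.md5(self.to_config_text().encode()).digest()

    def __eq__(self, other):
        return isinstance(other, RecordSchema) and (
            self.name == other.name and self.fields == other.fields
        )

    def __repr__(self):
        return (
            f"RecordSchema({self.name!r}, {len(self.key_fields)} key parts, "
            f"record_size={self.record_size})"
        )


def encode_record(schema: RecordSchema, values: Sequence) -> bytes:
    """Encode one record; result length is exactly ``schema.record_size``."""
    return schema.encode(values)


def decode_record(schema: RecordSchema, raw: bytes) -> tuple:
    """Exact inverse of :func:`encode_record`."""
    return schema.decode(raw)


def compare_keys(a: bytes, b: bytes) -> int:
    """Bytewise comparison of two encoded keys: -1, 0 or +1.

    Equals comparison of the decoded key tuples by construction of the codec.
    """
    if len(a) != len(b):
        raise SchemaError(f"key length mismatch: {len(a)} vs {len(b)}")
    if a < b:
        return -1
    if a > b:
        return 1
    return 0


def builtin_snp_schema() -> RecordSchema:
    """SNP records keyed by (accession, chromosome, position).

    Key: accession id (1 B), chromosome (2 B), position (4 B); value:
    reference and mutated nucleotide (1 ASCII byte each).  Record size 9 B.
    """
    return RecordSchema(
        "snp",
        [
            FieldSpec("accession", "key", 1, 1, "unsigned-int"),
            FieldSpec("chromosome", "key", 2, 2, "unsigned-int"),
            FieldSpec("position", "key", 3, 4, "unsigned-int"),
            FieldSpec("ref", "value", 1, 1, "fixed-ascii"),
            FieldSpec("alt", "value", 2, 1, "fixed-ascii"),
        ],
    )


def builtin_herv_schema() -> RecordSchema:
    """BLAST-hit records for retroviral fragments mapped onto a genome.

    Key: chromosome (1 B), start/end on chromosome (4 B each), start/end on
    the fragment (2 B each), fragment id (2 B), strand (1 B); value: E-value
    as float32 (4 B).  Key 16 B, record 20 B.
    """
    return RecordSchema(
        "herv",
        [
            FieldSpec("chromosome", "key", 1, 1, "unsigned-int"),
            FieldSpec("chrom_start", "key", 2, 4, "unsigned-int"),
            FieldSpec("chrom_end", "key", 3, 4, "unsigned-int"),
            FieldSpec("herv_start", "key", 4, 2, "unsigned-int"),
            FieldSpec("herv_end", "key", 5, 2, "unsigned-int"),
            FieldSpec("herv_id", "key", 6, 2, "unsigned-int"),
            FieldSpec("strand", "key", 7, 1, "unsigned-int"),
            FieldSpec("evalue", "value", 1, 4, "float32"),
        ],
    )


BUILTIN_SCHEMAS = {
    "snp": builtin_snp_schema,
    "herv": builtin_herv_schema,
}
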