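"""Exception hierarchy for the store.

Every failure mode named in the on-disk and in-memory contracts maps to one
of these classes so callers (and the CLI exit-code mapping) can distinguish
usage errors from data corruption.
"""


class GenoKVError(Exception):
    """Base class for all store errors."""


class SchemaError(GenoKVError):
    """Schema definition or arity/shape violation."""


class FieldRangeError(SchemaError):
    """A field value does not fit the declared width/kind."""


class IntegrityError(GenoKVError):
    """Sorted/unique/fixed-width invariants violated while writing."""


class IncompatibleFileError(GenoKVError):
    """Bucket file magic, version or schema hash does not match."""


class CorruptionError(GenoKVError):
    """Bucket file is internally inconsistent (e.g. truncated)."""


class StoreStateError(GenoKVError):
    """Operation on a closed store, or creating over an existing one."""
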