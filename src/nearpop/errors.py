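"""Exception taxonomy for nearpop.

Exit-code mapping used by the CLI: SchemaError -> 2, GeoIOError -> 3,
CRSError -> 4. FormatError is a schema-level problem with a file's dialect
(wrong extension, not actually GeoParquet) and maps to 2 as well.
"""


class NearpopError(Exception):
    """Base class for all nearpop errors."""


class SchemaError(NearpopError):
    """A table violates the column/ID contract (missing or duplicate IDs,
    missing buffer_dist/buffered_hazard columns, negative distances)."""


class FormatError(SchemaError):
    """A file has an unsupported or inconsistent format."""


class GeoIOError(NearpopError):
    """A file could not be read or written."""


class CRSError(NearpopError):
    """Missing, unsupported, or mismatched coordinate reference system."""


class DomainError(NearpopError, ValueError):
    """An argument is outside its mathematical domain (coordinates out of
    range, negative buffer distance, empty geometry where one is needed)."""
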