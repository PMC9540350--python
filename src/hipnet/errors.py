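"""Structured exceptions raised across the toolkit.

Every error that the contracts define as "structured" derives from
:class:`HipnetError` and carries enough context (column name, sample id,
field name) for a caller to report the failure without parsing the message.
"""


class HipnetError(Exception):
    """Base class for all toolkit errors."""


class MissingColumnError(HipnetError):
    """A mandatory column is absent from an input table."""

    def __init__(self, column: str, source: str = "input table"):
        self.column = column
        self.source = source
        super().__init__(f"missing mandatory column {column!r} in {source}")


class DuplicateFilterError(HipnetError):
    """Two filter specifications target the same metadata field."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"more than one filter supplied for field {field!r}")


class InvalidThresholdError(HipnetError):
    """A threshold or parameter is outside its documented range."""

    def __init__(self, name: str, value, allowed: str):
        self.name = name
        self.value = value
        self.allowed = allowed
        super().__init__(f"{name}={value!r} outside allowed range {allowed}")


class BaitQuantError(HipnetError):
    """The bait protein is missing or non-positive in a sample."""

    def __init__(self, bait: str, sample: str):
        self.bait = bait
        self.sample = sample
        super().__init__(
            f"bait {bait!r} is missing or non-positive in sample {sample!r}"
        )


class EmptyInputError(HipnetError):
    """An operation received an input it cannot work with (e.g. empty)."""


class DuplicateStudyError(HipnetError):
    """A user dataset re-uses an already-registered study identifier."""

    def __init__(self, study_id: str):
        self.study_id = study_id
        super().__init__(f"study id {study_id!r} is already registered")


class FileFormatError(HipnetError):
    """An input file cannot be read in the expected dialect."""
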