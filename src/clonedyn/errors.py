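"""Exception types shared across the pipeline."""


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A data row could not be parsed; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class EmptyInputError(ValueError):
    """An input table contained a header but no data rows."""


class DuplicateRecordError(ValueError):
    """Duplicate (participant, variant, age) records."""

    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(f"duplicate records for keys: {self.keys}")


class ParameterError(ValueError):
    """An operation was called with an invalid parameter value."""
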