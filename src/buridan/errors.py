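"""Exception hierarchy for trajectory ingestion and analysis."""


class BuridanError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(BuridanError):
    """A file does not follow the expected dialect (missing column, bad header)."""


class DataError(BuridanError):
    """A file parses but its contents violate a data invariant (e.g. time runs backwards)."""


class UsageError(BuridanError):
    """An operation was called with arguments that make no sense (empty input, zero duration)."""
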