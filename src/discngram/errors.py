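"""Exception hierarchy shared across the package."""


class DiscngramError(Exception):
    """Base class for all package-specific errors."""


class DataError(DiscngramError):
    """Invalid or malformed input data (sequences, tables, datasets)."""


class FastaError(DataError):
    """Malformed FASTA input; the message names the file and record."""


class ConfigurationError(DiscngramError):
    """Invalid parameter combination (e.g. fewer than three classes)."""


class PatternError(DiscngramError):
    """A pattern could not be converted; the message names token and offset."""
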