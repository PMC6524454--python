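"""Exception hierarchy shared across neurofind modules."""


class NeurofindError(Exception):
    """Base class for all package errors."""


class FormatError(NeurofindError, ValueError):
    """A record on disk does not conform to the expected schema."""


class CorpusError(NeurofindError, ValueError):
    """A corpus-level invariant is violated (e.g. duplicate report ids)."""


class SizeError(NeurofindError, ValueError):
    """An input collection is too small for the requested operation."""


class DegenerateInputError(NeurofindError, ValueError):
    """Input is degenerate for the operation (e.g. single-class labels)."""


class ConfigurationError(NeurofindError, ValueError):
    """Inconsistent configuration (e.g. shape mismatch, bad rate)."""


class AlignmentError(NeurofindError, ValueError):
    """Paired vectors have mismatched lengths."""
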