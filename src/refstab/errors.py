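"""Exception hierarchy shared across the package."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class ParseError(RefstabError):
    """A file could not be parsed; the message names the offending row."""


class ValidationError(RefstabError):
    """Input data violate a contract (range, uniqueness, presence)."""


class NoAmplificationError(RefstabError):
    """An amplification curve shows no usable exponential phase."""


class RejectedWellError(RefstabError):
    """A well's regression is unusable (non-positive log-slope)."""


class InsufficientDataError(RefstabError):
    """Too few genes, samples or wells for the requested statistic."""


class InvalidDilutionSeriesError(RefstabError):
    """A standard curve has a non-negative Cq-vs-log10(dilution) slope."""
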