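"""Exception hierarchy for the scan pipeline.

Stage code raises these instead of bare ValueError so that the orchestrator
can tag failures with the stage that produced them.
"""


class EpiscanError(Exception):
    """Base class for all pipeline errors."""


class FormatError(EpiscanError):
    """Malformed input file (inconsistent PED/MAP, bad header, ...)."""


class DataError(EpiscanError):
    """Input parsed fine but the data violate a contract (>2 alleles, ...)."""


class DegenerateDataError(DataError):
    """Data too degenerate for the requested computation (monomorphic SNP,
    constant trait, all-missing column)."""


class ParameterError(EpiscanError):
    """Parameter outside its valid range (e.g. rho not in [0, 1))."""


class InsufficientDataError(DataError):
    """Not enough observations to fit the requested model."""
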