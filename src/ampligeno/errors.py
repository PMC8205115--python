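"""Exception hierarchy for the genotyping toolkit.

Every failure mode the pipeline can hit maps to one of these, so callers
(and the CLI) can distinguish bad configuration from bad data from bad
lookups without string-matching messages.
"""


class AmpligenoError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(AmpligenoError):
    """Input data violates an invariant (bad alphabet, duplicate key, ...)."""


class ConfigurationError(AmpligenoError):
    """A configuration file or parameter set is unusable (missing column,
    ambiguous barcode map, ...)."""


class SampleLookupError(AmpligenoError):
    """A FASTQ filename could not be resolved to a sample record."""


class ReadParseError(AmpligenoError):
    """A sequence file is malformed (truncated record, length mismatch)."""


class CapacityError(AmpligenoError):
    """A multiplex layout asks for more barcodes than the sets provide."""


class RunError(AmpligenoError):
    """A whole-run precondition failed (empty input directory, empty join)."""
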