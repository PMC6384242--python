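"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`ImmunoscreenError`; the CLI maps
these to a nonzero exit with the stage name in the message.
"""


class ImmunoscreenError(Exception):
    """Base class for all pipeline errors."""


class InputError(ImmunoscreenError):
    """A required input file is missing or unreadable."""


class ParseError(ImmunoscreenError):
    """A flat file violates its dialect (wrong column count, bad stanza...)."""


class ConfigurationError(ImmunoscreenError):
    """The pipeline configuration is inconsistent with the inputs."""


class LookupError_(ImmunoscreenError):
    """A requested entity (e.g. a chemical) is not present in the table."""


class UsageError(ImmunoscreenError):
    """An operation was called with arguments outside its contract."""
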