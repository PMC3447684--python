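"""Exception hierarchy shared across the package.

All tvnet errors derive from :class:`TVNError` so callers (and the CLI) can
catch domain failures without masking programming errors.
"""


class TVNError(Exception):
    """Base class for all tvnet domain errors."""


class FormatError(TVNError, ValueError):
    """A file does not conform to the expected dialect (bad header, wrong
    column count, unparseable field). The message names the offending line."""


class ValidationError(TVNError, ValueError):
    """Input data violates a domain invariant (self-loop, non-positive
    weight, duplicate edge, bad parameter range)."""


class UsageError(TVNError, ValueError):
    """An operation was invoked in a mode its inputs do not support
    (e.g. in-degree of an undirected series, empty node universe)."""


class GeneLookupError(TVNError, KeyError):
    """A requested gene or group label does not exist in the input."""
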