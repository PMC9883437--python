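"""Exception hierarchy for pairscan.

Exit-code mapping used by the CLI: user-facing input problems (bad files,
bad config) derive from :class:`UserInputError` and exit 1; anything else
is an internal error and exits 2.
"""


class PairscanError(Exception):
    """Base class for all pairscan errors."""


class UserInputError(PairscanError):
    """Invalid user-provided file, value or configuration."""


class MalformedLibraryError(UserInputError):
    """A guide library violates its invariants (duplicate ids, missing genes...)."""


class ParseError(UserInputError):
    """A tabular input file could not be parsed into a valid object."""


class ConfigError(UserInputError):
    """Invalid run or simulation configuration."""


class DegenerateFitError(PairscanError):
    """An anchor regression cannot be fit (zero-variance regressor)."""
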