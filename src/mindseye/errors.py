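"""Exception hierarchy.

All package errors derive from :class:`MindseyeError` so callers can catch
one base class; the subclasses distinguish bad arguments, malformed files,
inconsistent data, and impossible configurations.
"""


class MindseyeError(Exception):
    """Base class for all errors raised by mindseye."""


class InputError(MindseyeError, ValueError):
    """An argument violates an operation's preconditions."""


class FormatError(MindseyeError, ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class DataError(MindseyeError, ValueError):
    """A file parses but its content is inconsistent (e.g. non-monotone onsets)."""


class ConfigError(MindseyeError, ValueError):
    """A configuration is internally impossible to satisfy."""
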