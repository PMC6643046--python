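"""Exception hierarchy.

Argument errors (bad values passed by the caller) raise :class:`ArgumentError`
(a ``ValueError``); malformed or insufficient input data raise
:class:`DataError`; failed model fits raise :class:`FitError` carrying
diagnostics in the message.
"""


class StoichlabError(Exception):
    """Base class for all package errors."""


class ArgumentError(StoichlabError, ValueError):
    """A function argument violates a precondition."""


class DataError(StoichlabError):
    """Input data are malformed, inconsistent, or insufficient."""


class FitError(StoichlabError):
    """A least-squares fit failed to converge or is ill-posed."""


class ConfigError(StoichlabError):
    """A run/simulation configuration is invalid."""
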