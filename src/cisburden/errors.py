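"""Exception hierarchy shared across the pipeline stages."""


class CisburdenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CisburdenError):
    """A configuration problem: bad parameter ranges, missing mandatory
    columns in a dialect, empty selector sets, unknown module labels.

    The command-line layer maps this to exit code 2.
    """


class InputDataError(CisburdenError):
    """An input-data problem: unreadable or empty files that a stage
    cannot proceed without (zero genes loaded, empty GMT, empty query
    after universe intersection).

    The command-line layer maps this to exit code 1.
    """
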