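"""Package exception hierarchy."""


class NuageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NuageError, ValueError):
    """Invalid generator / model / scorer configuration."""


class InputError(NuageError, ValueError):
    """Invalid data passed to an operation (bad records, wrong shapes)."""
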