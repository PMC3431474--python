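"""Exception hierarchy used across the package."""


class GutsError(Exception):
    """Base class for all package errors."""


class DomainError(GutsError, ValueError):
    """An argument lies outside its mathematical domain (e.g. time outside a profile)."""


class ParameterError(GutsError, ValueError):
    """A parameter value violates a model invariant (e.g. non-positive rate constant)."""


class DataError(GutsError, ValueError):
    """A dataset is malformed or insufficient for the requested operation."""


class ConfigurationError(GutsError, ValueError):
    """A model/pipeline configuration is inconsistent or incomplete."""
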