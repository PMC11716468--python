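"""Exception hierarchy shared across the pipeline."""


class IVDirectError(Exception):
    """Base class for all package errors."""


class InputError(IVDirectError):
    """An input file could not be parsed."""


class ConfigurationError(IVDirectError):
    """A variable map or run configuration is inconsistent with the data."""


class DegenerateTableError(IVDirectError):
    """A contingency table has too few levels (or zero df) to be tested."""


class EstimationError(IVDirectError):
    """A model fit failed even after the fallback strategy."""


class AnalysisError(IVDirectError):
    """A multi-imputation analysis lost too many imputations to proceed."""
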