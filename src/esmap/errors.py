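"""Exception hierarchy shared by all esmap modules."""


class ESMapError(Exception):
    """Base class for all esmap errors."""


class ContractError(ESMapError):
    """A call violated a documented precondition (wrong CRS, missing key, ...)."""


class AlignmentError(ContractError):
    """Two gridded inputs that must share a grid/legend do not."""


class ValidationError(ESMapError):
    """Input data failed a content check (bad scores, non-stochastic rows, ...)."""


class MappingError(ValidationError):
    """A crosswalk left source labels unmapped."""
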