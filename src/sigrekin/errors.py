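"""Exception hierarchy shared across the package."""


class SigrekinError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SigrekinError, ValueError):
    """An argument value is outside its documented domain."""


class ContractError(SigrekinError, ValueError):
    """A precondition on the *state* of an input object is violated
    (e.g. de-logging a profile that is already on the linear scale)."""


class StructuralError(SigrekinError, ValueError):
    """Inputs are individually valid but structurally incompatible
    (mismatched time grids, ragged alignments, unknown contigs...)."""
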