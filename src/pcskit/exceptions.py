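"""Exception hierarchy shared across pcskit modules."""


class PCSKitError(Exception):
    """Base class for all pcskit errors."""


class ValidationError(PCSKitError):
    """Input violates a structural contract (shape, labels, symmetry, duplicates)."""


class DegenerateInputError(PCSKitError):
    """Data is structurally valid but statistically degenerate (zero variance, n=0)."""


class ContractError(PCSKitError):
    """Two objects that must share an atlas / edge ordering do not."""


class UndefinedScoreError(PCSKitError):
    """A score has no defined value (e.g. template with no non-zero weights)."""


class ConfigError(PCSKitError):
    """A simulation or pipeline configuration is invalid."""


class DataIntegrityError(PCSKitError):
    """Longitudinal records are inconsistent (e.g. follow-up age <= baseline age)."""
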