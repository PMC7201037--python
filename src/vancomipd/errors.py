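"""Exception hierarchy shared across the package."""


class VancoMipdError(Exception):
    """Base class for all domain errors raised by this package."""


class ValidationError(VancoMipdError):
    """An input value violates a domain invariant."""


class MissingCovariateError(ValidationError):
    """A PK model requires a covariate that the record does not provide."""

    def __init__(self, covariate: str, model_id: str):
        self.covariate = covariate
        self.model_id = model_id
        super().__init__(
            f"model '{model_id}' requires covariate '{covariate}', "
            "which is missing from the patient record"
        )


class ModelUndeterminedError(VancoMipdError):
    """Age-based model selection cannot be resolved from the available ages."""


class ConvergenceError(VancoMipdError):
    """The MAP optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoFeasibleRegimenError(VancoMipdError):
    """No regimen on the search grid attains the requested exposure band."""
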