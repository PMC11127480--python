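"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """A generator or model parameter is outside its admissible domain."""


class IntegrityError(ValueError):
    """Input tables violate a structural contract (overlapping spans, grid mismatch...)."""


class PositivityError(RuntimeError):
    """A predicted probability of exposure/remaining-uncensored is zero for some
    covariate pattern, so an inverse-probability weight is undefined."""


class FitDiagnosticError(RuntimeError):
    """A nuisance-model fit failed (separation, non-convergence)."""


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed for the bands to be trustworthy."""


class ConfigError(ValueError):
    """A run configuration is invalid; carries the full list of violations."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
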