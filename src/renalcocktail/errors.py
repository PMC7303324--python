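"""Exception hierarchy for the renal-marker pipeline."""


class RenalCocktailError(Exception):
    """Base class for package errors."""


class InvalidDesignError(RenalCocktailError):
    """Study design or simulation arguments violate preconditions."""


class EmptyProfileError(RenalCocktailError):
    """All observations of a plasma profile were censored or removed."""


class FitError(RenalCocktailError):
    """Optimiser failed to converge; carries the best parameters seen."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class InvalidCollectionError(RenalCocktailError):
    """Urine collection intervals overlap or are otherwise inconsistent."""


class ConfigurationError(RenalCocktailError):
    """A required marker role, control or stage output is missing."""


class PipelineOrderError(ConfigurationError):
    """A report was requested before an upstream stage produced its output."""
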