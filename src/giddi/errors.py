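"""Exception types shared across the package."""


class GiddiError(Exception):
    """Base class for package errors."""


class UnknownTermError(GiddiError, KeyError):
    """A MedDRA PT identifier is absent from the hierarchy (strict mode)."""


class FeatureUnavailable(GiddiError):
    """A feature cannot be computed for this pair (missing annotations,
    targets, homologs or scored genetic interactions).  Distinct from a
    value of 0.0: pairs with unavailable features are dropped, not imputed.
    """


class BalanceError(GiddiError):
    """A drug-based split could not reach the required label balance."""

    def __init__(self, message: str, best_imbalance: float):
        super().__init__(message)
        self.best_imbalance = best_imbalance
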