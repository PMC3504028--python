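"""Exception hierarchy shared across the package."""


class GrsJointError(Exception):
    """Base class for all package errors."""


class PanelError(GrsJointError):
    """Malformed or inconsistent SNP panel."""


class GenotypeFileError(GrsJointError):
    """Unparseable or panel-incompatible genotype input."""


class AlleleMismatchError(GenotypeFileError):
    """A variant's allele pair cannot be reconciled with the panel descriptor."""


class MonomorphicInputError(GrsJointError):
    """An operation requiring polymorphic dosages received a constant vector.

    Raised (rather than returning 0) so that an undefined r-squared is never
    confused with genuine linkage equilibrium.
    """


class FitError(GrsJointError):
    """A maximum-likelihood fit failed."""


class ConvergenceError(FitError):
    """Newton iterations did not converge within the iteration budget."""


class SeparationError(FitError):
    """Complete or quasi-complete separation: a coefficient diverged."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"separation detected for term {term!r} (|beta| diverging)")
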