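"""Exception hierarchy for octbias."""


class OctBiasError(Exception):
    """Base class for all octbias errors."""


class InvalidContourError(OctBiasError):
    """Contour is degenerate, too small or self-intersecting."""


class PreconditionError(OctBiasError):
    """A documented operation precondition was violated."""


class BiasUndefinedError(OctBiasError):
    """Catheter is (numerically) concentric with the vessel: no bias direction."""


class DomainError(OctBiasError, ValueError):
    """Scalar argument outside its mathematical domain."""


class UnalignableError(OctBiasError):
    """Pullbacks cannot be aligned (missing fiduciary landmark)."""


class NoOverlapError(OctBiasError):
    """Aligned pullbacks share no common analyzable span."""


class UndefinedStatisticError(OctBiasError):
    """Statistic undefined for the given data (constant input, single class...)."""


class DegenerateTestError(OctBiasError):
    """Paired test degenerate (zero variance of the AUC difference)."""


class AnalysisError(OctBiasError):
    """Analysis stage cannot run on the supplied dataset."""


class SchemaError(OctBiasError):
    """Input file does not conform to the pullback JSON schema."""
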