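"""Exception hierarchy for the strain-imaging pipeline.

All errors derive from :class:`PRMStrainError` so callers can catch the
package's failures with one clause while still distinguishing bad
parameters (:class:`SpecificationError`), bad data (:class:`InputError`)
and mathematically undefined results
(:class:`DegenerateDenominatorError`).
"""


class PRMStrainError(Exception):
    """Base class for all package errors."""


class SpecificationError(PRMStrainError, ValueError):
    """A parameter object violates one of its invariants."""


class InputError(PRMStrainError, ValueError):
    """Input data are malformed or inconsistent (shape/grid mismatch...)."""


class DomainError(PRMStrainError, ValueError):
    """A scalar argument lies outside its mathematical domain."""


class DisconnectedMaskError(InputError):
    """A segmentation mask that must be a single component is not."""


class EmptyRegionError(PRMStrainError, ValueError):
    """A muscle region contains no defined strain voxels."""


class DegenerateDenominatorError(PRMStrainError, ArithmeticError):
    """The normalized strain ratio denominator is (numerically) zero.

    The ratio is undefined in this case and is never silently reported
    as infinity.
    """


class StageError(PRMStrainError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause!r}")
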