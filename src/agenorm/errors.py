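"""Exception hierarchy for the pipeline.

Grid mismatches and coverage failures are ordinary data conditions in a
multi-reference analysis, so they get dedicated types that callers can
catch and turn into skip records rather than hard failures.
"""


class AgenormError(Exception):
    """Base class for all package errors."""


class ParameterError(AgenormError, ValueError):
    """An argument violates a documented precondition."""


class GridMismatchError(AgenormError):
    """Two volumes do not share shape and voxel size."""


class FormatError(AgenormError):
    """A file is not a readable scalar NIfTI / atlas of the expected kind."""


class CoverageError(AgenormError):
    """Not enough eligible reference subjects near the target age.

    Carries the target age so callers can log which subjects were skipped.
    """

    def __init__(self, target_age: float, n_eligible: int, k: int):
        self.target_age = target_age
        self.n_eligible = n_eligible
        self.k = k
        super().__init__(
            f"only {n_eligible} eligible reference subjects near age "
            f"{target_age:g} (need {k})"
        )


class DegenerateStatisticError(AgenormError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
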