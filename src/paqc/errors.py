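"""Exception and warning vocabulary shared across the package.

Warnings carry a stable code (e.g. ``W_MISSING_WEIGHT``) as their first
token so batch runs can count them and tests can assert on them.
"""

from __future__ import annotations

import warnings


class PaqcError(Exception):
    """Base class for package errors."""


class CodebookError(PaqcError):
    """The guideline codebook failed to load or violates an invariant."""


class RecordError(PaqcError):
    """A case-record row failed schema validation."""


class UnitMismatchError(PaqcError):
    """A prescription's dose units are incompatible with the dose rule."""


class NotScoreableError(PaqcError):
    """The record carries none of the in-scope diagnoses."""


class DegenerateTableError(PaqcError):
    """A 2x2 table has an empty margin; the tetrachoric rho is undefined."""


class ScoringWarning(UserWarning):
    """Non-fatal scoring condition (missing weight, duplicate prescription...)."""


# stable warning codes
W_MISSING_WEIGHT = "W_MISSING_WEIGHT"
W_OUT_OF_BAND = "W_OUT_OF_BAND"
W_DUPLICATE_RX = "W_DUPLICATE_RX"
W_NOT_SCOREABLE = "W_NOT_SCOREABLE"


def warn(code: str, message: str) -> None:
    warnings.warn(f"{code}: {message}", ScoringWarning, stacklevel=3)
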