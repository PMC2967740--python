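"""Exception hierarchy.

Every error carries a stable machine-readable ``code`` so callers (and the
CLI exit-code mapping) never have to parse messages.
"""

from __future__ import annotations


class PgxError(Exception):
    """Base class for all package errors."""

    code: str = "PGX_ERROR"

    def __init__(self, message: str, *, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class EmptyStatementError(PgxError):
    code = "EMPTY_STATEMENT"


class EmptyCatalogError(PgxError):
    code = "EMPTY_CATALOG"


class EmptySetError(PgxError):
    code = "EMPTY_SET"


class EmptySetsError(PgxError):
    code = "EMPTY_SETS"


class EmptyMatrixError(PgxError):
    code = "EMPTY_MATRIX"


class MissingCategoryError(PgxError):
    code = "MISSING_CATEGORY"


class UnitMismatchError(PgxError):
    code = "UNIT_MISMATCH"


class UnboundDerivationError(PgxError):
    code = "UNBOUND_DERIVATION"


class DerivationLimitError(PgxError):
    code = "DERIVATION_LIMIT"


class ProfileConflictError(PgxError):
    code = "PROFILE_CONFLICT"


class InvalidOverlapError(PgxError):
    code = "INVALID_OVERLAP"


class CatalogFormatError(PgxError):
    """Schema/serialization problem in an interchange file.

    ``context`` points at the offending rule/field where known.
    """

    code = "SCHEMA_ERROR"

    def __init__(self, message: str, *, code: str | None = None, context: str = ""):
        super().__init__(message, code=code)
        self.context = context

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        return f"{base} (at {self.context})" if self.context else base


class InvalidRuleError(PgxError):
    code = "INVALID_RULE"
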