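"""Exception hierarchy and violation records shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field


class ClidescError(Exception):
    """Base class for all errors raised by this package."""


class DescriptorParseError(ClidescError):
    """The descriptor document is not syntactically valid JSON."""

    def __init__(self, message: str, line: int | None = None,
                 column: int | None = None):
        super().__init__(message)
        self.line = line
        self.column = column


class SchemaError(ClidescError):
    """The descriptor document does not conform to the base schema."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(f"{v.path}: {v.message}" for v in self.violations)
        super().__init__(msg or "schema error")


class InvalidDescriptorError(ClidescError):
    """A semantically invalid descriptor was passed where a valid one is required."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations)
        super().__init__(msg or "invalid descriptor")


class InvalidInvocationError(ClidescError):
    """An invocation failed validation against the invocation schema."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations)
        super().__init__(msg or "invalid invocation")


class UnresolvedValueKeyError(ClidescError):
    """A value key could not be substituted because no value is available."""

    def __init__(self, value_key: str):
        super().__init__(f"unresolved value key {value_key!r}")
        self.value_key = value_key


class UnsupportedContainerError(ClidescError):
    """The container type cannot be launched (only simulated)."""


class ExecutionEnvironmentError(ClidescError):
    """A required container runtime is not available on this host."""


class RandomInvocationError(ClidescError):
    """No valid random invocation was found within the attempt budget."""

    def __init__(self, budget: int):
        super().__init__(
            f"no valid invocation found within {budget} attempts; "
            "the descriptor constraints may be unsatisfiable")
        self.budget = budget


@dataclass(frozen=True)
class SchemaViolation:
    """One base-schema conformance failure, located by document path."""

    path: str
    message: str


@dataclass(frozen=True)
class Violation:
    """One semantic rule violation.

    ``rule_code`` identifies the rule (``V1``..``V18`` for descriptor rules,
    ``I1``..``I4`` for invocation rules); ``subjects`` lists the offending
    identifiers or value keys.
    """

    rule_code: str
    message: str
    subjects: tuple[str, ...] = field(default_factory=tuple)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        subj = ",".join(self.subjects)
        return f"{self.rule_code} [{subj}] {self.message}"
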