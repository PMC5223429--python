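"""Exception hierarchy for the GDL interpreter and the registry pipeline."""

from __future__ import annotations


class GDLError(Exception):
    """Base class for all errors raised by this package."""


class GDLSyntaxError(GDLError):
    """A positioned syntax error in guideline or expression text.

    ``line`` and ``column`` are 1-based. For errors inside an expression
    string, ``line`` refers to the guideline file line when known, otherwise 1.
    """

    def __init__(self, message: str, line: int = 1, column: int = 1):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class UnresolvedCodeError(GDLError):
    """A rule references gt-codes that no binding or rule assignment defines."""

    def __init__(self, codes):
        self.codes = sorted(set(codes))
        super().__init__("unresolved gt-codes: " + ", ".join(self.codes))


class UnitError(GDLError):
    """Unknown unit, or a conversion between incommensurable units."""


class EngineError(GDLError):
    """Runtime evaluation failure (type mismatch, iteration cap exceeded)."""


class RegistryError(GDLError):
    """Malformed registry or archetype-dataset input."""


class AssemblyError(GDLError):
    """A patient could not be assembled from the archetype datasets."""


class InfeasibleSpecError(GDLError):
    """A synthetic cohort specification that cannot be satisfied."""


class PipelineError(GDLError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
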