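"""Exception hierarchy and diagnostics shared across the engine."""

from __future__ import annotations

from dataclasses import dataclass


class CwlflowError(Exception):
    """Base class for all engine errors."""


# --- document loading ---------------------------------------------------

class ParseError(CwlflowError):
    """File content is not valid YAML or JSON, or not a mapping."""


class VersionError(CwlflowError):
    """Document declares a cwlVersion other than v1.0."""


class UnsupportedFeature(CwlflowError):
    """Document uses a CWL feature outside the supported subset.

    The message always names the offending feature or key.
    """


class UnresolvedReference(CwlflowError):
    """A ``run:`` file reference or similar could not be resolved."""


# --- job intake ---------------------------------------------------------

class MissingMandatoryField(CwlflowError):
    """Job file lacks one of the mandatory workflow/output_folder/uid keys."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"job file is missing mandatory field {field!r}")


class DuplicateUid(CwlflowError):
    """A job re-uses a uid already present in the run-state store."""


# --- DAG construction ---------------------------------------------------

class CycleDetected(CwlflowError):
    """Workflow dataflow contains a cycle; message lists one cycle's step ids."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("workflow dataflow contains a cycle: " + " -> ".join(cycle))


class ConnectivityError(CwlflowError):
    """Workflow wiring diagnostics escalated to an error."""


# --- step execution -----------------------------------------------------

class UnknownReference(CwlflowError):
    """A $(...) parameter reference names an unknown namespace or id."""


class UnsupportedExpression(CwlflowError):
    """A ``${...}`` JavaScript expression was encountered (out of subset)."""


class TypeMismatch(CwlflowError):
    """A supplied value does not match the declared parameter type."""


class MissingRequiredInput(CwlflowError):
    """A required (non-optional, defaultless) input has no value."""


class StagingError(CwlflowError):
    """An input file could not be staged into the step working directory."""


class SpawnError(CwlflowError):
    """The step executable could not be started at all."""


class MissingOutput(CwlflowError):
    """A non-optional output matched no file after a successful run."""


class AmbiguousOutput(CwlflowError):
    """A single-File output glob matched more than one file."""


# --- scheduler / lifecycle ----------------------------------------------

class ValidationError(CwlflowError):
    """Job or workflow validation failed at dispatch time."""


class DeliveryError(CwlflowError):
    """Outputs could not be moved into the job's output folder."""


class DigestMismatch(CwlflowError):
    """Workflow file changed between pause and resume."""


class UnknownTask(CwlflowError):
    """restart_step was asked for a task id not present in the run."""


class UnknownRun(CwlflowError):
    """No run with the requested uid exists in the store."""


# --- diagnostics --------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    """One validation finding. ``severity`` is ``error`` or ``warning``."""

    severity: str
    message: str
    reference: str = ""

    @property
    def is_error(self) -> bool:
        return self.severity == "error"


def errors_only(diags: list[Diagnostic]) -> list[Diagnostic]:
    return [d for d in diags if d.is_error]
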