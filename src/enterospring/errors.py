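"""Exception hierarchy for enterospring.

All package errors derive from :class:`EnterospringError` so callers can
catch everything from one base, while pipelines (force-map sweeps) can
distinguish recoverable solver failures from configuration mistakes.
"""


class EnterospringError(Exception):
    """Base class for all enterospring errors."""


class InvalidParameterError(EnterospringError, ValueError):
    """A physical parameter is out of its admissible range (e.g. E <= 0)."""


class ConfigurationError(EnterospringError, ValueError):
    """Inconsistent model configuration (inverted range, bad fractions...)."""


class InvalidMeasurementError(EnterospringError, ValueError):
    """A raw measurement is nonphysical (e.g. flattened width <= 0)."""


class NonPhysicalParameterError(EnterospringError, ValueError):
    """Material constants outside the physically meaningful domain (nu > 0.5)."""


class InconsistentMeasurementsError(EnterospringError, ValueError):
    """Layer decomposition produced a negative modulus."""


class EmptyAfterTrimError(EnterospringError, ValueError):
    """Trimming a tensile curve removed every sample."""


class DegenerateSpecimenError(EnterospringError, ValueError):
    """Modulus estimation failed (non-positive slope)."""


class LabellingError(EnterospringError, KeyError):
    """Unknown layer-group label during aggregation."""


class InvertedElementError(EnterospringError, ValueError):
    """det F <= 0: the deformation state is inadmissible."""


class SolverFailureError(EnterospringError, RuntimeError):
    """A nonlinear solve failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MeshingError(EnterospringError, ValueError):
    """Mesh construction failed (degenerate layer vs resolution, etc.)."""


class QueryError(EnterospringError, ValueError):
    """A post-processing query addressed a location outside the mesh."""


class ParseError(EnterospringError, ValueError):
    """Malformed on-disk artifact; carries the offending line when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class PipelineError(EnterospringError, RuntimeError):
    """Every entry of a sweep failed; carries per-spec diagnostics."""

    def __init__(self, message: str, failures: dict | None = None):
        super().__init__(message)
        self.failures = failures or {}
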