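"""Exception hierarchy for the cell-model pipeline."""


class HLECellError(Exception):
    """Base class for all package errors."""


class InvalidKinematicsError(HLECellError):
    """Non-positive stretch or deformation gradient with det F <= 0."""


class InadmissibleMicrostateError(HLECellError):
    """Microstate violates fold-over or substrate-pattern constraints."""


class SolverError(HLECellError):
    """A nonlinear solve (chemical equilibrium, calibration, root find) failed."""


class NonSimpleBoundaryError(HLECellError):
    """Cell boundary polygon self-intersects; shape observables undefined."""


class ParameterError(HLECellError):
    """Invalid or inconsistent model parameters / configuration."""
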