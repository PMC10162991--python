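"""Exception hierarchy for carriermd."""


class CarrierMDError(Exception):
    """Base class for all carriermd errors."""


class FormatError(CarrierMDError):
    """A file could not be parsed as its declared format."""


class EmptyInputError(CarrierMDError):
    """An input contained no usable records (e.g. a PDB with zero atoms)."""


class UnsupportedBoxError(CarrierMDError):
    """Only orthorhombic periodic boxes are supported."""


class TopologyMismatchError(CarrierMDError):
    """Trajectory atom count does not match the supplied topology."""


class TruncatedTrajectoryError(CarrierMDError):
    """A trajectory file ended mid-frame.

    ``frames_read`` holds the number of complete frames successfully read
    before the truncation point.
    """

    def __init__(self, message: str, frames_read: int):
        super().__init__(message)
        self.frames_read = frames_read


class SelectionError(CarrierMDError):
    """A selection expression is malformed or resolves to nothing."""


class EmptySelectionError(SelectionError):
    """An operation received an empty atom selection."""


class AnalysisError(CarrierMDError):
    """An analysis precondition failed (bad window, missing atoms, ...)."""


class SpecError(CarrierMDError):
    """A synthetic-data specification is inconsistent or infeasible."""
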