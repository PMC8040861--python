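"""Exception hierarchy shared across helixgraft modules."""


class HelixgraftError(Exception):
    """Base class for all package errors."""


class PDBParseError(HelixgraftError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(HelixgraftError):
    """A structure contained no coordinate records, or an empty structure
    was passed where a non-empty one is required."""


class SequenceValidationError(HelixgraftError):
    """A sequence contains characters outside the accepted alphabet."""

    def __init__(self, message, offending=None):
        super().__init__(message)
        self.offending = offending or []


class SelectionError(HelixgraftError):
    """A residue/atom selection string is malformed or resolves to nothing."""


class PairingError(HelixgraftError):
    """Residues could not be paired 1:1 between two structures."""

    def __init__(self, message, mismatches=None):
        super().__init__(message)
        self.mismatches = mismatches or []


class ConfigError(HelixgraftError):
    """Invalid configuration value."""


class GraftError(HelixgraftError):
    """A graft was rejected (e.g. anchor RMSD above threshold)."""
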