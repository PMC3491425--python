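"""Exception hierarchy shared across the pipeline stages."""


class OxymarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OxymarkError):
    """Invalid simulation or run configuration; names the offending field."""


class CoordinateError(OxymarkError):
    """A region or position falls outside its contig."""


class SimulationError(OxymarkError):
    """A generator reached an unsatisfiable state (e.g. zero total IP weight)."""


class InputError(OxymarkError):
    """Malformed or invalid user input."""


class ParseError(InputError):
    """A record could not be parsed; carries a line number where possible."""


class ReferenceMismatchError(InputError):
    """A contig referenced by the input is absent from the FASTA index."""


class PairingError(InputError):
    """Two libraries or runs that must be paired do not match."""


class DegenerateFitError(OxymarkError):
    """A model fit is undefined for the given points."""


class CalibrationError(OxymarkError):
    """Score-distribution resolution too coarse or FDR unreachable."""


class MapError(InputError):
    """A scrambled locus map violates its invariants."""


class ProductMapError(OxymarkError):
    """A rearrangement product cannot be tiled onto the locus."""


class CloneMapError(OxymarkError):
    """A bisulfite clone does not align to the reference in either orientation."""


class QCIndeterminateError(OxymarkError):
    """Conversion QC has no informative sites."""


class InsufficientReplicationError(InputError):
    """A qPCR contrast lacks the minimum number of replicates."""
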