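"""Named exceptions raised across the pipeline."""


class SomavarError(Exception):
    """Base class for all package errors."""


class VcfParseError(SomavarError):
    """A VCF file could not be parsed."""


class MissingDepthError(SomavarError):
    """A call set carries no recoverable depth / allele-depth fields."""


class InsufficientDataError(SomavarError):
    """Too few usable observations for a statistical estimate."""


class ReferenceMismatchError(SomavarError):
    """Variant REF alleles disagree with the reference sequence."""


class SimulationError(SomavarError):
    """Infeasible simulation configuration (e.g. exon packing)."""


class PanelError(SomavarError):
    """Degenerate population-panel statistics (zero denominator, empty model)."""


class SignatureError(SomavarError):
    """Invalid signature extraction / refitting input."""
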