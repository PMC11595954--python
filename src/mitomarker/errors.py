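"""Exception hierarchy for the pipeline."""


class MitomarkerError(Exception):
    """Base class for all pipeline errors."""


class ParseError(MitomarkerError):
    """Malformed input file (GenBank, FASTA, newick)."""


class BoundsError(MitomarkerError):
    """Feature coordinates fall outside the sequence on a linear record."""


class MissingGeneError(MitomarkerError):
    """Requested gene absent from a record."""

    def __init__(self, gene: str, available: list[str]):
        self.gene = gene
        self.available = sorted(set(available))
        super().__init__(f"gene {gene!r} not found; available: {', '.join(self.available)}")


class AmbiguousGeneError(MitomarkerError):
    """Gene present in multiple copies and no copy index given."""


class AlphabetError(MitomarkerError):
    """Sequence contains a character outside the allowed alphabet."""


class TranslationError(MitomarkerError):
    """CDS cannot be translated: bad frame or premature/missing stop."""


class AlignmentError(MitomarkerError):
    """Invalid alignment input or malformed alignment."""


class TreeError(MitomarkerError):
    """Invalid tree operation: too few taxa, leaf-set mismatch, parse failure."""


class BarcodeError(MitomarkerError):
    """Barcode encoding/decoding failure."""


class SimulationError(MitomarkerError):
    """Infeasible simulator configuration or planting collision."""
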