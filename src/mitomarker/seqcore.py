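"""Elementary sequence operations.

Reverse complement, GC content and CDS translation under a configurable
genetic code. The default code is NCBI translation table 4 (mold
mitochondrial, TGA = Trp), the convention for fungal mitochondria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

from mitomarker.errors import AlphabetError, TranslationError

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_TABLE_ID = 4


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    cmap = dict(table.forward_table)
    for codon in table.stop_codons:
        cmap[codon] = "*"
    return cmap


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon -> amino-acid map; stops marked '*'."""

    table_id: int = DEFAULT_TABLE_ID
    codon_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.codon_map:
            object.__setattr__(self, "codon_map", _codon_map(self.table_id))
        if len(self.codon_map) != 64:
            raise ValueError(f"codon map must have 64 entries, got {len(self.codon_map)}")
        if "*" not in self.codon_map.values():
            raise ValueError("genetic code must have at least one stop codon")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_map.items() if aa == "*")


MOLD_MITO_CODE = GeneticCode(table_id=4)
STANDARD_CODE = GeneticCode(table_id=1)


def _check_alphabet(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"illegal characters in sequence: {sorted(bad)}")
    return seq


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T) in [0, 1]; N bases are ignored entirely.

    Raises AlphabetError for empty or all-N input (content undefined).
    """
    seq = _check_alphabet(sequence)
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise AlphabetError("GC content undefined for empty or all-N sequence")
    return (seq.count("G") + seq.count("C")) / denom


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}. Involution: rc(rc(s)) == s."""
    seq = _check_alphabet(sequence)
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(sequence: str, code: GeneticCode = MOLD_MITO_CODE, mode: str = "complete") -> str:
    """Translate a coding sequence, returning residues without the stop.

    mode "complete": length divisible by 3, exactly one stop codon, at the
    end; yields len/3 - 1 residues. mode "fragment": in-frame piece, no stop
    required, internal stops are errors.
    """
    if mode not in ("complete", "fragment"):
        raise ValueError(f"unknown translation mode {mode!r}")
    seq = _check_alphabet(sequence)
    if len(seq) % 3 != 0:
        raise TranslationError(f"CDS length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    residues = []
    for idx, codon in enumerate(codons):
        if "N" in codon:
            residues.append("X")
            continue
        aa = code.codon_map[codon]
        if aa == "*":
            if idx != len(codons) - 1:
                raise TranslationError(f"premature stop codon {codon} at codon index {idx}")
            if mode == "fragment":
                raise TranslationError("fragment mode does not accept stop codons")
            return "".join(residues)
        residues.append(aa)
    if mode == "complete":
        raise TranslationError("complete CDS must end with a stop codon")
    return "".join(residues)
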