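"""Reading and writing of annotated mitogenomes and FASTA files.

GenBank flat files are the carrier for annotated circular mitogenomes;
gene features are extracted strand-resolved with normalized lowercase gene
symbols. Coordinates are 1-based inclusive at the interface (matching the
GenBank convention) and 0-based half-open internally; the conversion is
confined to this module.

Parsing and serialization delegate to Biopython's SeqIO; this module owns
the domain types, the gene-name normalization table, and the extraction
semantics (strand resolution, multi-interval joins, origin wrapping).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from mitomarker.errors import (
    AmbiguousGeneError,
    BoundsError,
    MissingGeneError,
    ParseError,
)
from mitomarker.seqcore import reverse_complement

#: Canonical lowercase symbols for the genes the pipeline knows about.
CORE_GENES = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6", "rps3",
)
RRNA_GENES = ("rrnl", "rrns")

#: Synonym map: deposited records vary in case and naming ("cytb" for cob,
#: "COI" for cox1, "rnl" for the large rRNA subunit gene, ...).
GENE_SYNONYMS: dict[str, str] = {
    "cytb": "cob", "cob": "cob", "cytochrome b": "cob",
    "coi": "cox1", "co1": "cox1", "coii": "cox2", "co2": "cox2",
    "coiii": "cox3", "co3": "cox3",
    "rnl": "rrnl", "rrn l": "rrnl", "lsu": "rrnl", "mtlsu": "rrnl",
    "rns": "rrns", "rrn s": "rrns", "ssu": "rrns", "mtssu": "rrns",
    "nad4-l": "nad4l",
}


def normalize_gene_name(name: str) -> str:
    """Case-fold and map synonyms onto the canonical symbol set."""
    key = name.strip().lower()
    return GENE_SYNONYMS.get(key, key)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: 1-based inclusive coordinates, strand-resolved sequence.

    ``sequence`` is already reverse-complemented for minus-strand features,
    so it reads 5'->3' in gene orientation. ``interval_count`` > 1 marks
    joined (intron-containing or origin-wrapping) features whose exons were
    concatenated in annotation order.
    """

    gene_name: str
    start: int
    end: int
    strand: str
    sequence: str
    feature_type: str = "gene"
    interval_count: int = 1

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.gene_name}: end {self.end} < start {self.start}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.interval_count == 1 and len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.gene_name}: sequence length {len(self.sequence)} != span "
                f"{self.end - self.start + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MitogenomeRecord:
    """One annotated (usually circular) mitogenome."""

    accession: str
    organism: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_circular: bool = True

    def __post_init__(self):
        self.sequence = self.sequence.upper()

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def gene_names(self) -> list[str]:
        return [f.gene_name for f in self.features]


def _feature_name(feat) -> str | None:
    for key in ("gene", "standard_name", "product", "locus_tag"):
        if key in feat.qualifiers:
            return normalize_gene_name(feat.qualifiers[key][0])
    return None


_FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "gene")


def _convert_features(record: SeqRecord, circular: bool) -> list[GeneFeature]:
    n = len(record.seq)
    out: list[GeneFeature] = []
    seen: set[tuple[str, int, int]] = set()
    # CDS/rRNA/tRNA carry the biology; bare 'gene' features only fill gaps.
    for ftype in _FEATURE_TYPES:
        for feat in record.features:
            if feat.type != ftype:
                continue
            name = _feature_name(feat)
            if name is None:
                continue
            parts = feat.location.parts
            lo = min(int(p.start) for p in parts)
            hi = max(int(p.end) for p in parts)
            if not circular and (lo < 0 or hi > n):
                raise BoundsError(
                    f"{record.id}: feature {name} at {lo + 1}..{hi} exceeds linear "
                    f"sequence of {n} bp"
                )
            strand = "-" if feat.location.strand == -1 else "+"
            if (name, lo, hi) in seen and ftype == "gene":
                continue  # bare gene feature duplicating a CDS/rRNA/tRNA
            seen.add((name, lo, hi))
            seq = str(feat.extract(record.seq)).upper()
            out.append(
                GeneFeature(
                    gene_name=name,
                    start=lo + 1,
                    end=hi,
                    strand=strand,
                    sequence=seq,
                    feature_type=ftype,
                    interval_count=len(parts),
                )
            )
    out.sort(key=lambda f: (f.start, f.end, f.gene_name))
    return out


def _record_from_seqrecord(rec: SeqRecord) -> MitogenomeRecord:
    circular = rec.annotations.get("topology", "linear") == "circular"
    organism = rec.annotations.get("organism", "") or rec.description
    return MitogenomeRecord(
        accession=rec.id,
        organism=organism,
        sequence=str(rec.seq),
        features=_convert_features(rec, circular),
        is_circular=circular,
    )


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Parse a single-record GenBank flat file into a MitogenomeRecord."""
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return _record_from_seqrecord(rec)


def read_genbank_dir(directory: str | Path, pattern: str = "*.gb*") -> list[MitogenomeRecord]:
    """Parse every GenBank file in a directory, sorted by filename."""
    records = [read_genbank(p) for p in sorted(Path(directory).glob(pattern))]
    seen = set()
    for r in records:
        if r.accession in seen:
            raise ParseError(f"duplicate accession {r.accession} in {directory}")
        seen.add(r.accession)
    return records


def write_genbank(record: MitogenomeRecord, path: str | Path) -> Path:
    """Serialize a MitogenomeRecord back to a GenBank flat file."""
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description=f"{record.organism} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.is_circular else "linear",
            "organism": record.organism,
        },
    )
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        loc = FeatureLocation(f.start - 1, f.end, strand=strand)
        rec.features.append(
            SeqFeature(loc, type=f.feature_type, qualifiers={"gene": [f.gene_name]})
        )
    path = Path(path)
    SeqIO.write([rec], str(path), "genbank")
    return path


def extract_gene(
    record: MitogenomeRecord, gene_name: str, copy_index: int | None = None
) -> GeneFeature:
    """Return the unique feature matching a normalized gene symbol.

    Where both a bare 'gene' feature and its CDS/rRNA exist at the same
    locus the parser already deduplicated them. Multiple true copies (e.g.
    repeated tRNAs) require an explicit 0-based ``copy_index``.
    """
    target = normalize_gene_name(gene_name)
    matches = [f for f in record.features if f.gene_name == target]
    if not matches:
        raise MissingGeneError(target, record.gene_names())
    if len(matches) > 1:
        if copy_index is None:
            raise AmbiguousGeneError(
                f"{record.accession}: {len(matches)} copies of {target}; give copy_index"
            )
        return matches[copy_index]
    return matches[0]


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> Path:
    """Write (id, sequence) pairs as FASTA; ids must be nonempty and unique."""
    entries = list(entries)
    ids = [i for i, _ in entries]
    if any(not i for i in ids):
        raise ValueError("FASTA ids must be nonempty")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def read_fasta(source: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs; accepts a path or raw text."""
    text_mode = isinstance(source, str) and source.lstrip().startswith(">")
    handle = _io.StringIO(source) if text_mode else str(source)
    pairs = [(rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    ids = [i for i, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ParseError("duplicate ids in FASTA input")
    return pairs


def gene_inventory(records: Iterable[MitogenomeRecord]) -> str:
    """Tab-separated inventory: accession, gene, start, end, strand, length."""
    lines = ["accession\tgene\tstart\tend\tstrand\tlength"]
    for rec in records:
        for f in rec.features:
            lines.append(
                f"{rec.accession}\t{f.gene_name}\t{f.start}\t{f.end}\t{f.strand}\t{f.length}"
            )
    return "\n".join(lines) + "\n"


def reverse_complement_record(record: MitogenomeRecord) -> MitogenomeRecord:
    """Flip a record to the opposite strand, preserving extracted gene sequences."""
    n = record.length_bp
    feats = []
    for f in record.features:
        feats.append(
            GeneFeature(
                gene_name=f.gene_name,
                start=n - f.end + 1,
                end=n - f.start + 1,
                strand="-" if f.strand == "+" else "+",
                sequence=f.sequence,
                feature_type=f.feature_type,
                interval_count=f.interval_count,
            )
        )
    feats.sort(key=lambda f: (f.start, f.end, f.gene_name))
    return MitogenomeRecord(
        accession=record.accession,
        organism=record.organism,
        sequence=reverse_complement(record.sequence),
        features=feats,
        is_circular=record.is_circular,
    )
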