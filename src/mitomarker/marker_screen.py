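"""Barcode-marker screening over annotated mitogenome collections.

Scores each candidate gene (the 15 core protein-coding genes plus the two
rRNAs) against the selection criteria for a genus-scale DNA barcode:

* the single-gene tree must reproduce the concatenated 15-core-gene
  reference topology exactly (Robinson-Foulds distance 0);
* the gene must carry at least one between-group diagnostic site;
* it must be short enough to Sanger-sequence and print as a barcode
  (default <= 300 bp) and length-stable across every record;
* genes riddled with indels or high site variation are excluded, as are
  the intron-bearing, length-unstable rRNAs.

Survivors are ranked by ascending length; taxa are then grouped into
clades of zero pairwise marker SNPs, and every clade is annotated with
its SNP positions relative to a designated reference standard.
Species labels are metadata only; the algorithm never uses them.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from mitomarker.align_variants import (
    MultipleAlignment,
    PairwiseAlignment,
    count_variants,
    diagnostic_site_count,
    msa,
    variable_sites,
)
from mitomarker.errors import AlignmentError, TreeError
from mitomarker.mito_io import CORE_GENES, RRNA_GENES, MitogenomeRecord
from mitomarker.phylo import PhyloTree, concat_alignment, nj_tree, p_distance_matrix, rf_distance
from mitomarker.seqcore import GeneticCode, MOLD_MITO_CODE, translate_cds

VERDICT_SELECTED = "selected"
VERDICT_LENGTH_UNSTABLE = "excluded_length_unstable"
VERDICT_TOO_LONG_VARIABLE = "excluded_too_long_variable"
VERDICT_INSUFFICIENT = "excluded_insufficient_resolution"
VERDICT_CANDIDATE = "candidate"


@dataclass
class ScreeningConfig:
    """Thresholds and gene lists for the screen.

    ``max_candidate_variable_fraction`` encodes the "long sequence and
    numerous SNP/InDel sites" exclusion: a gene whose alignment contains
    any indel column, or whose variable-site fraction exceeds the
    threshold, is dropped. ``groups`` optionally overrides the default
    genomic grouping (taxa with zero pairwise differences over the
    concatenated core genes form one group).
    """

    core_gene_list: tuple[str, ...] = CORE_GENES
    rrna_gene_list: tuple[str, ...] = RRNA_GENES
    max_barcode_length: int = 300
    max_candidate_variable_fraction: float = 0.10
    reference_accession: str | None = None
    groups: dict[str, str] | None = None
    genetic_code: GeneticCode = MOLD_MITO_CODE

    def __post_init__(self):
        if not self.core_gene_list:
            raise ValueError("core_gene_list must be nonempty")
        if self.max_barcode_length <= 0 or self.max_candidate_variable_fraction <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class MarkerScore:
    """Screening record for one candidate gene."""

    gene: str
    lengths_across_taxa: list[int]
    length_stable: bool
    median_length_bp: int
    rf_vs_reference: int | None
    interspecies_diagnostic_sites: int
    intraspecies_variable_sites: int
    indel_columns: int
    protein_conserved: bool | None
    verdict: str
    reason: str = ""


@dataclass
class CladeTable:
    """One zero-marker-SNP clade and its SNPs against the barcode standard."""

    clade_id: int
    member_accessions: list[str]
    snps_vs_reference: dict[str, int] = field(default_factory=dict)
    snp_details: dict[str, list[str]] = field(default_factory=dict)


def _gene_sequences(
    records: list[MitogenomeRecord], gene: str
) -> dict[str, str] | None:
    out = {}
    for rec in records:
        matches = [f for f in rec.features if f.gene_name == gene]
        if not matches:
            return None
        out[rec.accession] = matches[0].sequence
    return out


def _retained_records(
    records: list[MitogenomeRecord], config: ScreeningConfig, log: list[str]
) -> list[MitogenomeRecord]:
    retained = []
    for rec in records:
        present = set(rec.gene_names())
        missing = [g for g in config.core_gene_list if g not in present]
        if missing:
            log.append(
                f"dropped {rec.accession}: missing core genes {', '.join(missing)}"
            )
        else:
            retained.append(rec)
    return retained


def core_gene_supermatrix(
    records: list[MitogenomeRecord], config: ScreeningConfig | None = None
) -> MultipleAlignment:
    """Concatenated per-gene alignments over every retained record."""
    config = config or ScreeningConfig()
    log: list[str] = []
    retained = _retained_records(records, config, log)
    if len(retained) < 3:
        raise TreeError(f"fewer than 3 records carry all core genes ({len(retained)})")
    blocks = []
    for gene in config.core_gene_list:
        seqs = _gene_sequences(retained, gene)
        blocks.append(msa(sorted(seqs.items())))
    return concat_alignment(blocks, list(config.core_gene_list))


def build_reference_tree(
    records: list[MitogenomeRecord],
    config: ScreeningConfig | None = None,
    log: list[str] | None = None,
) -> PhyloTree:
    """Neighbor-joining tree on the concatenated core-gene supermatrix.

    Records missing any core gene are dropped with a logged warning.
    """
    config = config or ScreeningConfig()
    log = log if log is not None else []
    retained = _retained_records(records, config, log)
    if len(retained) < 3:
        raise TreeError(f"fewer than 3 records carry all core genes ({len(retained)})")
    blocks = [
        msa(sorted(_gene_sequences(retained, g).items())) for g in config.core_gene_list
    ]
    supermatrix = concat_alignment(blocks, list(config.core_gene_list))
    return nj_tree(p_distance_matrix(supermatrix))


def default_groups(
    records: list[MitogenomeRecord], config: ScreeningConfig
) -> dict[str, str]:
    """Group taxa by genomic identity over the concatenated core genes.

    Taxa whose concatenated core-gene sequences are identical share a
    group; everything else is a singleton. This is the species-free proxy
    the screen uses for "interspecies" when no grouping is supplied.
    """
    retained = _retained_records(records, config, [])
    keys: dict[str, str] = {}
    groups: dict[str, str] = {}
    for rec in retained:
        key = "|".join(
            [f for g in config.core_gene_list for f in
             [next(ft.sequence for ft in rec.features if ft.gene_name == g)]]
        )
        if key not in keys:
            keys[key] = f"G{len(keys) + 1}"
        groups[rec.accession] = keys[key]
    return groups


def _score_gene(
    gene: str,
    seqs: dict[str, str] | None,
    reference_tree: PhyloTree,
    groups: dict[str, str],
    config: ScreeningConfig,
    is_rrna: bool,
) -> MarkerScore:
    if seqs is None:
        return MarkerScore(
            gene=gene,
            lengths_across_taxa=[],
            length_stable=False,
            median_length_bp=0,
            rf_vs_reference=None,
            interspecies_diagnostic_sites=0,
            intraspecies_variable_sites=0,
            indel_columns=0,
            protein_conserved=None,
            verdict=VERDICT_LENGTH_UNSTABLE,
            reason="annotation incomplete in at least one record",
        )
    lengths = [len(s) for s in seqs.values()]
    length_stable = len(set(lengths)) == 1
    median_length = int(statistics.median(lengths))
    alignment = msa(sorted(seqs.items()))
    classes = variable_sites(alignment, groups)
    diagnostic = sum(1 for c in classes if c == "between-group-diagnostic")
    within_var = sum(1 for c in classes if c == "within-group-variable")
    indel_columns = sum(
        1 for j in range(alignment.width) if "-" in alignment.column(j)
    )
    protein_conserved: bool | None = None
    if not is_rrna and length_stable and lengths[0] % 3 == 0:
        try:
            proteins = {translate_cds(s, config.genetic_code) for s in seqs.values()}
            protein_conserved = len(proteins) == 1
        except Exception:
            protein_conserved = None
    rf: int | None = None
    try:
        gene_tree = nj_tree(p_distance_matrix(alignment))
        rf = rf_distance(gene_tree, reference_tree)[0]
    except (TreeError, AlignmentError):
        rf = None

    # Indel evidence is true length variation across taxa, not stray gap
    # columns an aligner may place between length-conserved sequences.
    if is_rrna and not length_stable:
        verdict, reason = VERDICT_LENGTH_UNSTABLE, (
            "intron-driven length variation across taxa"
        )
    elif not length_stable or (
        alignment.width > 0
        and (diagnostic + within_var) / alignment.width
        > config.max_candidate_variable_fraction
    ):
        verdict, reason = VERDICT_TOO_LONG_VARIABLE, (
            f"lengths {min(lengths)}-{max(lengths)} bp, {indel_columns} indel columns, "
            f"{diagnostic + within_var}/{alignment.width} variable sites"
        )
    elif rf is None or rf != 0 or diagnostic < 1:
        verdict = VERDICT_INSUFFICIENT
        reason = (
            "single-gene tree disagrees with reference"
            if rf not in (0, None)
            else "no between-group diagnostic site"
            if diagnostic < 1
            else "gene tree could not be built"
        )
    elif median_length > config.max_barcode_length:
        verdict, reason = VERDICT_CANDIDATE, (
            f"tree-concordant but {median_length} bp exceeds barcode length "
            f"limit {config.max_barcode_length}"
        )
    else:
        verdict, reason = VERDICT_SELECTED, "tree-concordant, diagnostic, short, length-stable"
    return MarkerScore(
        gene=gene,
        lengths_across_taxa=lengths,
        length_stable=length_stable,
        median_length_bp=median_length,
        rf_vs_reference=rf,
        interspecies_diagnostic_sites=diagnostic,
        intraspecies_variable_sites=within_var,
        indel_columns=indel_columns,
        protein_conserved=protein_conserved,
        verdict=verdict,
        reason=reason,
    )


def screen_markers(
    records: list[MitogenomeRecord],
    config: ScreeningConfig | None = None,
    reference_tree: PhyloTree | None = None,
    log: list[str] | None = None,
) -> list[MarkerScore]:
    """Score every candidate gene and rank: selected first, by ascending length."""
    config = config or ScreeningConfig()
    log = log if log is not None else []
    retained = _retained_records(records, config, log)
    if len(retained) < 3:
        raise TreeError("fewer than 3 records carry all core genes")
    if reference_tree is None:
        reference_tree = build_reference_tree(retained, config, log)
    groups = config.groups or default_groups(retained, config)
    scores = []
    for gene in tuple(config.core_gene_list) + tuple(config.rrna_gene_list):
        seqs = _gene_sequences(retained, gene)
        is_rrna = gene in config.rrna_gene_list
        score = _score_gene(gene, seqs, reference_tree, groups, config, is_rrna)
        log.append(f"{gene}: {score.verdict} ({score.reason})")
        scores.append(score)
    order = {
        VERDICT_SELECTED: 0,
        VERDICT_CANDIDATE: 1,
        VERDICT_INSUFFICIENT: 2,
        VERDICT_TOO_LONG_VARIABLE: 3,
        VERDICT_LENGTH_UNSTABLE: 4,
    }
    scores.sort(key=lambda s: (order[s.verdict], s.median_length_bp, s.gene))
    return scores


def _leaf_order(tree: PhyloTree, start: str | None) -> list[str]:
    """Leaves in traversal order, rotated to start at the reference leaf."""
    leaves = tree.leaf_names()
    if start and start in leaves:
        k = leaves.index(start)
        leaves = leaves[k:] + leaves[:k]
    return leaves


def assign_clades(
    tree: PhyloTree,
    marker_msas: dict[str, MultipleAlignment],
    reference_accession: str | None = None,
) -> list[CladeTable]:
    """Partition taxa into clades of zero pairwise SNPs in every marker.

    Two taxa share a clade iff their aligned rows are identical in each
    selected marker. Clades are numbered by tree traversal order starting
    from the reference leaf.
    """
    taxa = tree.leaf_names()
    for gene, alignment in marker_msas.items():
        missing = set(taxa) - set(alignment.taxa)
        if missing:
            raise AlignmentError(f"marker {gene} missing taxa {sorted(missing)}")
    key_of = {
        t: tuple(marker_msas[g].row(t) for g in sorted(marker_msas)) for t in taxa
    }
    clades: list[CladeTable] = []
    key_to_clade: dict[tuple[str, ...], CladeTable] = {}
    for taxon in _leaf_order(tree, reference_accession):
        key = key_of[taxon]
        if key not in key_to_clade:
            table = CladeTable(clade_id=len(clades) + 1, member_accessions=[])
            key_to_clade[key] = table
            clades.append(table)
        key_to_clade[key].member_accessions.append(taxon)
    return clades


def snps_vs_standard(
    clades: list[CladeTable],
    marker_msas: dict[str, MultipleAlignment],
    standard_accession: str,
) -> list[CladeTable]:
    """Annotate each clade with SNP counts/positions of a representative
    member against the barcode standard sequence, per marker."""
    for gene, alignment in marker_msas.items():
        if standard_accession not in alignment.taxa:
            raise AlignmentError(
                f"standard {standard_accession} absent from marker {gene}"
            )
    for clade in clades:
        rep = min(clade.member_accessions)
        for gene in sorted(marker_msas):
            alignment = marker_msas[gene]
            row_std = alignment.row(standard_accession)
            row_rep = alignment.row(rep)
            # drop columns gapped in both rows (shared insertions elsewhere)
            kept = [(a, b) for a, b in zip(row_std, row_rep) if not (a == "-" and b == "-")]
            pair = PairwiseAlignment(
                seq_a_aligned="".join(a for a, _ in kept),
                seq_b_aligned="".join(b for _, b in kept),
                score=0.0,
                label_a=standard_accession,
                label_b=rep,
            )
            summary = count_variants(pair, reference="a")
            clade.snps_vs_reference[gene] = summary.snp_count
            clade.snp_details[gene] = summary.snp_positions
    return clades


def marker_scores_tsv(scores: list[MarkerScore]) -> str:
    header = (
        "gene\tmedian_length_bp\tlength_stable\trf_vs_reference\t"
        "diagnostic_sites\twithin_group_variable\tindel_columns\t"
        "protein_conserved\tverdict\treason"
    )
    lines = [header]
    for s in scores:
        rf = "NA" if s.rf_vs_reference is None else s.rf_vs_reference
        pc = "NA" if s.protein_conserved is None else s.protein_conserved
        lines.append(
            f"{s.gene}\t{s.median_length_bp}\t{s.length_stable}\t{rf}\t"
            f"{s.interspecies_diagnostic_sites}\t{s.intraspecies_variable_sites}\t"
            f"{s.indel_columns}\t{pc}\t{s.verdict}\t{s.reason}"
        )
    return "\n".join(lines) + "\n"


def clades_tsv(clades: list[CladeTable]) -> str:
    lines = ["clade\tmembers\tsnps_vs_standard\tsnp_details"]
    for c in clades:
        snps = ";".join(f"{g}={n}" for g, n in sorted(c.snps_vs_reference.items()))
        details = ";".join(
            f"{g}:[{', '.join(d)}]" for g, d in sorted(c.snp_details.items()) if d
        )
        lines.append(
            f"{c.clade_id}\t{','.join(c.member_accessions)}\t{snps}\t{details}"
        )
    return "\n".join(lines) + "\n"
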