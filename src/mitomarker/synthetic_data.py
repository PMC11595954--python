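"""Synthetic annotated-mitogenome collections with known ground truth.

Emulates a genus-scale clade of fungal mitogenomes: 15 length-conserved
core protein-coding genes (with the canonical per-gene lengths observed in
*Ganoderma*), low within-genus divergence (a handful of substitutions per
short gene), optional synonymous-only evolution (nucleotides diverge while
the encoded protein stays fixed), and intron-bearing rRNA genes whose
lengths vary from taxon to taxon. Substitutions follow a continuous-time
Jukes-Cantor process along a random ultrametric binary tree (or a supplied
newick); every event is logged so that tests can replay the history and
check exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mitomarker.errors import SimulationError
from mitomarker.mito_io import GeneFeature, MitogenomeRecord
from mitomarker.phylo import PhyloTree, TreeNode, newick_read
from mitomarker.seqcore import GeneticCode, MOLD_MITO_CODE, reverse_complement

#: Canonical core-gene lengths (bp) of length-conserved fungal mitogenomes.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "atp6": 774,
    "atp8": 159,
    "atp9": 222,
    "cob": 1158,
    "cox1": 1587,
    "cox2": 756,
    "cox3": 810,
    "nad1": 1017,
    "nad2": 1509,
    "nad3": 360,
    "nad4": 1452,
    "nad4l": 267,
    "nad5": 1983,
    "nad6": 612,
    "rps3": 1020,
}

#: Exon (intron-free) lengths for the rRNA genes; realized lengths grow by
#: 1-4 random introns per taxon, mimicking 2.5-3.2 kb / 1.8-2.1 kb totals.
DEFAULT_RRNA_LENGTHS: dict[str, int] = {"rrnl": 2300, "rrns": 1600}

MINUS_STRAND_GENES = frozenset({"nad6", "rrns"})


@dataclass
class SimConfig:
    """Simulator configuration; ``seed`` fixes all randomness."""

    n_taxa: int = 9
    tree_newick: str | None = None  # fixed tree; otherwise random with seed
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    rrna_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_RRNA_LENGTHS))
    subst_rate: float = 0.01  # per site per unit branch length
    gene_rate_overrides: dict[str, float] = field(default_factory=dict)
    indel_rate: float = 0.0  # per site per unit branch length
    gene_indel_overrides: dict[str, float] = field(default_factory=dict)
    synonymous_only: frozenset[str] = frozenset()
    rrna_intron_count_range: tuple[int, int] = (1, 4)
    rrna_intron_length_range: tuple[int, int] = (100, 400)
    genome_gc: float = 0.27
    genome_length: int = 60_000
    genetic_code: GeneticCode = MOLD_MITO_CODE
    root_gene_overrides: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def rate_for(self, gene: str) -> float:
        return self.gene_rate_overrides.get(gene, self.subst_rate)

    def indel_rate_for(self, gene: str) -> float:
        return self.gene_indel_overrides.get(gene, self.indel_rate)


@dataclass(frozen=True)
class MutationEvent:
    """One logged event on a branch (identified by its child node)."""

    branch: str
    gene: str
    kind: str  # "sub" | "ins" | "del" | "intron"
    position: int  # 1-based on the gene sequence at event time
    ref: str
    alt: str


@dataclass
class TruthSet:
    """Ground truth: the generating tree, root gene sequences, the ordered
    per-branch mutation log, and the identical-marker clade partition."""

    true_tree: PhyloTree
    root_genes: dict[str, str]
    mutation_log: list[MutationEvent]
    clades: dict[str, int]
    marker_genes: tuple[str, str] = ("atp9", "nad4l")

    def events_for(self, gene: str) -> list[MutationEvent]:
        return [e for e in self.mutation_log if e.gene == gene]


def _random_ultrametric_tree(rng: np.random.Generator, labels: list[str]) -> PhyloTree:
    """Random binary ultrametric tree, coalescent-style joins, depth scaled to 1.

    Successive coalescence heights are separated by at least a fixed
    fraction of the eventual depth, so every internal branch represents
    measurable divergence -- emulating a genus whose clades differ by a
    handful of substitutions per short gene rather than collapsing into
    effectively identical lineages.
    """
    nodes = [TreeNode(name=lab) for lab in labels]
    heights = {id(n): 0.0 for n in nodes}
    h = 0.0
    k = len(nodes)
    while len(nodes) > 1:
        h += 0.5 + float(rng.exponential(1.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(children=[a, b])
        a.length = h - heights[id(a)]
        b.length = h - heights[id(b)]
        heights[id(parent)] = h
        nodes = [n for t, n in enumerate(nodes) if t not in (int(i), int(j))] + [parent]
    root = nodes[0]
    # scale depth to 1 so subst_rate is per-site at the root-to-tip scale
    scale = 1.0 / h if h > 0 else 1.0

    def rescale(node: TreeNode):
        node.length *= scale
        for c in node.children:
            rescale(c)

    rescale(root)
    root.length = 0.0
    return PhyloTree(root=root)


def _weighted_base(rng: np.random.Generator, gc: float, size: int) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=size, p=probs))


def _cds_gc_adjust(gc: float, stops: frozenset[str]) -> float:
    """Base-probability GC that yields the target GC after stop-codon
    rejection (stops are AT-rich, so naive sampling runs high)."""

    def realized(g: float) -> float:
        pb = {"A": (1 - g) / 2, "C": g / 2, "G": g / 2, "T": (1 - g) / 2}
        total_gc = total_mass = 0.0
        for c1 in "ACGT":
            for c2 in "ACGT":
                for c3 in "ACGT":
                    codon = c1 + c2 + c3
                    if codon in stops:
                        continue
                    p = pb[c1] * pb[c2] * pb[c3]
                    total_mass += p
                    total_gc += p * sum(b in "GC" for b in codon)
        return total_gc / (3 * total_mass)

    lo, hi = max(gc - 0.1, 0.01), gc
    for _ in range(40):
        mid = (lo + hi) / 2
        if realized(mid) < gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _random_cds(rng: np.random.Generator, length: int, gc: float, code: GeneticCode) -> str:
    if length % 3 != 0 or length < 9:
        raise SimulationError(f"CDS length {length} must be a multiple of 3 and >= 9")
    stops = code.stop_codons
    gc_adj = _cds_gc_adjust(gc, stops)
    codons = ["ATG"]
    while len(codons) < length // 3 - 1:
        c = _weighted_base(rng, gc_adj, 3)
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _synonymous_options(seq: str, code: GeneticCode) -> list[tuple[int, str]]:
    """All (0-based position, new base) single-base changes preserving the protein."""
    options = []
    for ci in range(len(seq) // 3):
        codon = seq[3 * ci : 3 * ci + 3]
        aa = code.codon_map[codon]
        for off in range(3):
            for base in "ACGT":
                if base == codon[off]:
                    continue
                alt = codon[:off] + base + codon[off + 1 :]
                if code.codon_map[alt] == aa:
                    options.append((3 * ci + off, base))
    return options


def _mutate_gene(
    rng: np.random.Generator,
    seq: str,
    gene: str,
    branch_id: str,
    t: float,
    config: SimConfig,
    log: list[MutationEvent],
) -> str:
    rate = config.rate_for(gene)
    n_sub = int(rng.poisson(rate * len(seq) * t))
    synonymous = gene in config.synonymous_only
    is_cds = gene in config.gene_lengths
    stops = config.genetic_code.stop_codons
    for _ in range(n_sub):
        if synonymous:
            options = _synonymous_options(seq, config.genetic_code)
            if not options:
                break
            pos, base = options[int(rng.integers(len(options)))]
        else:
            # purifying selection against nonsense mutations: reject
            # proposals that create a premature in-frame stop codon
            for _attempt in range(20):
                pos = int(rng.integers(len(seq)))
                base = "ACGT".replace(seq[pos], "")[int(rng.integers(3))]
                if not is_cds or len(seq) % 3 != 0:
                    break
                ci = pos // 3
                if ci == len(seq) // 3 - 1:
                    continue  # keep the terminal stop intact
                codon = seq[3 * ci : 3 * ci + 3]
                mutated = codon[: pos % 3] + base + codon[pos % 3 + 1 :]
                if mutated not in stops:
                    break
            else:
                continue
        log.append(MutationEvent(branch_id, gene, "sub", pos + 1, seq[pos], base))
        seq = seq[:pos] + base + seq[pos + 1 :]
    n_indel = int(rng.poisson(config.indel_rate_for(gene) * len(seq) * t))
    for _ in range(n_indel):
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5 and len(seq) > length + 6:
            pos = int(rng.integers(len(seq) - length))
            log.append(MutationEvent(branch_id, gene, "del", pos + 1, seq[pos : pos + length], ""))
            seq = seq[:pos] + seq[pos + length :]
        else:
            pos = int(rng.integers(len(seq) + 1))
            ins = _weighted_base(rng, config.genome_gc, length)
            log.append(MutationEvent(branch_id, gene, "ins", pos + 1, "", ins))
            seq = seq[:pos] + ins + seq[pos:]
    return seq


def _evolve(
    node: TreeNode,
    genes: dict[str, str],
    rng: np.random.Generator,
    config: SimConfig,
    log: list[MutationEvent],
    leaf_genes: dict[str, dict[str, str]],
    counter: list[int],
) -> None:
    if node.is_leaf():
        final = dict(genes)
        for rgene in config.rrna_lengths:
            seq = final[rgene]
            lo, hi = config.rrna_intron_count_range
            k = int(rng.integers(lo, hi + 1))
            for _ in range(k):
                ilen = int(rng.integers(*config.rrna_intron_length_range))
                pos = int(rng.integers(1, len(seq)))
                intron = _weighted_base(rng, config.genome_gc, ilen)
                log.append(MutationEvent(node.name, rgene, "intron", pos + 1, "", intron))
                seq = seq[:pos] + intron + seq[pos:]
            final[rgene] = seq
        leaf_genes[node.name] = final
        return
    for child in node.children:
        if child.is_leaf():
            branch_id = child.name
        else:
            # name internal nodes so the mutation log's branch ids can be
            # located on the truth tree (replay + per-branch reporting)
            if not child.name:
                child.name = f"internal{counter[0]}"
                counter[0] += 1
            branch_id = child.name
        child_genes = {
            g: _mutate_gene(rng, s, g, branch_id, child.length, config, log)
            for g, s in genes.items()
        }
        _evolve(child, child_genes, rng, config, log, leaf_genes, counter)


def _assemble_record(
    accession: str, genes: dict[str, str], spacers: list[str], config: SimConfig
) -> MitogenomeRecord:
    order = sorted(genes)
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for idx, gene in enumerate(order):
        spacer = spacers[idx]
        parts.append(spacer)
        pos += len(spacer)
        gseq = genes[gene]
        strand = "-" if gene in MINUS_STRAND_GENES else "+"
        genomic = reverse_complement(gseq) if strand == "-" else gseq
        parts.append(genomic)
        ftype = "rRNA" if gene in config.rrna_lengths else "CDS"
        features.append(
            GeneFeature(
                gene_name=gene,
                start=pos + 1,
                end=pos + len(gseq),
                strand=strand,
                sequence=gseq,
                feature_type=ftype,
            )
        )
        pos += len(gseq)
    parts.append(spacers[-1])
    return MitogenomeRecord(
        accession=accession,
        organism="Simulatomyces exemplaris",
        sequence="".join(parts),
        features=features,
        is_circular=True,
    )


def _marker_clades(
    leaf_genes: dict[str, dict[str, str]], markers: tuple[str, str]
) -> dict[str, int]:
    key_to_clade: dict[tuple[str, ...], int] = {}
    clades: dict[str, int] = {}
    for taxon in sorted(leaf_genes):
        key = tuple(leaf_genes[taxon][m] for m in markers)
        if key not in key_to_clade:
            key_to_clade[key] = len(key_to_clade) + 1
        clades[taxon] = key_to_clade[key]
    return clades


def simulate_collection(config: SimConfig) -> tuple[list[MitogenomeRecord], TruthSet]:
    """Simulate an annotated mitogenome collection plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    labels = [f"SIM{i + 1:03d}.1" for i in range(config.n_taxa)]
    if config.tree_newick:
        tree = newick_read(config.tree_newick)
        labels = sorted(tree.leaf_names())
    else:
        if config.n_taxa < 3:
            raise SimulationError("need at least 3 taxa")
        tree = _random_ultrametric_tree(rng, labels)

    root_genes: dict[str, str] = {}
    for gene, length in sorted(config.gene_lengths.items()):
        root_genes[gene] = _random_cds(rng, length, config.genome_gc, config.genetic_code)
    for gene, length in sorted(config.rrna_lengths.items()):
        root_genes[gene] = _weighted_base(rng, config.genome_gc, length)
    for gene, seq in config.root_gene_overrides.items():
        if gene not in root_genes:
            raise SimulationError(f"root override for unknown gene {gene!r}")
        if len(seq) != len(root_genes[gene]):
            raise SimulationError(
                f"root override for {gene} is {len(seq)} bp, expected {len(root_genes[gene])}"
            )
        root_genes[gene] = seq.upper()

    genic = sum(len(s) for s in root_genes.values())
    n_spacers = len(root_genes) + 1
    spacer_total = config.genome_length - genic
    if spacer_total < n_spacers * 10:
        raise SimulationError(
            f"genome_length {config.genome_length} too small for {genic} bp of genes"
        )
    base_len = spacer_total // n_spacers
    spacers = [
        _weighted_base(rng, config.genome_gc, base_len + (1 if i < spacer_total % n_spacers else 0))
        for i in range(n_spacers)
    ]

    log: list[MutationEvent] = []
    leaf_genes: dict[str, dict[str, str]] = {}
    _evolve(tree.root, root_genes, rng, config, log, leaf_genes, [0])

    records = [_assemble_record(lab, leaf_genes[lab], spacers, config) for lab in labels]
    truth = TruthSet(
        true_tree=tree,
        root_genes=root_genes,
        mutation_log=log,
        clades=_marker_clades(leaf_genes, ("atp9", "nad4l"))
        if "atp9" in root_genes and "nad4l" in root_genes
        else {lab: i + 1 for i, lab in enumerate(sorted(labels))},
    )
    return records, truth


#: Fixed three-clade topology used by the worked example: three clades of
#: three identical taxa each, separated by measurable stem divergence.
EXAMPLE_TREE = (
    "((A1:0.0,A2:0.0,A3:0.0):0.6,"
    "(B1:0.0,B2:0.0,B3:0.0):0.6,"
    "(C1:0.0,C2:0.0,C3:0.0):0.6);"
)


def example_genus_collection(
    seed: int = 0,
) -> tuple[list[MitogenomeRecord], TruthSet]:
    """Nine-taxon, three-clade collection emulating a genus-scale marker screen.

    The two short marker genes (atp9, nad4L) carry exactly two planted,
    synonymous, clade-diagnostic substitutions each (so every clade is
    distinguished while the encoded proteins stay identical); the shortest
    gene (atp8) evolves with zero substitutions and therefore cannot
    resolve anything; the longest gene (nad5) accumulates indels on the
    clade stems; the rRNA genes carry 1-4 random introns per taxon. The
    remaining core genes evolve neutrally and carry the tree signal.
    """
    rng = np.random.default_rng([seed, 97])
    gc = 0.27
    atp9_root = _random_cds(rng, 222, gc, MOLD_MITO_CODE)
    # codon 23 -> GCA (Ala) so position 69 is A; codon 50 -> GGA (Gly) so
    # position 150 is A; the plants below are then synonymous third-position
    # changes (GCA->GCG, GGA->GGT)
    atp9_root = atp9_root[:66] + "GCA" + atp9_root[69:147] + "GGA" + atp9_root[150:]
    nad4l_root = _random_cds(rng, 267, gc, MOLD_MITO_CODE)
    # codon 10 -> GTA (Val), codon 67 -> CTA (Leu); plants GTA->GTC, CTA->CTC
    nad4l_root = nad4l_root[:27] + "GTA" + nad4l_root[30:198] + "CTA" + nad4l_root[201:]
    config = SimConfig(
        n_taxa=9,
        tree_newick=EXAMPLE_TREE,
        gene_rate_overrides={"atp8": 0.0, "atp9": 0.0, "nad4l": 0.0},
        gene_indel_overrides={"nad5": 0.004},
        root_gene_overrides={"atp9": atp9_root, "nad4l": nad4l_root},
        genome_gc=gc,
        genome_length=40_000,
        seed=seed,
    )
    records, truth = simulate_collection(config)
    clade_b = ["B1", "B2", "B3"]
    clade_c = ["C1", "C2", "C3"]
    plan = [
        (clade_b, "atp9", 69, "G"),
        (clade_c, "atp9", 150, "T"),
        (clade_b, "nad4l", 30, "C"),
        (clade_c, "nad4l", 201, "C"),
    ]
    return plant_diagnostics(records, truth, plan)


def replay_leaf_genes(truth: TruthSet) -> dict[str, dict[str, str]]:
    """Replay the mutation log from the root sequences down the truth tree.

    Returns per-leaf gene sequences; by construction these must equal the
    sequences carried by the simulated records (the log is complete), which
    is the core verification invariant of the generator.
    """
    events_by_branch: dict[str, list[MutationEvent]] = {}
    for e in truth.mutation_log:
        events_by_branch.setdefault(e.branch, []).append(e)

    def apply_events(genes: dict[str, str], branch: str) -> dict[str, str]:
        out = dict(genes)
        for e in events_by_branch.get(branch, []):
            seq = out[e.gene]
            idx = e.position - 1
            if e.kind == "sub":
                if seq[idx] != e.ref:
                    raise SimulationError(
                        f"replay mismatch at {e.branch}/{e.gene}:{e.position}"
                    )
                out[e.gene] = seq[:idx] + e.alt + seq[idx + 1 :]
            elif e.kind == "del":
                if seq[idx : idx + len(e.ref)] != e.ref:
                    raise SimulationError(
                        f"replay mismatch at {e.branch}/{e.gene}:{e.position}"
                    )
                out[e.gene] = seq[:idx] + seq[idx + len(e.ref) :]
            elif e.kind in ("ins", "intron"):
                out[e.gene] = seq[:idx] + e.alt + seq[idx:]
            else:  # pragma: no cover
                raise SimulationError(f"unknown event kind {e.kind}")
        return out

    leaves: dict[str, dict[str, str]] = {}

    def walk(node, genes: dict[str, str]):
        if node.is_leaf():
            # leaf-level events (introns, planted diagnostics) use the leaf
            # name as branch id and are applied on top of the branch events
            leaves[node.name] = genes
            return
        for child in node.children:
            branch = child.name
            walk(child, apply_events(genes, branch))

    root = truth.true_tree.root
    walk(root, dict(truth.root_genes))
    return leaves


def plant_diagnostics(
    records: list[MitogenomeRecord],
    truth: TruthSet,
    plan: list[tuple[list[str], str, int, str]],
) -> tuple[list[MitogenomeRecord], TruthSet]:
    """Plant clade-diagnostic substitutions into designated taxa.

    ``plan`` entries are (accessions, gene, 1-based position on the gene,
    new base). The planted base must differ from the current one and must
    not collide with an existing logged mutation at the same gene position.
    Returns a modified copy of the collection plus updated truth.
    """
    if not plan:
        return records, truth
    occupied = {
        (e.gene, e.position) for e in truth.mutation_log if e.kind == "sub"
    }
    by_acc = {r.accession: r for r in records}
    new_records = {r.accession: r for r in records}
    new_log = list(truth.mutation_log)
    for accessions, gene, position, base in plan:
        if (gene, position) in occupied:
            raise SimulationError(
                f"planting collision: {gene} position {position} already mutated"
            )
        for acc in accessions:
            if acc not in by_acc:
                raise SimulationError(f"unknown accession {acc}")
            rec = new_records[acc]
            feats = []
            changed = False
            genome = rec.sequence
            for f in rec.features:
                if f.gene_name != gene:
                    feats.append(f)
                    continue
                if not 1 <= position <= len(f.sequence):
                    raise SimulationError(
                        f"position {position} outside {gene} ({len(f.sequence)} bp)"
                    )
                old = f.sequence[position - 1]
                if old == base:
                    raise SimulationError(
                        f"{acc} {gene} position {position} already {base}"
                    )
                new_seq = f.sequence[: position - 1] + base + f.sequence[position:]
                if f.strand == "+":
                    gpos = f.start - 1 + position - 1
                    gbase = base
                else:
                    gpos = f.end - position
                    gbase = reverse_complement(base)
                genome = genome[:gpos] + gbase + genome[gpos + 1 :]
                feats.append(replace(f, sequence=new_seq))
                new_log.append(MutationEvent(acc, gene, "sub", position, old, base))
                changed = True
            if not changed:
                raise SimulationError(f"{acc} has no {gene} feature")
            new_records[acc] = MitogenomeRecord(
                accession=rec.accession,
                organism=rec.organism,
                sequence=genome,
                features=feats,
                is_circular=rec.is_circular,
            )
        occupied.add((gene, position))
    out_records = [new_records[r.accession] for r in records]
    leaf_genes = {
        r.accession: {f.gene_name: f.sequence for f in r.features} for r in out_records
    }
    new_truth = TruthSet(
        true_tree=truth.true_tree,
        root_genes=truth.root_genes,
        mutation_log=new_log,
        clades=_marker_clades(leaf_genes, truth.marker_genes)
        if all(
            m in leaf_genes[a] for a in leaf_genes for m in truth.marker_genes
        )
        else truth.clades,
        marker_genes=truth.marker_genes,
    )
    return out_records, new_truth
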